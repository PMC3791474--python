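"""Species-by-site incidence matrices: data model, I/O and graph construction.

The substrate of the whole analysis is a binary occurrence table — species in
rows, sites (nature reserves) in columns, a 1 wherever a species was recorded
in a site.  Species additionally carry a residence-time status (``native``,
``archaeophyte`` or ``neophyte``) and a taxonomic family, which drive the
assemblage splitting and the downstream module-comparison statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATUSES = ("native", "archaeophyte", "neophyte")

#: node-name prefixes keeping species and site labels distinct in the
#: unipartite graph view (a reserve and a species may share a label)
SPECIES_PREFIX = "sp:"
SITE_PREFIX = "st:"


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


class EmptyInputError(ValueError):
    """Raised for empty files or matrices with no occurrences."""


class MissingAttributeError(KeyError):
    """Raised when a species lacks a required attribute (status, family)."""


@dataclass
class IncidenceMatrix:
    """Binary species-by-site occurrence matrix.

    Parameters
    ----------
    species_ids : list of str
        Unique row labels.
    site_ids : list of str
        Unique column labels.
    cells : ndarray of shape (n_species, n_sites)
        0/1 occurrence values.
    species_attrs : DataFrame, optional
        Indexed by species id; typically columns ``status`` and ``family``.
    """

    species_ids: list
    site_ids: list
    cells: np.ndarray
    species_attrs: pd.DataFrame | None = None
    site_attrs: pd.DataFrame | None = None

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids")
        if self.cells.shape != (len(self.species_ids), len(self.site_ids)):
            raise ValueError(
                f"cell block {self.cells.shape} does not match id lists "
                f"({len(self.species_ids)}, {len(self.site_ids)})"
            )
        bad = ~np.isin(self.cells, (0, 1))
        if bad.any():
            raise FormatError("incidence cells must be 0/1")

    # -- basic accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_occurrences(self) -> int:
        """Total number of presences L (= edge count of the bipartite graph)."""
        return int(self.cells.sum())

    def row_sums(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return (
            self.species_ids == other.species_ids
            and self.site_ids == other.site_ids
            and np.array_equal(self.cells, other.cells)
        )

    def copy(self) -> "IncidenceMatrix":
        return IncidenceMatrix(
            list(self.species_ids),
            list(self.site_ids),
            self.cells.copy(),
            None if self.species_attrs is None else self.species_attrs.copy(),
            None if self.site_attrs is None else self.site_attrs.copy(),
        )

    def drop_empty_species(self) -> "IncidenceMatrix":
        """Remove species with zero occurrences (logged, not an error)."""
        keep = self.row_sums() > 0
        if not keep.all():
            dropped = [s for s, k in zip(self.species_ids, keep) if not k]
            logger.warning("dropping %d species with no occurrences: %s",
                           len(dropped), dropped[:10])
        return self.subset_species([s for s, k in zip(self.species_ids, keep) if k])

    def subset_species(self, species: list) -> "IncidenceMatrix":
        idx = [self.species_ids.index(s) for s in species]
        return IncidenceMatrix(
            list(species), list(self.site_ids), self.cells[idx, :],
            self.species_attrs, self.site_attrs,
        )


@dataclass
class AssemblageSet:
    """Per-status views of a parent incidence matrix.

    Sites where a status has no occurrences are dropped from that status's
    matrix (the "Empty" reserve blocks) and listed in ``empty_sites``.
    """

    parent: IncidenceMatrix
    status_map: dict
    matrices: dict = field(default_factory=dict)
    empty_sites: dict = field(default_factory=dict)

    def __getitem__(self, status: str) -> IncidenceMatrix:
        return self.matrices[status]


# ---------------------------------------------------------------------------
# I/O

def load_incidence(path, format: str = "wide") -> IncidenceMatrix:
    """Read an incidence matrix from ``path``.

    ``wide``: header row of site ids, first column species ids, 0/1 cells.
    ``edgelist``: two columns (species, site), one row per presence;
    duplicate rows collapse to a single presence.
    """
    if format == "wide":
        try:
            df = pd.read_csv(path, index_col=0, encoding="utf-8")
        except pd.errors.EmptyDataError as e:
            raise EmptyInputError(f"empty incidence file: {path}") from e
        if df.size == 0:
            raise EmptyInputError(f"no cells in incidence file: {path}")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))][0]
            raise FormatError(f"non-binary cell value {bad!r} in wide incidence file")
        return IncidenceMatrix([str(s) for s in df.index],
                               [str(c) for c in df.columns], vals)
    elif format == "edgelist":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        try:
            df = pd.read_csv(path, sep=sep, header=None, encoding="utf-8",
                             comment="#", dtype=str)
        except pd.errors.EmptyDataError as e:
            raise EmptyInputError(f"empty edge list: {path}") from e
        if df.shape[1] < 2:
            raise FormatError("edge list needs two columns (species, site)")
        # tolerate a header line
        if list(df.iloc[0]) == ["species", "site"]:
            df = df.iloc[1:]
        if df.empty:
            raise EmptyInputError(f"no edges in edge list: {path}")
        return from_edges(list(zip(df.iloc[:, 0], df.iloc[:, 1])))
    raise ValueError(f"unknown format {format!r}")


def from_edges(edges) -> IncidenceMatrix:
    """Build a matrix from (species, site) presence pairs; duplicates collapse."""
    edges = [(str(a), str(b)) for a, b in edges]
    species = sorted({a for a, _ in edges})
    sites = sorted({b for _, b in edges})
    cells = np.zeros((len(species), len(sites)), dtype=np.int8)
    si = {s: i for i, s in enumerate(species)}
    ti = {t: j for j, t in enumerate(sites)}
    for a, b in edges:
        cells[si[a], ti[b]] = 1
    return IncidenceMatrix(species, sites, cells)


def write_incidence(m: IncidenceMatrix, path, format: str = "wide") -> None:
    if format == "wide":
        pd.DataFrame(m.cells, index=m.species_ids, columns=m.site_ids).to_csv(
            path, encoding="utf-8")
    elif format == "edgelist":
        rows, cols = np.nonzero(m.cells)
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        with open(path, "w", encoding="utf-8") as fh:
            for r, c in zip(rows, cols):
                fh.write(f"{m.species_ids[r]}{sep}{m.site_ids[c]}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_species_attrs(path) -> pd.DataFrame:
    """Species attribute table: columns species, status, family."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    required = {"species", "status"}
    if not required.issubset(df.columns):
        raise FormatError(f"species attribute table needs columns {sorted(required)}")
    return df.set_index("species")


# ---------------------------------------------------------------------------
# assemblage splitting

def split_by_status(m: IncidenceMatrix, status_map: dict) -> AssemblageSet:
    """Split a matrix into native / archaeophyte / neophyte assemblages.

    Every species must have a status.  For each status, sites that hold no
    species of that status are dropped from the view and recorded in
    ``empty_sites``.
    """
    missing = [s for s in m.species_ids if s not in status_map]
    if missing:
        raise MissingAttributeError(
            f"species without status: {missing[:5]}" +
            (" ..." if len(missing) > 5 else ""))
    out = AssemblageSet(parent=m, status_map=dict(status_map))
    for status in STATUSES:
        species = [s for s in m.species_ids if status_map[s] == status]
        idx = [m.species_ids.index(s) for s in species]
        block = m.cells[idx, :] if idx else np.zeros((0, m.n_sites), dtype=np.int8)
        occupied = block.sum(axis=0) > 0
        empty = [t for t, occ in zip(m.site_ids, occupied) if not occ]
        sites = [t for t, occ in zip(m.site_ids, occupied) if occ]
        out.matrices[status] = IncidenceMatrix(
            species, sites, block[:, occupied],
            m.species_attrs, m.site_attrs)
        out.empty_sites[status] = empty
    return out


def merge_matrices(matrices) -> IncidenceMatrix:
    """Union of several incidence matrices (combined assemblage).

    Species sets must be disjoint; sites are unioned and absent
    combinations filled with 0.
    """
    matrices = list(matrices)
    species = [s for m in matrices for s in m.species_ids]
    if len(set(species)) != len(species):
        raise ValueError("species sets overlap; cannot merge")
    sites = sorted({t for m in matrices for t in m.site_ids})
    ti = {t: j for j, t in enumerate(sites)}
    cells = np.zeros((len(species), len(sites)), dtype=np.int8)
    row = 0
    for m in matrices:
        cols = [ti[t] for t in m.site_ids]
        cells[row:row + m.n_species, cols] = m.cells
        row += m.n_species
    return IncidenceMatrix(species, sites, cells)


# ---------------------------------------------------------------------------
# graph construction

def species_node(s: str) -> str:
    return SPECIES_PREFIX + str(s)


def site_node(t: str) -> str:
    return SITE_PREFIX + str(t)


def to_bipartite_graph(m: IncidenceMatrix) -> nx.Graph:
    """Undirected bipartite graph: species and sites both become nodes,
    one edge per presence.  Node degrees equal the matrix margins."""
    if m.n_occurrences == 0:
        raise EmptyInputError("matrix has no occurrences; graph would be empty")
    g = nx.Graph()
    g.add_nodes_from((species_node(s), {"kind": "species"}) for s in m.species_ids)
    g.add_nodes_from((site_node(t), {"kind": "site"}) for t in m.site_ids)
    rows, cols = np.nonzero(m.cells)
    g.add_edges_from(
        (species_node(m.species_ids[r]), site_node(m.site_ids[c]))
        for r, c in zip(rows, cols))
    return g
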