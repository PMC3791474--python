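"""Synthetic data with the statistical structure the pipeline assumes.

Reserve inventory datasets of this kind are rarely publicly deposited, so
every pipeline input can be generated here instead:

* planted-module incidence matrices with tunable module strength
  (``p_in``/``p_out``) and lognormal degree heterogeneity;
* a three-assemblage suite of increasing module strength
  (neophyte < archaeophyte < native), mimicking the residence-time
  ordering, together with a family table whose module compositions grow
  more distinct with assemblage age, a genetic distance matrix with
  within-module clustering for natives, and a habitat table whose
  descriptor means differ by site module;
* exact-margin random matrices (Gale–Ryser constructive fill + swaps).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .incidence import IncidenceMatrix, species_node, site_node
from .modularity import Partition


def _planted_cells(sp_mod, st_mod, p_in, p_out, degree_heterogeneity, rng):
    """One Bernoulli draw of a planted-module incidence block."""
    n_sp, n_st = len(sp_mod), len(st_mod)
    het = degree_heterogeneity
    w = rng.lognormal(0, het, n_sp) if het else np.ones(n_sp)
    v = rng.lognormal(0, het, n_st) if het else np.ones(n_st)
    base = np.where(np.asarray(sp_mod)[:, None] == np.asarray(st_mod)[None, :],
                    p_in, p_out)
    prob = np.clip(base * w[:, None] * v[None, :], 0, 1)
    cells = (rng.random((n_sp, n_st)) < prob).astype(np.int8)
    # one resampling pass for empty rows/columns; leftovers are dropped later
    empty_r = cells.sum(axis=1) == 0
    cells[empty_r] = (rng.random((int(empty_r.sum()), n_st)) < prob[empty_r])
    empty_c = cells.sum(axis=0) == 0
    cells[:, empty_c] = (rng.random((n_sp, int(empty_c.sum()))) < prob[:, empty_c])
    return cells


def gen_planted_incidence(K: int = 4, species_per_module: int = 15,
                          sites_per_module: int = 10, p_in: float = 0.7,
                          p_out: float = 0.1,
                          degree_heterogeneity: float = 0.0,
                          seed: int = 0, species_ids=None, site_ids=None,
                          site_modules=None):
    """Binary incidence matrix with K planted species+site modules.

    Cell (i, k) is 1 with probability ``p_in * w_i * v_k`` when species i
    and site k share a planted module and ``p_out * w_i * v_k`` otherwise,
    with lognormal weights w, v (sigma = ``degree_heterogeneity``) clipped
    into [0, 1].  Species or sites left empty are resampled once, then
    dropped.  ``site_modules`` overrides the default contiguous-block site
    assignment (used to plant several assemblages over a shared site set).
    Returns (IncidenceMatrix, planted Partition over graph nodes).
    """
    if not 0 <= p_out <= p_in <= 1:
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    n_sp = K * species_per_module
    sp_mod = np.repeat(np.arange(K), species_per_module)
    if site_modules is None:
        st_mod = np.repeat(np.arange(K), sites_per_module)
    else:
        st_mod = np.asarray(site_modules, dtype=int)
        if st_mod.max() >= K:
            raise ValueError("site_modules refer to more than K modules")
    n_st = len(st_mod)
    cells = _planted_cells(sp_mod, st_mod, p_in, p_out,
                           degree_heterogeneity, rng)
    keep_r = cells.sum(axis=1) > 0
    keep_c = cells.sum(axis=0) > 0
    species = species_ids if species_ids is not None else [
        f"s{i:03d}" for i in range(n_sp)]
    sites = site_ids if site_ids is not None else [
        f"r{k:03d}" for k in range(n_st)]
    m = IncidenceMatrix([s for s, k in zip(species, keep_r) if k],
                        [t for t, k in zip(sites, keep_c) if k],
                        cells[np.ix_(keep_r, keep_c)])
    assignment = {}
    for s, mod, k in zip(species, sp_mod, keep_r):
        if k:
            assignment[species_node(s)] = int(mod)
    for t, mod, k in zip(sites, st_mod, keep_c):
        if k:
            assignment[site_node(t)] = int(mod)
    return m, Partition(assignment)


@dataclass
class AssemblageSuite:
    """One full synthetic study: three assemblages plus attribute tables."""

    matrices: dict                 # status -> IncidenceMatrix
    partitions: dict               # status -> planted Partition
    families: "pd.Series | None" = None   # species -> family (all assemblages)
    family_table: object = None    # fingerprints.FamilyTable
    distances: object = None       # phylo.DistanceMatrix (native species)
    habitat: pd.DataFrame | None = None   # site -> descriptors
    site_modules: dict = field(default_factory=dict)  # status -> site->module
    seed: int = 0


# occupancy probability inside vs outside the planted module for the three
# residence-time layers; chosen so the weakest layer is still detectably
# structured at the default 60x40 scale while the ordering of the
# standardized modularity (weak < moderate < strong) stays well separated
SUITE_STRENGTH = {"neophyte": (0.55, 0.15), "archaeophyte": (0.50, 0.0833),
                  "native": (0.55, 0.0275)}
SUITE_K = {"neophyte": 6, "archaeophyte": 6, "native": 4}


def gen_assemblage_suite(seed: int = 0, n_species: int = 60, n_sites: int = 40,
                         n_families: int = 12,
                         degree_heterogeneity: float = 0.3) -> AssemblageSuite:
    """Synthetic counterpart of the three-assemblage study design.

    Assemblage module strength (p_in/p_out ratio) increases with residence
    time: neophyte 2, archaeophyte 5, native 20.  Family composition
    concentrates within modules as assemblages age (Dirichlet-multinomial
    with decreasing concentration), genetic distances cluster within native
    modules, and the habitat table separates native site modules on January
    temperature, longitude and establishment year, weakly for younger
    layers.
    """
    from .fingerprints import FamilyTable
    from .phylo import DistanceMatrix

    rng = np.random.default_rng(seed)
    matrices, partitions, site_modules = {}, {}, {}
    fam_names = [f"fam{j:02d}" for j in range(n_families)]
    shared_sites = [f"r{k:03d}" for k in range(n_sites)]
    species_fam = {}
    # family "base" popularity shared across assemblages
    base_pop = rng.dirichlet(np.full(n_families, 4.0))
    # Dirichlet concentration of per-module family composition around the
    # shared base popularity: high = modules look like random draws from the
    # pool (young layers), low = spiky module-specific compositions (natives)
    concentration = {"neophyte": 20.0, "archaeophyte": 2.0, "native": 0.1}
    for status in ("neophyte", "archaeophyte", "native"):
        K = SUITE_K[status]
        p_in, p_out = SUITE_STRENGTH[status]
        spm = max(2, n_species // K)
        # one shared site set across layers: contiguous blocks per layer,
        # so site modules of different layers overlap spatially
        st_mod = (np.arange(n_sites) * K) // n_sites
        pref = status[:3]
        m, part = gen_planted_incidence(
            K=K, species_per_module=spm,
            p_in=p_in, p_out=p_out,
            degree_heterogeneity=degree_heterogeneity,
            seed=int(rng.integers(0, 2**31 - 1)),
            species_ids=[f"{pref}_s{i:03d}" for i in range(K * spm)],
            site_ids=shared_sites, site_modules=st_mod)
        matrices[status] = m
        partitions[status] = part
        site_modules[status] = {
            t: part.assignment[site_node(t)] for t in m.site_ids}
        # family labels: per-module Dirichlet-multinomial around base_pop
        for mod in range(K):
            members = [s for s in m.species_ids
                       if part.assignment[species_node(s)] == mod]
            probs = rng.dirichlet(base_pop * concentration[status] * n_families)
            draws = rng.choice(n_families, size=len(members), p=probs)
            for s, f in zip(members, draws):
                species_fam[s] = fam_names[f]
    families = pd.Series(species_fam)
    family_table = FamilyTable.from_mapping(species_fam)

    # genetic distances for natives: within-module clustering
    nat = matrices["native"]
    nat_part = partitions["native"]
    taxa = list(nat.species_ids)
    mods = np.array([nat_part.assignment[species_node(s)] for s in taxa])
    n = len(taxa)
    within = rng.uniform(0.01, 0.06, (n, n))
    between = rng.uniform(0.08, 0.16, (n, n))
    same = mods[:, None] == mods[None, :]
    d = np.where(same, within, between)
    d = np.triu(d, 1)
    d = d + d.T
    distances = DistanceMatrix(taxa, d)

    # habitat table: one row per shared site; native site modules drive the
    # descriptor means strongly, younger layers only weakly
    strength = {"neophyte": 0.2, "archaeophyte": 0.45, "native": 1.0}
    rows = []
    for t in shared_sites:
        row = {"site": t,
               "temp_january": -3.0 + rng.normal(0, 0.6),
               "longitude": 14.0 + rng.normal(0, 0.4),
               "year_established": 1960.0 + rng.normal(0, 8),
               "latitude": 49.5 + rng.normal(0, 0.4),
               "log_area": 2.0 + rng.normal(0, 0.7),
               "habitat_types": max(1, int(rng.poisson(4))),
               "human_density": rng.lognormal(4, 0.5)}
        for status in ("neophyte", "archaeophyte", "native"):
            mod = site_modules[status].get(t)
            if mod is None:
                continue
            s = strength[status]
            row["temp_january"] += s * (mod - (SUITE_K[status] - 1) / 2) * 2.0
            row["longitude"] += s * (mod % 2) * 1.6
            row["year_established"] += s * (mod // 2) * 25.0
        rows.append(row)
    habitat = pd.DataFrame(rows).set_index("site")

    return AssemblageSuite(matrices=matrices, partitions=partitions,
                           families=families, family_table=family_table,
                           distances=distances, habitat=habitat,
                           site_modules=site_modules, seed=seed)


# ---------------------------------------------------------------------------
# exact-margin matrices

def gen_null_matrix(row_sums, col_sums, seed: int = 0) -> IncidenceMatrix:
    """A random binary matrix with exactly the given margins.

    Feasibility is checked by the Gale–Ryser condition; construction fills
    greedily (largest column demand first) and then shuffles with
    margin-preserving checkerboard swaps.
    """
    from .nulls import randomize_swap

    r = np.asarray(row_sums, dtype=int)
    c = np.asarray(col_sums, dtype=int)
    if r.sum() != c.sum():
        raise ValueError(
            f"margin totals differ: sum(rows)={r.sum()} != sum(cols)={c.sum()}")
    if np.any(r < 0) or np.any(c < 0) or np.any(r > len(c)) or np.any(c > len(r)):
        raise ValueError("margins out of range")
    # Gale–Ryser: sum of the k largest row sums <= sum_j min(c_j, k)
    r_sorted = np.sort(r)[::-1]
    for k in range(1, len(r) + 1):
        lhs = int(r_sorted[:k].sum())
        rhs = int(np.minimum(c, k).sum())
        if lhs > rhs:
            raise ValueError(
                f"infeasible margins (Gale–Ryser fails at k={k}: "
                f"{lhs} > {rhs})")
    cells = np.zeros((len(r), len(c)), dtype=np.int8)
    remaining = r.copy()
    for j in np.argsort(-c):
        rows = np.argsort(-remaining)[:c[j]]
        cells[rows, j] = 1
        remaining[rows] -= 1
    if np.any(remaining != 0):
        raise RuntimeError("constructive fill failed despite feasible margins")
    m = IncidenceMatrix([f"s{i}" for i in range(len(r))],
                        [f"r{j}" for j in range(len(c))], cells)
    if cells.all() or cells.shape[0] < 2 or cells.shape[1] < 2:
        return m
    return randomize_swap(m, seed=seed)
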