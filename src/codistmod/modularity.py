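"""Newman–Girvan modularity, simulated-annealing maximization, exhaustive
small-graph oracle, and functional-cartography node roles.

Species and sites are both treated as nodes of one undirected graph; a
partition assigns every node to exactly one module.  Modularity is

    M = sum_s [ l_s / L - (d_s / 2L)^2 ]

where ``l_s`` counts edges inside module ``s``, ``d_s`` is the summed degree
of its members, and ``L`` the total edge count.  The all-in-one partition
scores exactly 0; M is invariant under module relabelling.

Node roles within a given partition:

* within-module degree ``z_i`` — the z-score of the number of links node i
  has into its own module, relative to its module mates (population SD;
  a zero SD yields z = 0);
* participation coefficient ``P_i = 1 - sum_s (kappa_is / k_i)^2`` — 0 when
  all links stay in the node's own module, approaching 1 - 1/K when links
  spread evenly over K modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._sa_kernel import anneal_kernel, exhaustive_kernel, modularity_value


class PartitionCoverageError(ValueError):
    """A node of the graph is missing from the partition."""


@dataclass
class Partition:
    """Node → module assignment (non-overlapping, non-predefined)."""

    assignment: dict

    def compact(self) -> "Partition":
        """Relabel modules to contiguous ids 0..K-1 (order of first use)."""
        remap = {}
        out = {}
        for node, mod in self.assignment.items():
            if mod not in remap:
                remap[mod] = len(remap)
            out[node] = remap[mod]
        return Partition(out)

    @property
    def K(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict:
        """module id → set of nodes."""
        out = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"node": list(self.assignment), "module": list(self.assignment.values())}
        ).to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "Partition":
        df = pd.read_csv(path, encoding="utf-8")
        return cls(dict(zip(df["node"].astype(str), df["module"].astype(int))))


@dataclass
class SAParams:
    """Annealing schedule for the modularity maximizer.

    ``T0`` defaults to 1/(2n) when left as None; each temperature stage
    proposes ``f * n**2`` single-node and ``f * n`` collective (merge/split)
    moves; cooling is multiplicative; the run halts after ``stop_stall``
    stages without improving the best partition.
    """

    T0: float | None = None
    cooling: float = 0.995
    moves_factor: float = 1.0
    stop_stall: int = 10
    max_stages: int = 3000
    restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0,1)")
        if self.moves_factor < 0.1:
            raise ValueError("moves_factor must be >= 0.1")


@dataclass
class ModularityResult:
    M: float
    partition: Partition
    roles: pd.DataFrame | None = None
    sa_trace: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "M": self.M,
            "K": self.partition.K,
            "assignment": self.partition.assignment,
            "sa_trace": self.sa_trace,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# CSR plumbing

def _graph_to_csr(g: nx.Graph):
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v in nodes:
        indptr[index[v] + 1] = g.degree(v)
    indptr = np.cumsum(indptr)
    indices = np.empty(indptr[-1], dtype=np.int64)
    fill = indptr[:-1].copy()
    for u, v in g.edges():
        iu, iv = index[u], index[v]
        indices[fill[iu]] = iv
        fill[iu] += 1
        indices[fill[iv]] = iu
        fill[iv] += 1
    return nodes, indptr, indices


def _labels_from_partition(nodes, p: Partition) -> np.ndarray:
    missing = [v for v in nodes if v not in p.assignment]
    if missing:
        raise PartitionCoverageError(f"nodes not covered by partition: {missing[:5]}")
    compacted = p.compact().assignment
    return np.array([compacted[v] for v in nodes], dtype=np.int64)


# ---------------------------------------------------------------------------
# modularity and optimizers

def modularity(g: nx.Graph, p: Partition) -> float:
    """Evaluate M for an explicit partition of ``g``."""
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges; modularity undefined")
    nodes, indptr, indices = _graph_to_csr(g)
    labels = _labels_from_partition(nodes, p)
    return float(modularity_value(indptr, indices, labels, g.number_of_edges()))


def exhaustive_best_partition(g: nx.Graph, max_nodes: int = 12) -> ModularityResult:
    """Test oracle: global optimum over every set partition of the nodes.

    Enumerates restricted-growth strings, so only graphs with at most
    ``max_nodes`` nodes are accepted; ties keep the lexicographically first
    assignment (in graph node order).
    """
    n = g.number_of_nodes()
    if n > max_nodes:
        raise ValueError(f"{n} nodes exceed the enumeration limit {max_nodes}")
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    nodes, indptr, indices = _graph_to_csr(g)
    labels, best = exhaustive_kernel(indptr, indices, g.number_of_edges())
    part = Partition({v: int(l) for v, l in zip(nodes, labels)}).compact()
    return ModularityResult(M=float(best), partition=part)


def anneal(g: nx.Graph, params: SAParams | None = None) -> ModularityResult:
    """Stochastic modularity maximizer (simulated annealing).

    Runs ``params.restarts`` independent chains from the all-singletons
    start and keeps the best partition ever visited.  Identical seeds yield
    identical results.
    """
    if params is None:
        params = SAParams()
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes to anneal")
    L = g.number_of_edges()
    if L == 0:
        raise ValueError("graph has no edges")
    nodes, indptr, indices = _graph_to_csr(g)
    T0 = params.T0 if params.T0 is not None else 1.0 / (2.0 * n)
    labels0 = np.arange(n, dtype=np.int64)
    best_m = -np.inf
    best_labels = labels0
    stages = []
    for r in range(params.restarts):
        seed_r = (int(params.seed) * 1000003 + 7919 * r) % (2**31 - 1)
        lab, m, stage = anneal_kernel(
            indptr, indices, L, T0, params.cooling, params.moves_factor,
            params.stop_stall, params.max_stages, seed_r, labels0)
        stages.append(int(stage))
        if m > best_m + 1e-12:
            best_m = float(m)
            best_labels = lab
    part = Partition({v: int(l) for v, l in zip(nodes, best_labels)}).compact()
    res = ModularityResult(M=best_m, partition=part,
                           sa_trace={"stages": stages, "restarts": params.restarts,
                                     "T0": T0, "seed": params.seed})
    res.roles = node_roles(g, part)
    return res


# ---------------------------------------------------------------------------
# node roles

def within_module_degree(g: nx.Graph, p: Partition) -> dict:
    """z-score of each node's link count into its own module (population SD;
    degenerate modules — equal or single kappa — give z = 0)."""
    nodes, indptr, indices = _graph_to_csr(g)
    labels = _labels_from_partition(nodes, p)
    kappa = np.zeros(len(nodes))
    for i in range(len(nodes)):
        kappa[i] = np.sum(labels[indices[indptr[i]:indptr[i + 1]]] == labels[i])
    z = np.zeros(len(nodes))
    for mod in np.unique(labels):
        mask = labels == mod
        sd = kappa[mask].std()  # population convention
        if sd > 0:
            z[mask] = (kappa[mask] - kappa[mask].mean()) / sd
    return {v: float(zz) for v, zz in zip(nodes, z)}


def participation_coefficient(g: nx.Graph, p: Partition) -> dict:
    """P_i = 1 - sum_s (kappa_is / k_i)^2 over modules s."""
    nodes, indptr, indices = _graph_to_csr(g)
    labels = _labels_from_partition(nodes, p)
    out = {}
    for i, v in enumerate(nodes):
        k = indptr[i + 1] - indptr[i]
        if k == 0:
            raise ValueError(f"isolated node {v!r}: participation undefined")
        neigh = labels[indices[indptr[i]:indptr[i + 1]]]
        counts = np.bincount(neigh)
        out[v] = float(1.0 - np.sum((counts / k) ** 2))
    return out


def node_roles(g: nx.Graph, p: Partition) -> pd.DataFrame:
    """Combined role table (z, P) indexed by node; isolated nodes get P=0."""
    z = within_module_degree(g, p)
    nodes, indptr, indices = _graph_to_csr(g)
    labels = _labels_from_partition(nodes, p)
    P = {}
    for i, v in enumerate(nodes):
        k = indptr[i + 1] - indptr[i]
        if k == 0:
            P[v] = 0.0
            continue
        counts = np.bincount(labels[indices[indptr[i]:indptr[i + 1]]])
        P[v] = float(1.0 - np.sum((counts / k) ** 2))
    df = pd.DataFrame({"z": pd.Series(z), "P": pd.Series(P)})
    df["module"] = pd.Series(p.assignment)
    return df
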