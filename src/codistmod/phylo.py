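"""Pairwise genetic distances and within- vs between-module divergence tests.

Distances are expressed as substitutions per site.  Two classical distance
estimators over an alignment are provided — the raw proportion of differing
sites (p-distance) and the Kimura two-parameter correction — both with
pairwise deletion of gapped/ambiguous positions.  Model-based distances
computed elsewhere can be supplied as a square CSV matrix instead.

The divergence question: are species pairs drawn from two different modules
genetically farther apart than pairs within those modules?  For a module
pair (s, t) the within-s and within-t pairwise distances are pooled into a
"within" group and compared against the between-(s,t) pairs with a
Kruskal–Wallis rank test (tie-corrected).  Pairwise distances are not
independent observations; the p-values are therefore heuristic — the usual
caveat for this style of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

class SaturationError(ValueError):
    """Substitution proportions exceed the model's valid range."""


class MissingDistanceError(ValueError):
    """A pair of sequences shares no comparable positions."""


@dataclass
class DistanceMatrix:
    taxa: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a, b) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.taxa,
                     columns=self.taxa).to_csv(path, encoding="utf-8")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
        return cls([str(t) for t in df.index], df.to_numpy())


def read_alignment(path) -> dict:
    """FASTA alignment → {name: sequence}; all sequences must align."""
    from Bio import SeqIO
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 taxa")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return seqs


def _pair_arrays(s1: str, s2: str):
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    valid = np.frombuffer(b"ACGT", dtype=np.uint8)
    ok = np.isin(a, valid) & np.isin(b, valid)   # pairwise deletion
    return a[ok], b[ok]


def p_distance(aln: dict) -> DistanceMatrix:
    """Proportion of differing sites over pairwise-complete positions."""
    taxa = list(aln)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = _pair_arrays(aln[taxa[i]], aln[taxa[j]])
        if a.size == 0:
            raise MissingDistanceError(
                f"no comparable positions between {taxa[i]} and {taxa[j]}")
        d[i, j] = d[j, i] = np.mean(a != b)
    return DistanceMatrix(taxa, d)


def k2p_distance(aln: dict) -> DistanceMatrix:
    """Kimura two-parameter distance with pairwise deletion.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P/Q the transition and
    transversion proportions.  Saturated pairs (log argument <= 0) raise.
    """
    taxa = list(aln)
    n = len(taxa)
    d = np.zeros((n, n))
    purine = np.frombuffer(b"AG", dtype=np.uint8)
    for i, j in combinations(range(n), 2):
        a, b = _pair_arrays(aln[taxa[i]], aln[taxa[j]])
        if a.size == 0:
            raise MissingDistanceError(
                f"no comparable positions between {taxa[i]} and {taxa[j]}")
        diff = a != b
        same_class = np.isin(a, purine) == np.isin(b, purine)
        P = np.mean(diff & same_class)     # transitions
        Q = np.mean(diff & ~same_class)    # transversions
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError(
                f"pair ({taxa[i]}, {taxa[j]}) saturated (P={P:.3f}, Q={Q:.3f})")
        d[i, j] = d[j, i] = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
    return DistanceMatrix(taxa, d)


def _pair_distances(d: DistanceMatrix, taxa_a, taxa_b=None):
    """Within-set (taxa_b None) or between-set pairwise distances."""
    idx = {t: i for i, t in enumerate(d.taxa)}
    if taxa_b is None:
        pairs = combinations([idx[t] for t in taxa_a], 2)
    else:
        pairs = ((idx[a], idx[b]) for a in taxa_a for b in taxa_b)
    return np.array([d.values[i, j] for i, j in pairs])


def within_between_test(d: DistanceMatrix, modules: dict, pair,
                        three_group: bool = False):
    """Kruskal–Wallis comparison of within- vs between-module distances.

    ``pair`` is a tuple (s, t) of module ids in ``modules`` (node→module).
    Default grouping pools within-s and within-t pairs against the
    between-pairs; ``three_group=True`` keeps within-s and within-t apart.
    Returns (H, p, direction) with direction "between greater" or
    "within greater" by mean rank.
    """
    s, t = pair
    taxa_s = [x for x, m in modules.items() if m == s and x in d.taxa]
    taxa_t = [x for x, m in modules.items() if m == t and x in d.taxa]
    if len(taxa_s) < 2 or len(taxa_t) < 2:
        raise ValueError(f"modules {pair} need >= 2 taxa each with distances")
    within_s = _pair_distances(d, taxa_s)
    within_t = _pair_distances(d, taxa_t)
    between = _pair_distances(d, taxa_s, taxa_t)
    groups = ([within_s, within_t, between] if three_group
              else [np.concatenate([within_s, within_t]), between])
    if any(len(gr) < 2 for gr in groups):
        raise ValueError("insufficient pairwise distances in a group")
    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0   # all distances tied; scipy would divide by zero
    else:
        h, p = stats.kruskal(*groups)
    ranks = stats.rankdata(np.concatenate(groups))
    n_within = sum(len(gr) for gr in groups[:-1])
    mean_within = ranks[:n_within].mean()
    mean_between = ranks[n_within:].mean()
    direction = ("between greater" if mean_between > mean_within
                 else "within greater")
    return float(h), float(p), direction


def all_pairs_test(d: DistanceMatrix, modules: dict,
                   three_group: bool = False) -> pd.DataFrame:
    """within_between_test over every module pair; pairs lacking data are
    reported with NaN statistics."""
    mods = sorted(set(modules.values()))
    rows = []
    for s, t in combinations(mods, 2):
        try:
            h, p, direction = within_between_test(d, modules, (s, t),
                                                  three_group=three_group)
        except ValueError:
            h, p, direction = np.nan, np.nan, "insufficient data"
        rows.append({"module_a": s, "module_b": t, "H": h, "p": p,
                     "direction": direction})
    return pd.DataFrame(rows)
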