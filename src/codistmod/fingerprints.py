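"""Family-composition fingerprints and the dimension-free KS distance.

Whether a module (or assemblage) over- or under-represents particular
taxonomic families is judged against random draws: 10,000 resamples of an
equal number of species, without replacement, from the surrounding pool.
A family whose observed count falls above/below the resampling percentile
envelope is flagged over-/under-represented; families present in the pool
but absent from the focal set are "absent", everything else "present".

The overall compositional difference between two species sets is the
two-sample Kolmogorov–Smirnov sup-distance between their cumulative
family-composition proportions, taken over a fixed family ordering
(descending species richness in the total assemblage, ties alphabetical).
Its dimension-free form

    D_F = D_KS * sqrt(n1 n2 / (n1 + n2))

is compared against the asymptotic critical coefficients
c(alpha) = sqrt(-ln(alpha/2)/2); c(0.05) = 1.36 to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: significance levels reported for D_F (three line weights of the module
#: comparison diagrams)
DF_ALPHAS = (0.05, 0.01, 0.001)


def ks_critical(alpha: float) -> float:
    """Asymptotic two-sample KS critical coefficient c(alpha)."""
    return float(np.sqrt(-np.log(alpha / 2.0) / 2.0))


@dataclass
class FamilyTable:
    """species → family mapping with a fixed comparison ordering.

    ``ordering`` lists families by descending species count in the total
    assemblage (ties alphabetical); every fingerprint and KS comparison
    uses this one shared permutation.
    """

    species_to_family: dict
    ordering: list

    @classmethod
    def from_mapping(cls, species_to_family: dict) -> "FamilyTable":
        fams = pd.Series(list(species_to_family.values()))
        counts = fams.value_counts()
        ordering = sorted(counts.index, key=lambda f: (-counts[f], f))
        return cls(dict(species_to_family), ordering)

    @classmethod
    def from_csv(cls, path) -> "FamilyTable":
        df = pd.read_csv(path, encoding="utf-8", dtype=str)
        return cls.from_mapping(dict(zip(df["species"], df["family"])))

    def counts(self, species) -> np.ndarray:
        """Per-family species counts for a species set, in table order."""
        idx = {f: i for i, f in enumerate(self.ordering)}
        out = np.zeros(len(self.ordering), dtype=np.int64)
        for s in species:
            out[idx[self.species_to_family[s]]] += 1
        return out


@dataclass
class FingerprintResult:
    table: pd.DataFrame          # family, observed, CI_low, CI_high, status
    n_reps: int
    alpha: float
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, encoding="utf-8")


def resample_fingerprint(focal, pool, families: FamilyTable,
                         n_reps: int = 10000, alpha: float = 0.05,
                         seed: int = 0) -> FingerprintResult:
    """Over/under-representation fingerprint of ``focal`` within ``pool``.

    Draws ``n_reps`` random subsets of size |focal| from the pool without
    replacement and builds per-family percentile envelopes at
    (alpha/2, 1-alpha/2).
    """
    focal = list(focal)
    pool = list(pool)
    if not set(focal) <= set(pool):
        raise ValueError("focal species set must be contained in the pool")
    if len(focal) < 1:
        raise ValueError("focal set is empty")
    fam_idx = {f: i for i, f in enumerate(families.ordering)}
    pool_codes = np.array([fam_idx[families.species_to_family[s]] for s in pool])
    nfam = len(families.ordering)
    rng = np.random.default_rng(seed)
    nf = len(focal)
    # vectorized draws: random keys -> first nf of each permutation
    counts = np.empty((n_reps, nfam), dtype=np.int64)
    block = max(1, int(2e6 // max(1, len(pool))))
    for start in range(0, n_reps, block):
        b = min(block, n_reps - start)
        keys = rng.random((b, len(pool)))
        take = np.argpartition(keys, nf - 1, axis=1)[:, :nf]
        codes = pool_codes[take]
        for t in range(b):
            counts[start + t] = np.bincount(codes[t], minlength=nfam)
    lo = np.percentile(counts, 100 * alpha / 2, axis=0, method="midpoint")
    hi = np.percentile(counts, 100 * (1 - alpha / 2), axis=0, method="midpoint")
    obs = families.counts(focal)
    pool_counts = families.counts(pool)
    # absent (observed 0) takes precedence; otherwise envelope exceedance
    status = np.full(nfam, "present", dtype=object)
    status[obs > hi] = "over"
    status[(obs < lo) & (obs > 0)] = "under"
    status[obs == 0] = "absent"
    table = pd.DataFrame({
        "family": families.ordering, "observed": obs,
        "CI_low": lo, "CI_high": hi, "status": status,
        "pool_count": pool_counts,
    })
    return FingerprintResult(table=table, n_reps=n_reps, alpha=alpha, seed=seed)


def ks_distance(counts1, counts2, ordering=None) -> float:
    """Sup-difference of cumulative family-composition proportions.

    Both count vectors must already follow the same (fixed) family
    ordering; the result depends on that ordering, which is why a single
    shared permutation is used throughout an analysis.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("count vectors must share the family axis")
    n1, n2 = c1.sum(), c2.sum()
    if n1 < 1 or n2 < 1:
        raise ValueError("both species sets must be non-empty")
    return float(np.max(np.abs(np.cumsum(c1) / n1 - np.cumsum(c2) / n2)))


def df_statistic(counts1, counts2, ordering=None):
    """Dimension-free KS distance D_F and its significance levels.

    Returns ``(D_F, {alpha: significant})`` with D_F compared to
    c(alpha) = sqrt(-ln(alpha/2)/2) at alpha in 0.05/0.01/0.001.
    """
    d_ks = ks_distance(counts1, counts2, ordering)
    n1 = float(np.sum(counts1))
    n2 = float(np.sum(counts2))
    d_f = d_ks * np.sqrt(n1 * n2 / (n1 + n2))
    sig = {a: bool(d_f > ks_critical(a)) for a in DF_ALPHAS}
    return float(d_f), sig


def pairwise_df_matrix(module_species: dict, families: FamilyTable) -> pd.DataFrame:
    """D_F for every pair of modules (long form: module_a, module_b, D_F,
    and one significance column per alpha level)."""
    mods = sorted(module_species)
    rows = []
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            ca = families.counts(module_species[a])
            cb = families.counts(module_species[b])
            d_f, sig = df_statistic(ca, cb)
            row = {"module_a": a, "module_b": b, "D_F": d_f}
            row.update({f"sig_{al}": s for al, s in sig.items()})
            rows.append(row)
    return pd.DataFrame(rows)
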