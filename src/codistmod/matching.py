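"""Module correspondence across assemblages and ANOVA of node roles.

Modules detected independently for different assemblages (or for the
combined assemblage) are matched by Jaccard similarity of their node sets,
restricted to shared nodes, with an exact maximum-weight one-to-one
assignment; pairs with J >= 0.2 count as substantial overlap.

Node roles (within-module degree z and participation coefficient P) are
compared across assemblages and modules with a two-way fixed-effects ANOVA
(main effects only, type-II sums of squares for unbalanced designs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import linear_sum_assignment

#: threshold for calling two modules substantially similar
JACCARD_SUBSTANTIAL = 0.2


def jaccard(A, B) -> float:
    """|A ∩ B| / |A ∪ B|."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(A & B) / len(union)


def match_modules(pA, pB, node_universe=None,
                  threshold: float = JACCARD_SUBSTANTIAL):
    """Correspondence between the modules of two partitions.

    Returns ``(J, pairs)``: the full Jaccard matrix (DataFrame, modules of
    A × modules of B, computed on nodes shared by both partitions) and a
    DataFrame of the exact maximum-weight one-to-one assignment with a
    ``substantial`` flag at J >= ``threshold``.
    """
    shared = set(pA.assignment) & set(pB.assignment)
    if node_universe is not None:
        shared &= set(node_universe)
    if not shared:
        raise ValueError("partitions share no nodes")
    mods_a = {}
    mods_b = {}
    for v in shared:
        mods_a.setdefault(pA.assignment[v], set()).add(v)
        mods_b.setdefault(pB.assignment[v], set()).add(v)
    ka = sorted(mods_a)
    kb = sorted(mods_b)
    J = np.zeros((len(ka), len(kb)))
    for i, a in enumerate(ka):
        for j, b in enumerate(kb):
            J[i, j] = jaccard(mods_a[a], mods_b[b])
    rows, cols = linear_sum_assignment(-J)
    pairs = pd.DataFrame({
        "module_a": [ka[i] for i in rows],
        "module_b": [kb[j] for j in cols],
        "J": [J[i, j] for i, j in zip(rows, cols)],
    })
    pairs["substantial"] = pairs["J"] >= threshold
    return pd.DataFrame(J, index=ka, columns=kb), pairs


def role_anova(roles: pd.DataFrame) -> dict:
    """Two-way ANOVA of z and P with assemblage and module as factors.

    ``roles`` must have columns z, P, assemblage, module.  Returns
    {"z": table, "P": table} of type-II ANOVA tables (F, p per factor).
    """
    for col in ("z", "P", "assemblage", "module"):
        if col not in roles.columns:
            raise ValueError(f"roles table lacks column {col!r}")
    for factor in ("assemblage", "module"):
        if roles[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    out = {}
    df = roles.copy()
    df["assemblage"] = df["assemblage"].astype(str)
    df["module"] = df["module"].astype(str)
    for response in ("z", "P"):
        if np.ptp(df[response].to_numpy()) == 0:
            # constant response: no variance to partition
            out[response] = pd.DataFrame(
                {"sum_sq": [0.0, 0.0, 0.0],
                 "df": [np.nan] * 3, "F": [0.0, 0.0, np.nan],
                 "PR(>F)": [1.0, 1.0, np.nan]},
                index=["C(assemblage)", "C(module)", "Residual"])
            continue
        model = smf.ols(f"{response} ~ C(assemblage) + C(module)", data=df).fit()
        out[response] = sm.stats.anova_lm(model, typ=2)
    return out
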