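"""End-to-end orchestration of the co-distribution modularity analysis.

The canonical sequence, on real or synthetic data:

1. split the species pool into residence-time assemblages
   (neophyte / archaeophyte / native);
2. standardized modularity (M_Z against a degree-constrained null) per
   assemblage and for the combined assemblage;
3. module correspondence (Jaccard matrix + one-to-one matching) between
   the combined-assemblage modules and each separate assemblage;
4. family-composition fingerprints and pairwise D_F between modules;
5. within- vs between-module phylogenetic divergence tests;
6. habitat stage: VIF pruning, outlier screening, Wilks' lambda MANOVA and
   a pruned classification tree per assemblage;
7. the residence-time trend: Spearman rank correlation of M_Z across
   (null pseudo-assemblage, neophyte, archaeophyte, native).

Every stochastic stage consumes an explicit seed derived from the single
top-level seed; the report bundle records them all, so a rerun with the
same configuration reproduces every number.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .incidence import merge_matrices
from .modularity import SAParams
from .nulls import Z_CRITICAL, mz_report, randomize_swap
from .fingerprints import resample_fingerprint, pairwise_df_matrix
from .phylo import all_pairs_test
from .matching import match_modules
from .habitat import (cart_fit, mahalanobis_outliers, vif_prune, wilks_manova)

logger = logging.getLogger(__name__)

ASSEMBLAGE_ORDER = ("neophyte", "archaeophyte", "native")

DEFAULT_CONFIG = {
    "n_reps": 1000,           # null-ensemble size
    "n_resamples": 10000,     # fingerprint resampling draws
    "cp": 0.02,               # tree pruning complexity
    "vif_threshold": 2.0,
    "jaccard_threshold": 0.2,
    "alpha": 0.05,
    "outlier_alpha": 0.001,
    "sa_restarts": 5,
    "null_method": "swap",
}


def spearman_trend(mz_values):
    """Spearman rho of M_Z against residence-time rank, with exact
    one-sided upper p for n <= 8 (permutation enumeration)."""
    vals = np.asarray(mz_values, dtype=float)
    n = len(vals)
    if n < 3:
        raise ValueError("trend needs at least 3 values")
    ranks = np.arange(1, n + 1)
    rho = stats.spearmanr(ranks, vals).statistic
    if n <= 8:
        val_ranks = stats.rankdata(vals)
        count = 0
        total = 0
        for perm in itertools.permutations(val_ranks):
            r = stats.spearmanr(ranks, perm).statistic
            count += r >= rho - 1e-12
            total += 1
        p = count / total
    else:
        p = stats.spearmanr(ranks, vals, alternative="greater").pvalue
    return float(rho), float(p)


def _seed_stream(seed: int):
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, 2**31 - 1))


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full analysis; returns (and optionally writes) the
    report bundle.

    ``config`` must contain an integer ``seed`` and either
    ``synthetic: {...}`` (forwarded to the assemblage-suite generator) or
    input paths (``incidence``, ``species_attrs``, optionally
    ``distances``, ``habitat``).  Stage constants default to the reference
    values (1,000 null replicates, 10,000 resamples, cp=0.02, VIF<2,
    J>=0.2).
    """
    cfg = {**DEFAULT_CONFIG, **config}
    if "seed" not in cfg:
        raise ValueError("config must name an explicit seed")
    seeds = _seed_stream(int(cfg["seed"]))
    bundle = {"config": {k: v for k, v in cfg.items()
                         if isinstance(v, (int, float, str, bool))}}
    sa = SAParams(restarts=int(cfg["sa_restarts"]), seed=next(seeds))

    # ---- stage 0: inputs
    if "synthetic" in cfg:
        from .synth import gen_assemblage_suite
        synth_cfg = dict(cfg["synthetic"] or {})
        synth_cfg.setdefault("seed", next(seeds))
        suite = gen_assemblage_suite(**synth_cfg)
        matrices = suite.matrices
        family_table = suite.family_table
        distances = suite.distances
        habitat = suite.habitat
    else:
        from .incidence import load_incidence, load_species_attrs, split_by_status
        from .fingerprints import FamilyTable
        from .phylo import DistanceMatrix
        from .habitat import load_habitat_table
        m = load_incidence(cfg["incidence"], format=cfg.get("format", "wide"))
        attrs = load_species_attrs(cfg["species_attrs"])
        aset = split_by_status(m, attrs["status"].to_dict())
        matrices = aset.matrices
        family_table = (FamilyTable.from_mapping(attrs["family"].to_dict())
                        if "family" in attrs.columns else None)
        distances = (DistanceMatrix.from_csv(cfg["distances"])
                     if cfg.get("distances") else None)
        habitat = (load_habitat_table(cfg["habitat"])
                   if cfg.get("habitat") else None)

    # ---- stage 1: per-assemblage and combined standardized modularity
    reports = {}
    for status in ASSEMBLAGE_ORDER:
        reports[status] = mz_report(matrices[status], sa=sa,
                                    n_reps=int(cfg["n_reps"]),
                                    method=cfg["null_method"],
                                    seed=next(seeds))
        logger.info("%s: M=%.3f K=%d M_Z=%.2f", status,
                    reports[status]["M"], reports[status]["K"],
                    reports[status]["M_Z"])
    combined = merge_matrices([matrices[s] for s in ASSEMBLAGE_ORDER])
    reports["combined"] = mz_report(combined, sa=sa,
                                    n_reps=int(cfg["n_reps"]),
                                    method=cfg["null_method"],
                                    seed=next(seeds))
    bundle["modularity"] = {
        k: {kk: v[kk] for kk in ("M", "K", "M_N", "SD_N", "M_Z", "p",
                                 "significant")}
        for k, v in reports.items()}

    # ---- stage 2: module correspondence vs the combined assemblage
    matching = {}
    for status in ASSEMBLAGE_ORDER:
        J, pairs = match_modules(reports["combined"]["partition"],
                                 reports[status]["partition"],
                                 threshold=float(cfg["jaccard_threshold"]))
        matching[status] = {"J": J, "pairs": pairs}
    bundle["matching"] = matching

    # ---- stage 3: composition fingerprints + pairwise D_F
    if family_table is not None:
        fingerprints = {}
        df_pairs = {}
        pool_all = [s for st in ASSEMBLAGE_ORDER
                    for s in matrices[st].species_ids]
        for status in ASSEMBLAGE_ORDER:
            m = matrices[status]
            fingerprints[status] = resample_fingerprint(
                m.species_ids, pool_all, family_table,
                n_reps=int(cfg["n_resamples"]), alpha=float(cfg["alpha"]),
                seed=next(seeds))
            # per detected module, within the assemblage pool
            part = reports[status]["partition"]
            module_species = {}
            for mod, nodes in part.modules().items():
                sp = [v[3:] for v in nodes if v.startswith("sp:")]
                if sp:
                    module_species[mod] = sp
            for mod, sp in module_species.items():
                fingerprints[f"{status}/module{mod}"] = resample_fingerprint(
                    sp, m.species_ids, family_table,
                    n_reps=int(cfg["n_resamples"]),
                    alpha=float(cfg["alpha"]), seed=next(seeds))
            df_pairs[status] = pairwise_df_matrix(module_species, family_table)
        bundle["fingerprints"] = fingerprints
        bundle["df_pairs"] = df_pairs

    # ---- stage 4: phylogenetic divergence (assemblages with coverage)
    if distances is not None:
        phylo = {}
        for status in ASSEMBLAGE_ORDER:
            part = reports[status]["partition"]
            modules = {v[3:]: mod for v, mod in part.assignment.items()
                       if v.startswith("sp:") and v[3:] in distances.taxa}
            if len(set(modules.values())) >= 2:
                phylo[status] = all_pairs_test(distances, modules)
        bundle["phylo"] = phylo

    # ---- stage 5: habitat differentiation per assemblage
    if habitat is not None:
        hab = {}
        retained, trace = vif_prune(habitat, threshold=float(cfg["vif_threshold"]))
        pruned = habitat[retained]
        outliers = mahalanobis_outliers(pruned, alpha=float(cfg["outlier_alpha"]))
        core = pruned.loc[~outliers["flagged"]]
        hab["vif_retained"] = retained
        hab["vif_trace"] = trace
        hab["outliers"] = outliers
        for status in ASSEMBLAGE_ORDER:
            part = reports[status]["partition"]
            site_mod = {v[3:]: mod for v, mod in part.assignment.items()
                        if v.startswith("st:")}
            rows = [t for t in core.index if t in site_mod]
            X = core.loc[rows]
            y = np.array([site_mod[t] for t in rows])
            entry = {}
            try:
                lam, F, df1, df2, p = wilks_manova(X, y)
                entry["wilks"] = {"lambda": lam, "F": F, "df1": df1,
                                  "df2": df2, "p": p}
            except ValueError as e:
                entry["wilks"] = {"error": str(e)}
            try:
                tree = cart_fit(X, y.astype(str), cp=float(cfg["cp"]),
                                seed=next(seeds))
                entry["tree"] = tree
                entry["misclassification"] = tree.misclassification
                entry["baseline"] = tree.baseline
            except ValueError as e:
                entry["tree_error"] = str(e)
            hab[status] = entry
        bundle["habitat"] = hab

    # ---- stage 6: the residence-time trend with a null pseudo-assemblage
    null_matrix = randomize_swap(matrices["neophyte"], seed=next(seeds))
    null_rep = mz_report(null_matrix, sa=sa, n_reps=int(cfg["n_reps"]),
                         method=cfg["null_method"], seed=next(seeds))
    mz_series = [null_rep["M_Z"]] + [reports[s]["M_Z"]
                                     for s in ASSEMBLAGE_ORDER]
    rho, p = spearman_trend(mz_series)
    bundle["trend"] = {
        "order": ("null",) + ASSEMBLAGE_ORDER,
        "M_Z": mz_series,
        "null_below_critical": bool(abs(null_rep["M_Z"]) < Z_CRITICAL),
        "rho": rho, "p": p,
    }

    if out_dir is not None:
        _write_bundle(bundle, reports, Path(out_dir))
    bundle["reports"] = reports
    return bundle


def _write_bundle(bundle, reports, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config": bundle["config"],
               "modularity": bundle["modularity"],
               "trend": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                         for k, v in bundle["trend"].items()}}
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, default=float)
    for status, rep in reports.items():
        rep["partition"].to_csv(out / f"partition_{status}.csv")
    for status, mt in bundle.get("matching", {}).items():
        mt["J"].to_csv(out / f"jaccard_{status}.csv")
        mt["pairs"].to_csv(out / f"matching_{status}.csv", index=False)
    for name, fp in bundle.get("fingerprints", {}).items():
        fp.to_csv(out / f"fingerprint_{name.replace('/', '_')}.csv")
    for status, df in bundle.get("df_pairs", {}).items():
        df.to_csv(out / f"df_pairs_{status}.csv", index=False)
    for status, df in bundle.get("phylo", {}).items():
        df.to_csv(out / f"phylo_{status}.csv", index=False)
    hab = bundle.get("habitat")
    if hab:
        hab["vif_trace"].to_csv(out / "vif_trace.csv", index=False)
        hab["outliers"].to_csv(out / "mahalanobis.csv")
        rows = []
        for status in ASSEMBLAGE_ORDER:
            entry = hab.get(status, {})
            if "misclassification" in entry:
                rows.append({"assemblage": status,
                             "misclassification": entry["misclassification"],
                             "baseline": entry["baseline"],
                             **{f"wilks_{k}": v for k, v in
                                entry.get("wilks", {}).items()}})
        pd.DataFrame(rows).to_csv(out / "habitat_summary.csv", index=False)
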