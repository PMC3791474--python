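# codistmod

Compartmentalization analysis of species-by-site co-distribution networks.

## The problem

When plant species are recorded across a network of nature reserves, the
resulting binary species-by-site matrix can be read as a bipartite network:
species and reserves are nodes, and each recorded presence is an edge.  A
central question in invasion ecology is whether assemblages that have been
in a region longer are more *compartmentalized* — partitioned into modules
of species and reserves that co-occur more than expected — than recently
introduced assemblages.  Splitting a regional flora by residence time
(neophytes, introduced after 1500 AD; archaeophytes, introduced between the
Neolithic and 1500 AD; natives) turns this into a space-for-time
comparison along the introduction–naturalization–invasion continuum.

`codistmod` implements the full analysis for this question:

* **Modularity** `M = Σ_s [l_s/L − (d_s/2L)²]` of a joint species+site
  partition (`l_s` edges inside module *s*, `d_s` its total degree, `L` all
  presences), maximized by simulated annealing with single-node and
  collective merge/split moves, plus an exhaustive-enumeration oracle for
  small graphs.
* **Standardized modularity** `M_Z = (M − M_N)/SD_N` against ensembles of
  degree-constrained random matrices (exact margin-preserving curveball
  swaps, or a proportional alternative), with the 1.96 normal critical
  value for significance.
* **Node roles**: within-module degree `z` and participation coefficient
  `P = 1 − Σ_s (κ_is/k_i)²`, with a two-way ANOVA of roles across
  assemblages and modules.
* A **Lotka–Volterra meta-community simulator** (site-wise competition plus
  diffusive dispersal) that tracks the incidence matrix and its `M_Z`
  through time, for the full assemblage and a fixed 50% species subset.
* **Module comparison statistics**: resampling fingerprints of family
  composition (10,000 draws without replacement), the dimension-free KS
  distance `D_F = D_KS·√(n₁n₂/(n₁+n₂))` with critical value 1.36 at 5%,
  Kruskal–Wallis within- vs between-module genetic divergence tests, and a
  habitat stage (VIF pruning to < 2, Mahalanobis outlier screening, Wilks'
  λ MANOVA, and an rpart-convention cost-complexity-pruned classification
  tree at cp = 0.02).
* A **synthetic-data module** generating planted-module incidence
  matrices, a three-assemblage suite of increasing module strength, exact
  margin matrices, family/distance/habitat tables — every input the
  pipeline needs.

## Worked example

```python
from codistmod.synth import gen_assemblage_suite
from codistmod.nulls import mz_report
from codistmod.modularity import SAParams
from codistmod.pipeline import spearman_trend

suite = gen_assemblage_suite(seed=1)
mz = {}
for status in ("neophyte", "archaeophyte", "native"):
    rep = mz_report(suite.matrices[status],
                    sa=SAParams(seed=2, restarts=3), n_reps=25, seed=3)
    mz[status] = rep["M_Z"]
    print(f"{status:13s} M={rep['M']:.3f}  K={rep['K']}  M_Z={rep['M_Z']:.2f}")
```

prints (seed 1):

```
neophyte      M=0.273  K=5  M_Z=5.28
archaeophyte  M=0.368  K=5  M_Z=10.01
native        M=0.647  K=4  M_Z=54.31
```

`M` is the annealed modularity of the assemblage, `K` the number of
detected modules, and `M_Z` how many null standard deviations the observed
modularity sits above random matrices with the same degrees: the young
neophyte layer is weakly but detectably structured, while the native layer
is dozens of standard deviations above its null — the residence-time
ordering the method is designed to expose.  With more null replicates (the
default is 1,000) the `M_Z` estimates tighten and the full pipeline
(`codistmod run --seed 1 --out results/`) reports the Spearman trend
across (null, neophyte, archaeophyte, native), which is ρ = 1.0 for this
ordering.

The same stages are available from the shell:
`codistmod modularity|null|simulate|fingerprint|phylo|habitat|match|synth|run`.

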