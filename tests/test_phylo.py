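import numpy as np
import pytest
from scipy import stats

from codistmod.phylo import (
    DistanceMatrix, MissingDistanceError, SaturationError, all_pairs_test,
    k2p_distance, p_distance, read_alignment, within_between_test,
)


class TestPDistance:
    def test_identical_sequences_zero(self):
        d = p_distance({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert d.get("a", "b") == 0.0

    def test_one_difference_in_four(self):
        d = p_distance({"a": "ACGT", "b": "ACGA"})
        assert d.get("a", "b") == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        d = p_distance({"a": "AC-T", "b": "ACGT"})
        assert d.get("a", "b") == pytest.approx(0.0)  # 3 compared sites

    def test_ambiguity_sites_removed(self):
        d = p_distance({"a": "ACNT", "b": "ACGA"})
        # compared sites: A/A, C/C, T/A -> 1/3
        assert d.get("a", "b") == pytest.approx(1 / 3)

    def test_no_shared_positions_raises(self):
        with pytest.raises(MissingDistanceError):
            p_distance({"a": "--AA", "b": "CC--"})


class TestK2P:
    def test_identical_zero(self):
        d = k2p_distance({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        assert d.get("a", "b") == 0.0

    def test_pure_transition_formula(self):
        # 2 transitions in 20 sites: P=0.1, Q=0 -> -0.5*ln(0.8)
        s1 = "A" * 20
        s2 = "G" * 2 + "A" * 18
        d = k2p_distance({"a": s1, "b": s2})
        assert d.get("a", "b") == pytest.approx(-0.5 * np.log(0.8), abs=1e-9)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance({"a": "ACAC" * 5, "b": "CACA" * 5})

    def test_k2p_at_least_p_distance(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        s1 = "".join(rng.choice(bases, 200))
        s2 = "".join(c if rng.random() > 0.1 else
                     rng.choice(bases) for c in s1)
        aln = {"a": s1, "b": s2}
        assert k2p_distance(aln).get("a", "b") >= p_distance(aln).get("a", "b")


class TestDistanceMatrix:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))

    def test_csv_round_trip(self, tmp_path):
        vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]])
        d = DistanceMatrix(["x", "y", "z"], vals)
        d.to_csv(tmp_path / "d.csv")
        back = DistanceMatrix.from_csv(tmp_path / "d.csv")
        assert back.taxa == d.taxa
        assert np.allclose(back.values, d.values)


def _module_distance_matrix(rng, n_per_module, within_range, between_range):
    taxa = [f"t{i}" for i in range(2 * n_per_module)]
    modules = {t: (0 if i < n_per_module else 1) for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = modules[taxa[i]] == modules[taxa[j]]
            lo, hi = within_range if same else between_range
            d[i, j] = d[j, i] = rng.uniform(lo, hi)
    return DistanceMatrix(taxa, d), modules


class TestWithinBetween:
    def test_all_equal_distances_null(self):
        taxa = list("abcd")
        d = DistanceMatrix(taxa, np.full((4, 4), 0.1) - 0.1 * np.eye(4))
        modules = {"a": 0, "b": 0, "c": 1, "d": 1}
        h, p, _ = within_between_test(d, modules, (0, 1))
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_distances_detected(self):
        """Clearly larger between-module distances are flagged in nearly
        every replicate."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d, modules = _module_distance_matrix(
                rng, 10, (0.0, 0.1), (0.2, 0.3))
            h, p, direction = within_between_test(d, modules, (0, 1))
            hits += (p < 0.01) and direction == "between greater"
        assert hits >= 95

    def test_single_taxon_module_rejected(self):
        d = DistanceMatrix(list("abc"),
                           np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]))
        with pytest.raises(ValueError, match=">= 2 taxa"):
            within_between_test(d, {"a": 0, "b": 0, "c": 1}, (0, 1))

    def test_h_matches_brute_force_ranks(self):
        """For 2 groups, H equals the rank-sum formula computed by hand."""
        rng = np.random.default_rng(5)
        d, modules = _module_distance_matrix(rng, 3, (0.0, 0.2), (0.1, 0.3))
        h, p, _ = within_between_test(d, modules, (0, 1))
        # brute force: recompute H = (12/(N(N+1))) * sum n_i (Rbar_i-Rbar)^2
        taxa0 = [t for t, m in modules.items() if m == 0]
        taxa1 = [t for t, m in modules.items() if m == 1]
        from itertools import combinations
        within = [d.get(a, b) for g in (taxa0, taxa1)
                  for a, b in combinations(g, 2)]
        between = [d.get(a, b) for a in taxa0 for b in taxa1]
        allv = np.array(within + between)
        ranks = stats.rankdata(allv)
        N = len(allv)
        groups = [ranks[:len(within)], ranks[len(within):]]
        H = 12 / (N * (N + 1)) * sum(
            len(g) * (g.mean() - (N + 1) / 2) ** 2 for g in groups)
        # tie correction
        _, counts = np.unique(allv, return_counts=True)
        H /= 1 - np.sum(counts**3 - counts) / (N**3 - N)
        assert h == pytest.approx(H)

    def test_type_one_error_calibrated(self):
        """Exchangeable distances: rejection rate near alpha (the pairwise
        non-independence caveat keeps this a loose band)."""
        rejections = 0
        n_sim = 1000
        rng = np.random.default_rng(123)
        for _ in range(n_sim):
            n = 8
            taxa = [f"t{i}" for i in range(n)]
            vals = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            draws = rng.random(len(iu[0]))
            vals[iu] = draws
            vals = vals + vals.T
            d = DistanceMatrix(taxa, vals)
            modules = {t: (0 if i < 4 else 1) for i, t in enumerate(taxa)}
            _, p, _ = within_between_test(d, modules, (0, 1))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08


def test_all_pairs_reports_every_module_pair():
    rng = np.random.default_rng(1)
    d, modules = _module_distance_matrix(rng, 5, (0.0, 0.1), (0.2, 0.3))
    out = all_pairs_test(d, modules)
    assert len(out) == 1
    assert out.iloc[0]["direction"] == "between greater"


def test_read_alignment_rejects_ragged(tmp_path):
    p = tmp_path / "aln.fasta"
    p.write_text(">a\nACGT\n>b\nACG\n")
    with pytest.raises(ValueError, match="aligned"):
        read_alignment(p)
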