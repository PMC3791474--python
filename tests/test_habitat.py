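import numpy as np
import pandas as pd
import pytest

from codistmod.habitat import (
    cart_fit, mahalanobis_outliers, random_baseline_error, vif_prune,
    wilks_manova,
)


class TestVifPrune:
    def test_orthogonal_columns_untouched(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((60, 4)))
        t = pd.DataFrame(q, columns=list("abcd"))
        cols, trace = vif_prune(t)
        assert cols == list("abcd")
        assert trace.empty

    def test_duplicated_column_removed_first(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        t["dup"] = t["a"]
        cols, trace = vif_prune(t)
        assert len(cols) == 3
        assert trace.iloc[0]["VIF"] == np.inf
        assert trace.iloc[0]["removed"] in ("a", "dup")

    def test_near_collinear_triple_one_removal(self):
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal(80)
        x2 = rng.standard_normal(80)
        x3 = x1 + x2 + rng.normal(0, 0.1, 80)
        t = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        cols, trace = vif_prune(t, threshold=2.0)
        assert len(trace) == 1
        assert len(cols) == 2

    def test_terminates_with_all_vif_below_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((100, 3))
        # heavily collinear expansion
        t = pd.DataFrame(np.column_stack([
            base, base @ rng.standard_normal((3, 4)) +
            rng.normal(0, 0.2, (100, 4))]))
        t.columns = [f"v{i}" for i in range(7)]
        cols, trace = vif_prune(t, threshold=2.0)
        from codistmod.habitat import _vif
        X = t[cols].to_numpy()
        assert all(_vif(X, j) < 2.0 for j in range(len(cols)))
        assert len(trace) <= 6


class TestMahalanobis:
    def test_row_at_mean_zero(self):
        t = pd.DataFrame({"a": [0, 1, -1, 0.5, -0.5],
                          "b": [0, -1, 1, 0.5, -0.5]})
        res = mahalanobis_outliers(t, alpha=0.01)
        # first row equals the column means (both zero)
        assert res["D2"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 3))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        t1 = pd.DataFrame(X)
        t2 = pd.DataFrame(X @ A + np.array([5.0, -2.0, 1.0]))
        d1 = mahalanobis_outliers(t1)["D2"]
        d2 = mahalanobis_outliers(t2)["D2"]
        assert np.allclose(d1, d2)

    def test_flag_threshold_is_chi2_quantile(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.standard_normal((50, 4)))
        res = mahalanobis_outliers(t, alpha=0.001)
        assert res.attrs["cutoff"] == pytest.approx(
            stats.chi2.ppf(0.999, df=4))


class TestWilks:
    def test_two_group_single_variable_matches_t(self):
        from scipy import stats
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        y = np.array([0] * 20 + [1] * 20)
        x[y == 1] += 0.8
        lam, F, df1, df2, p = wilks_manova(pd.DataFrame({"v": x}), y)
        t, _ = stats.ttest_ind(x[y == 0], x[y == 1])
        assert lam == pytest.approx(1 / (1 + t**2 / (40 - 2)), abs=1e-6)

    def test_null_p_values_roughly_uniform(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(300):
            X = pd.DataFrame(rng.standard_normal((30, 3)))
            y = rng.integers(0, 2, 30)
            if min((y == 0).sum(), (y == 1).sum()) < 2:
                continue
            pvals.append(wilks_manova(X, y)[4])
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01

    def test_single_group_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)))
        with pytest.raises(ValueError, match="2 groups"):
            wilks_manova(X, np.zeros(10))


def _rpart_fixture_null():
    """Frozen fixture checked against rpart (prune at cp=0.02):
    4 leaves, resubstitution error 0.475."""
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"temp_january": rng.uniform(-6, 0, 80),
                      "longitude": rng.uniform(12, 18, 80)})
    y = rng.choice(list("abcd"), 80)
    return X, y


class TestCart:
    def test_separable_single_split(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"temp_january": rng.uniform(-6, 0, 80),
                          "longitude": rng.uniform(12, 18, 80)})
        y = np.where(X["temp_january"] < -3, "cold", "warm")
        rep = cart_fit(X, y, cp=0.02, seed=1)
        assert rep.misclassification == 0.0
        assert rep.n_leaves == 2

    def test_matches_rpart_on_random_labels(self):
        """Pruned size and error agree with the reference recursive
        partitioning implementation on a shared fixture."""
        X, y = _rpart_fixture_null()
        rep = cart_fit(X, y, cp=0.02, seed=0)
        # rpart: prune(rpart(y ~ .), cp=0.02) -> 4 leaves, error 0.475
        assert rep.misclassification == pytest.approx(0.475)

    def test_matches_rpart_on_structured_labels(self):
        rng = np.random.default_rng(0)
        rng.uniform(-6, 0, 80)  # consume the draws of the null fixture
        rng.uniform(12, 18, 80)
        rng.choice(list("abcd"), 80)
        mod = rng.integers(0, 4, 120)
        X = pd.DataFrame({
            "temp_january": -3 + mod * 1.0 + rng.normal(0, 0.8, 120),
            "longitude": 13 + (mod % 2) * 2 + rng.normal(0, 0.7, 120)})
        y = np.array([f"m{m}" for m in mod])
        rep = cart_fit(X, y, cp=0.02, seed=0)
        # rpart on the same table: 4 leaves, error 0.10
        assert rep.misclassification == pytest.approx(0.10)
        assert rep.misclassification < rep.baseline

    def test_pruning_monotonicity(self):
        X, y = _rpart_fixture_null()
        loose = cart_fit(X, y, cp=0.001, seed=0)
        tight = cart_fit(X, y, cp=0.02, seed=0)
        assert tight.misclassification >= loose.misclassification - 1e-12

    def test_synthetic_modules_beat_baseline(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mod = rng.integers(0, 4, 100)
            X = pd.DataFrame({
                "temp_january": -3 + (mod - 1.5) * 2 + rng.normal(0, 0.6, 100),
                "longitude": 14 + (mod % 2) * 1.6 + rng.normal(0, 0.4, 100)})
            y = mod.astype(str)
            rep = cart_fit(X, y, cp=0.02, seed=seed)
            hits += rep.misclassification < rep.baseline
        assert hits >= 19

    def test_constant_labels_trivial_tree(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="trivial"):
            rep = cart_fit(X, np.array(["x"] * 4), cp=0.02)
        assert rep.misclassification == 0.0

    def test_invalid_cp_rejected(self):
        X, y = _rpart_fixture_null()
        with pytest.raises(ValueError, match="cp"):
            cart_fit(X, y, cp=1.5)

    def test_tree_json_serialization(self, tmp_path):
        X, y = _rpart_fixture_null()
        rep = cart_fit(X, y, cp=0.02, seed=0)
        rep.to_json(tmp_path / "tree.json")
        import json
        payload = json.loads((tmp_path / "tree.json").read_text())
        assert payload["misclassification"] == pytest.approx(0.475)
        assert "tree" in payload


class TestBaseline:
    @pytest.mark.parametrize("K,expected", [(4, 0.75), (1, 0.0), (2, 0.5),
                                            (7, 6 / 7)])
    def test_uniform_assignment_error(self, K, expected):
        assert random_baseline_error(K) == pytest.approx(expected)

    def test_zero_modules_rejected(self):
        with pytest.raises(ValueError):
            random_baseline_error(0)
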