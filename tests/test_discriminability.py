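import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from b2t.discriminability import (
    GaussianStats,
    fit_lda,
    kl_divergence,
    mean_pairwise_kl,
    normalize_scores,
    select_features,
    shift_null_klmap,
)
from b2t.io_session import ValidationError

finite_mean = st.floats(-5.0, 5.0)
pos_var = st.floats(0.05, 20.0)


def mc_kl_natural(g0: GaussianStats, g1: GaussianStats, n: int, rng) -> tuple[float, float]:
    """Monte-Carlo estimate of KL(N0||N1) in nats with its standard error."""
    x = rng.normal(g0.mean[0], np.sqrt(g0.var[0]), size=n)
    log_ratio = (
        -0.5 * np.log(g0.var[0]) - (x - g0.mean[0]) ** 2 / (2 * g0.var[0])
        + 0.5 * np.log(g1.var[0]) + (x - g1.mean[0]) ** 2 / (2 * g1.var[0])
    )
    return float(log_ratio.mean()), float(log_ratio.std(ddof=1) / np.sqrt(n))


class TestKlDivergence:
    def test_identical_distributions_zero(self):
        g = GaussianStats(np.array([1.0, -2.0]), np.array([0.5, 3.0]))
        assert kl_divergence(g, g, "eq1_verbatim") == pytest.approx(0.0, abs=1e-12)
        assert kl_divergence(g, g, "natural") == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_equal_variance(self):
        g0 = GaussianStats([0.0], [1.0])
        g1 = GaussianStats([1.0], [1.0])
        # equal variances: determinant term vanishes in both modes
        assert kl_divergence(g0, g1, "eq1_verbatim") == pytest.approx(0.5)
        assert kl_divergence(g0, g1, "natural") == pytest.approx(0.5)

    def test_variance_ratio_mixed_base(self):
        g0 = GaussianStats([0.0], [1.0])
        g1 = GaussianStats([0.0], [2.0])
        # 0.5 * (0.5 + 0 - 1 - log2(1/2)) = 0.25 with the base-2 determinant term
        assert kl_divergence(g0, g1, "eq1_verbatim") == pytest.approx(0.25)
        expect_nat = 0.5 * (0.5 - 1.0 + np.log(2.0))
        assert kl_divergence(g0, g1, "natural") == pytest.approx(expect_nat)

    def test_natural_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            g0 = GaussianStats([rng.uniform(-2, 2)], [rng.uniform(0.3, 3.0)])
            g1 = GaussianStats([rng.uniform(-2, 2)], [rng.uniform(0.3, 3.0)])
            closed = kl_divergence(g0, g1, "natural")
            est, se = mc_kl_natural(g0, g1, 100_000, rng)
            assert abs(closed - est) < 3 * se + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            kl_divergence(GaussianStats([0.0], [1.0]), GaussianStats([0.0, 0.0], [1.0, 1.0]))

    @given(finite_mean, pos_var)
    def test_self_divergence_zero_property(self, mu, var):
        g = GaussianStats([mu], [var])
        assert kl_divergence(g, g, "eq1_verbatim") == pytest.approx(0.0, abs=1e-9)

    @given(finite_mean, pos_var, finite_mean, pos_var)
    def test_natural_variant_nonnegative(self, m0, v0, m1, v1):
        g0, g1 = GaussianStats([m0], [v0]), GaussianStats([m1], [v1])
        assert kl_divergence(g0, g1, "natural") >= -1e-12


class TestMeanPairwiseKl:
    def test_identical_sample_sets_zero(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"], dtype=object)
        assert mean_pairwise_kl(x, labels)[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_classes_unit_shift(self):
        # class stats exactly (0,1) and (1,1): both directions give 0.5
        x = np.array([-1.0, 1.0, 0.0, 2.0])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        assert mean_pairwise_kl(x, labels)[0] == pytest.approx(0.5)

    def test_three_classes_equals_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        labels = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20, dtype=object)
        got = mean_pairwise_kl(x, labels, mode="eq1_verbatim")[0]
        stats = {}
        for c in "abc":
            rows = x[labels == c]
            stats[c] = GaussianStats([rows.mean()], [rows.var()])
        pairs = [(a, b) for a in "abc" for b in "abc" if a != b]
        expect = np.mean([kl_divergence(stats[a], stats[b], "eq1_verbatim") for a, b in pairs])
        assert got == pytest.approx(expect, rel=1e-9)

    def test_class_ordering_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(90, 3))
        labels = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30, dtype=object)
        perm = rng.permutation(90)
        assert np.allclose(mean_pairwise_kl(x, labels), mean_pairwise_kl(x[perm], labels[perm]))

    def test_small_class_excluded_with_warning(self, caplog):
        x = np.concatenate([np.zeros(10), np.ones(10), [5.0]])
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"], dtype=object)
        with caplog.at_level("WARNING", logger="b2t.discriminability"):
            d = mean_pairwise_kl(x, labels)
        assert "c" in caplog.text
        assert np.isfinite(d).all()


class TestSelectFeatures:
    def test_last_steep_drop_rule(self):
        d_hat = np.array([1.0, 3.0, 2.9, 0.98, 0.97])  # sorted: 3.0 2.9 1.0 .98 .97
        sel = select_features(d_hat, threshold=-0.05)
        assert set(sel.tolist()) == {1, 2}

    def test_all_equal_uses_fallback_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="b2t.discriminability"):
            sel = select_features(np.ones(40), threshold=-0.05, fallback_frac=0.05)
        assert len(sel) == 2  # ceil(5% of 40)
        assert "falling back" in caplog.text

    def test_single_feature(self):
        assert select_features(np.array([2.0])).tolist() == [0]

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=60))
    def test_selection_is_prefix_of_ranking(self, scores):
        d_hat = np.asarray(scores)
        sel = select_features(d_hat)
        order = np.argsort(-d_hat, kind="stable")
        assert sel.tolist() == order[: len(sel)].tolist()

    def test_normalization_modes(self):
        d = np.array([1.0, 3.0])
        assert normalize_scores(d, "mean").mean() == pytest.approx(1.0)
        assert normalize_scores(d, "sum").sum() == pytest.approx(1.0)


class TestLda:
    def _separable(self, rng, d=2, n=200, gap=10.0):
        X0 = rng.normal(size=(n, d))
        X1 = rng.normal(size=(n, d)) + gap
        X = np.vstack([X0, X1])
        y = np.array(["a"] * n + ["b"] * n, dtype=object)
        return X, y

    def test_two_class_projection_separates(self):
        rng = np.random.default_rng(0)
        X, y = self._separable(rng)
        proj = fit_lda(X, y)
        assert proj.matrix.shape[1] == 1
        z = proj.transform(X)[:, 0]
        z0, z1 = z[:200], z[200:]
        pooled_sd = np.sqrt((z0.var() + z1.var()) / 2)
        assert abs(z0.mean() - z1.mean()) > 5 * pooled_sd

    def test_single_class_error(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        y = np.array(["a"] * 50, dtype=object)
        with pytest.raises(ValidationError):
            fit_lda(X, y)

    def test_refit_gaussians_after_projection_separable(self):
        rng = np.random.default_rng(2)
        X, y = self._separable(rng, d=4, gap=6.0)
        proj = fit_lda(X, y)
        z = proj.transform(X)
        m0, m1 = z[y == "a"].mean(axis=0), z[y == "b"].mean(axis=0)
        assert np.linalg.norm(m0 - m1) > 1.0

    def test_feature_reordering_equivalent_up_to_sign(self):
        rng = np.random.default_rng(3)
        X, y = self._separable(rng, d=3, gap=4.0)
        proj1 = fit_lda(X, y)
        perm = [2, 0, 1]
        proj2 = fit_lda(X[:, perm], y)
        z1 = proj1.transform(X)[:, 0]
        z2 = proj2.transform(X[:, perm])[:, 0]
        corr = np.corrcoef(z1, z2)[0, 1]
        assert abs(corr) > 0.999


class TestShiftNull:
    def test_single_shift_is_half_rotation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        labels = np.array((["a"] * 10 + ["b"] * 10) * 2, dtype=object)
        null, _ = shift_null_klmap(X, labels, n_shifts=1)
        manual = mean_pairwise_kl(np.roll(X, 20, axis=0), labels)
        assert np.allclose(null[0], manual)

    def test_noise_features_mostly_below_pooled_p99(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 40))
        labels = np.array([["a", "b", "c", "d"][i % 4] for i in range(400)], dtype=object)
        real = mean_pairwise_kl(X, labels)
        _, p99 = shift_null_klmap(X, labels, n_shifts=5)
        assert np.mean(real <= p99) >= 0.95

    def test_planted_effect_exceeds_null(self):
        rng = np.random.default_rng(2)
        n = 400
        labels = np.array([["a", "b", "c"][i % 3] for i in range(n)], dtype=object)
        X = rng.normal(size=(n, 10))
        shift_by_class = {"a": -3.0, "b": 0.0, "c": 3.0}
        X[:, 0] += [shift_by_class[l] for l in labels]
        real = mean_pairwise_kl(X, labels)
        _, p99 = shift_null_klmap(X, labels, n_shifts=3)
        assert real[0] > p99
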