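"""Unit and property tests for joint-mixture fitting and conditioning."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal, norm

from gmrdesign.errors import (
    DimensionError,
    FitError,
    StandardizationError,
    UndefinedMetricError,
)
from gmrdesign.gmr import (
    ConditionalMixture,
    JointGaussianMixture,
    condition,
    cross_validated_r2,
    fit_joint,
    inverse_estimate,
    point_estimate,
    predict_forward,
    regression_metrics,
    sample_conditional,
    select_hyperparameters,
    swap_blocks,
)

from conftest import identity_standardizer, manual_mixture


def random_spd(rng, d):
    a = rng.normal(size=(d, d))
    return a @ a.T + d * np.eye(d)


class TestFitJoint:
    def test_single_standard_normal_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5000, 2))
        y = rng.normal(size=(5000, 1))
        m = fit_joint(x, y, 1, seed=0)
        # standardized space: mean ~0, covariance ~identity
        assert np.allclose(m.means[0], 0.0, atol=0.1)
        assert np.allclose(m.covariances[0], np.eye(3), atol=0.1)

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(3)
        true_means = np.array([[-5.0, -5.0, -5.0], [5.0, 5.0, 5.0]])
        labels = rng.integers(0, 2, size=2000)
        z = true_means[labels] + rng.normal(size=(2000, 3))
        m = fit_joint(z[:, :2], z[:, 2:], 2, seed=0)
        # de-standardize fitted means and match to truth
        center = np.concatenate([m.x_standardizer.center, m.y_standardizer.center])
        scale = np.concatenate([m.x_standardizer.scale, m.y_standardizer.scale])
        fitted = m.means * scale + center
        cost = np.linalg.norm(fitted[:, None] - true_means[None], axis=2)
        r, c = linear_sum_assignment(cost)
        assert cost[r, c].max() < 0.2

    def test_too_few_samples_raises(self):
        with pytest.raises(FitError):
            fit_joint(np.zeros((2, 1)) + [[0.0], [1.0]], [[0.0], [1.0]], 3)

    def test_zero_variance_column_names_offender(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 2))
        y = np.ones((50, 1))
        with pytest.raises(StandardizationError, match="column 0"):
            fit_joint(x, y, 1)

    def test_nonfinite_rejected(self):
        x = np.array([[0.0], [np.nan], [1.0]])
        with pytest.raises(FitError):
            fit_joint(x, np.ones((3, 1)) * [[0], [1], [2]], 1)


class TestConditionClosedForm:
    def test_single_component_matches_textbook_formula(self):
        """K=1 conditioning equals the conditional MVN (Schur complement)
        computed independently, on 100 random SPD covariances."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            d_x = int(rng.integers(1, 4))
            d_y = int(rng.integers(1, 4))
            d = d_x + d_y
            mu = rng.normal(size=d)
            cov = random_spd(rng, d)
            m = manual_mixture([1.0], [mu], [cov], (d_x, d_y))
            q = rng.normal(size=d_x)
            cm = condition(m, "on_x", q)
            # independent oracle: plain formula via explicit inverse
            s_ii = cov[:d_x, :d_x]
            s_oi = cov[d_x:, :d_x]
            s_oo = cov[d_x:, d_x:]
            inv = np.linalg.inv(s_ii)
            mean_ref = mu[d_x:] + s_oi @ inv @ (q - mu[:d_x])
            cov_ref = s_oo - s_oi @ inv @ s_oi.T
            worst = max(worst,
                        np.abs(cm.means[0] - mean_ref).max(),
                        np.abs(cm.covariances[0] - cov_ref).max())
            assert cm.weights[0] == pytest.approx(1.0)
        assert worst < 1e-8

    def test_zero_cross_covariance_gives_marginal_mean(self):
        cov = np.diag([2.0, 3.0])
        m = manual_mixture([1.0], [[1.5, -2.5]], [cov], (1, 1))
        for q in [-4.0, 0.0, 7.0]:
            cm = condition(m, "on_x", [q])
            assert cm.means[0] == pytest.approx([-2.5])

    def test_conditional_density_matches_bruteforce_grid(self):
        """On a 1+1-dim K=2 mixture, p(y|x) and p(x|y) from condition()
        match grid-evaluated p(x,y)/p(marginal) to 1e-6."""
        weights = [0.4, 0.6]
        means = [[-1.0, -2.0], [2.0, 1.5]]
        covs = [[[1.0, 0.6], [0.6, 2.0]], [[1.5, -0.4], [-0.4, 0.8]]]
        m = manual_mixture(weights, means, covs, (1, 1))
        grid = np.linspace(-6, 6, 200)

        def joint_pdf(x, y):
            return sum(
                w * multivariate_normal.pdf([x, y], mean=mu, cov=c)
                for w, mu, c in zip(m.weights, means, covs)
            )

        for q in [-1.3, 0.0, 2.4]:
            # condition on x: oracle marginal over x is sum of 1-d normals
            px = sum(w * norm.pdf(q, loc=mu[0], scale=np.sqrt(c[0][0]))
                     for w, mu, c in zip(m.weights, means, covs))
            cm = condition(m, "on_x", [q])
            ours = np.exp([cm.logpdf([g]) for g in grid])
            ref = np.array([joint_pdf(q, g) for g in grid]) / px
            assert np.abs(ours - ref).max() < 1e-6

            py = sum(w * norm.pdf(q, loc=mu[1], scale=np.sqrt(c[1][1]))
                     for w, mu, c in zip(m.weights, means, covs))
            cm = condition(m, "on_y", [q])
            ours = np.exp([cm.logpdf([g]) for g in grid])
            ref = np.array([joint_pdf(g, q) for g in grid]) / py
            assert np.abs(ours - ref).max() < 1e-6

    def test_block_symmetry(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        swapped = swap_blocks(m)
        q = y[0]
        a = condition(m, "on_y", q)
        b = condition(swapped, "on_x", q)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)
        np.testing.assert_allclose(a.means, b.means, atol=1e-12)
        np.testing.assert_allclose(a.covariances, b.covariances, atol=1e-12)

    def test_conditional_mixture_invariants(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        for q in x[:20]:
            cm = condition(m, "on_x", q)
            assert cm.weights.sum() == pytest.approx(1.0, abs=1e-10)
            assert (cm.weights >= 0).all()
            for s in cm.covariances:
                assert np.linalg.eigvalsh(s).min() >= -1e-10
            assert cm.means.shape[1] == m.d_y

    def test_dimension_mismatch_raises(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 2, seed=0)
        with pytest.raises(DimensionError):
            condition(m, "on_x", [0.0])  # d_x is 2
        with pytest.raises(DimensionError):
            condition(m, "on_y", [0.0, 0.0])
        with pytest.raises(DimensionError):
            condition(m, "on_x", [np.inf, 0.0])

    def test_far_query_not_degenerate_in_log_space(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        cm = condition(m, "on_x", x.mean(axis=0) + 50 * x.std(axis=0))
        assert cm.weights.sum() == pytest.approx(1.0, abs=1e-10)


class TestPointEstimate:
    def test_direct_arithmetic(self):
        cm = ConditionalMixture(
            conditioned_block="on_x", query=np.zeros(1),
            weights=np.array([0.7, 0.3]),
            means=np.array([[1.0], [3.0]]),
            covariances=np.ones((2, 1, 1)),
            out_standardizer=identity_standardizer(1),
        )
        assert point_estimate(cm, "weighted_mean") == pytest.approx([1.6])
        assert point_estimate(cm, "highest_weight") == pytest.approx([1.0])

    def test_single_component_methods_agree(self):
        cm = ConditionalMixture(
            conditioned_block="on_x", query=np.zeros(1),
            weights=np.array([1.0]), means=np.array([[2.5, -1.0]]),
            covariances=np.eye(2)[None],
            out_standardizer=identity_standardizer(2),
        )
        np.testing.assert_allclose(point_estimate(cm, "highest_weight"),
                                   point_estimate(cm, "weighted_mean"))

    def test_highest_weight_matches_enumeration(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        for q in x[:20]:
            cm = condition(m, "on_x", q)
            best = max(range(cm.n_components),
                       key=lambda k: (cm.weights[k], -k))  # enumeration oracle
            np.testing.assert_allclose(point_estimate(cm, "highest_weight"),
                                       cm.means[best])

    def test_tie_broken_by_lowest_index(self):
        cm = ConditionalMixture(
            conditioned_block="on_x", query=np.zeros(1),
            weights=np.array([0.5, 0.5]),
            means=np.array([[10.0], [20.0]]),
            covariances=np.ones((2, 1, 1)),
            out_standardizer=identity_standardizer(1),
        )
        assert point_estimate(cm, "highest_weight") == pytest.approx([10.0])


class TestForwardInverse:
    def test_linear_gaussian_prediction(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(4000, 1))
        y = 2.0 * x + 0.1 * rng.normal(size=(4000, 1))
        m = fit_joint(x, y, 1, seed=0)
        assert predict_forward(m, [0.0])[0] == pytest.approx(0.0, abs=0.05)
        assert predict_forward(m, [1.0])[0] == pytest.approx(2.0, abs=0.1)

    def test_raw_scale_round_trip_units(self):
        rng = np.random.default_rng(9)
        x = rng.normal(loc=100.0, scale=20.0, size=(2000, 1))
        y = 3.0 * x + rng.normal(size=(2000, 1))  # y lives around 300
        m = fit_joint(x, y, 1, seed=0)
        pred = predict_forward(m, x[:50])
        assert pred.mean() == pytest.approx(y[:50].mean(), rel=0.05)

    def test_batch_order_preserved(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        batch = predict_forward(m, x[:10])
        assert batch.shape == (10, 1)
        for i in range(10):
            np.testing.assert_allclose(batch[i], predict_forward(m, x[i]))

    def test_single_gaussian_inverse_is_closed_form(self):
        rng = np.random.default_rng(10)
        cov = random_spd(rng, 3)
        mu = rng.normal(size=3)
        m = manual_mixture([1.0], [mu], [cov], (2, 1))
        y0 = np.array([mu[2] + 1.0])
        est = inverse_estimate(m, y0)
        ref = mu[:2] + cov[:2, 2] / cov[2, 2] * (y0[0] - mu[2])
        np.testing.assert_allclose(est, ref, atol=1e-10)

    def test_inverse_forward_round_trip(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        y_sd = y.std(axis=0)
        for q in np.quantile(y, [0.2, 0.5, 0.8]):
            z = inverse_estimate(m, [q], method="highest_weight")
            back = predict_forward(m, z)
            assert np.abs((back - q) / y_sd).max() < 0.5


class TestSampleConditional:
    @pytest.fixture()
    def cmix(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        return condition(m, "on_y", np.quantile(y, 0.5, axis=0))

    def test_empty_draw(self, cmix):
        assert sample_conditional(cmix, 0).shape == (0, 2)

    def test_seed_determinism(self, cmix):
        a = sample_conditional(cmix, 50, seed=3)
        b = sample_conditional(cmix, 50, seed=3)
        np.testing.assert_array_equal(a, b)
        c = sample_conditional(cmix, 50, seed=4)
        assert not np.array_equal(a, c)

    def test_monte_carlo_mean_matches_analytic(self, cmix):
        draws = sample_conditional(cmix, 100_000, seed=0)
        analytic = point_estimate(cmix, "weighted_mean")
        # per-dim mixture variance for the standard error of the MC mean
        second = sum(w * (s.diagonal() + mu**2)
                     for w, mu, s in zip(cmix.weights, cmix.means, cmix.covariances))
        var = second - analytic**2
        se = np.sqrt(var / draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - analytic) < 3 * se + 1e-12).all()


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.arange(10.0)[:, None]
        m = regression_metrics(y, y)
        assert m.r2[0] == pytest.approx(1.0)
        assert m.rmse[0] == 0.0 and m.mae[0] == 0.0

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        m = regression_metrics(y, np.full_like(y, y.mean()))
        assert m.r2[0] == pytest.approx(0.0)

    def test_hand_checked_five_points(self):
        truth = np.array([1, 2, 3, 4, 5], float)
        pred = np.array([1, 2, 3, 4, 7], float)
        m = regression_metrics(truth, pred)
        assert m.rmse[0] == pytest.approx(np.sqrt(4 / 5))  # 0.894...
        assert m.mae[0] == pytest.approx(0.4)
        assert m.rmse[0] >= m.mae[0] >= 0

    def test_zero_variance_truth_column_raises(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics(np.ones((5, 1)), np.zeros((5, 1)))


class TestSerialization:
    def test_json_round_trip_bit_exact(self, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 3, seed=5)
        m2 = JointGaussianMixture.from_json(m.to_json())
        assert (m2.weights == m.weights).all()
        assert (m2.means == m.means).all()
        assert (m2.covariances == m.covariances).all()
        assert m2.block_split == m.block_split
        assert (m2.x_standardizer.center == m.x_standardizer.center).all()
        assert m2.ridge == m.ridge and m2.seed == m.seed

    def test_file_round_trip_preserves_predictions(self, tmp_path, separated_samples):
        x, y, _ = separated_samples
        m = fit_joint(x, y, 2, seed=1)
        m.save(tmp_path / "gmm.json")
        m2 = JointGaussianMixture.load(tmp_path / "gmm.json")
        np.testing.assert_array_equal(predict_forward(m, x[:5]), predict_forward(m2, x[:5]))


class TestHyperparameterSelection:
    def test_single_candidate_returned(self, separated_samples):
        x, y, _ = separated_samples
        cfg, score = select_hyperparameters(
            x[:500], y[:500], search_space=[(2, 1e-6)], n_folds=3, seed=0)
        assert cfg == {"n_components": 2, "ridge": 1e-6}
        assert np.isfinite(score)

    def test_cv_score_reproducible(self, separated_samples):
        x, y, _ = separated_samples
        space = {"n_components": [1, 2, 3], "ridge": [1e-6]}
        cfg, score = select_hyperparameters(x[:600], y[:600], space, n_folds=3, seed=4)
        again = cross_validated_r2(x[:600], y[:600], cfg["n_components"], cfg["ridge"],
                                   n_folds=3, seed=4)
        assert abs(again - score) < 1e-12

    def test_bayesian_path_stays_in_space_and_improves(self, separated_samples):
        x, y, _ = separated_samples
        space = {"n_components": range(1, 7), "ridge": np.logspace(-8, -3, 6)}
        cfg, score = select_hyperparameters(x[:600], y[:600], space,
                                            n_folds=3, n_trials=12, seed=0)
        assert cfg["n_components"] in range(1, 7)
        assert np.isfinite(score) and score > 0.5

    def test_infeasible_fold_scored_failed_not_fatal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 1))
        y = x + 0.1 * rng.normal(size=(12, 1))
        # K=10 cannot fit in a 2-fold split of 12 points
        score = cross_validated_r2(x, y, 10, 1e-6, n_folds=2, seed=0)
        assert score == -np.inf
        cfg, best = select_hyperparameters(x, y, [(1, 1e-6), (10, 1e-6)],
                                           n_folds=2, seed=0)
        assert cfg["n_components"] == 1
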