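"""Bayesian dynamic stopping core: parameter estimation, Gaussian score
moments, the quadratic likelihood-ratio test, decision boundaries, and the
sequential procedure."""

import numpy as np
import pytest
import scipy.stats

from cvepstop.bds import (
    DistributionParams,
    StoppingModel,
    calibrate_bds,
    class_distribution_params,
    decide,
    decision_boundary,
    estimate_alpha_sigma,
    log_likelihood_ratio,
    make_grid,
    quadratic_coefficients,
)
from cvepstop.reconvolution import ScoreVector, SpatialFilter, TemplateSet


def random_params(rng, force_order=True):
    """Random valid distribution parameters with b1 > b0 (Cauchy-Schwarz)."""
    alpha = rng.uniform(0.2, 3.0)
    sigma = rng.uniform(0.1, 2.0)
    b1 = rng.uniform(0.5, 5.0)
    b0 = rng.uniform(-0.5, b1 * 0.9) if force_order else rng.uniform(-1, 5)
    var1 = sigma**2 * b1 * rng.uniform(1.0, 2.0)
    var0 = sigma**2 * b1 * rng.uniform(0.5, 1.5)
    return DistributionParams(alpha, sigma, b1, b0, var1, var0, window_len=10)


class TestAlphaSigma:
    def test_exact_scaling_recovered(self):
        t = np.linspace(-1, 1, 64)
        alpha, sigma = estimate_alpha_sigma(2.0 * t, t)
        assert alpha == pytest.approx(2.0)
        assert sigma == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_recovery(self, rng):
        n = 50_000
        t = rng.standard_normal(n)
        x = 0.8 * t + rng.normal(0.0, 0.5, n)
        alpha, sigma = estimate_alpha_sigma(x, t)
        assert alpha == pytest.approx(0.8, rel=0.02)
        assert sigma == pytest.approx(0.5, rel=0.02)

    def test_negative_scale_preserved(self, caplog):
        t = np.arange(1.0, 10.0)
        alpha, _ = estimate_alpha_sigma(-t, t)
        assert alpha == pytest.approx(-1.0)

    def test_zero_template_rejected(self):
        with pytest.raises(ValueError, match="identically zero"):
            estimate_alpha_sigma(np.ones(5), np.zeros(5))


def brute_force_params(t, alpha, sigma):
    """Direct double-sum oracle for the Gaussian score moments."""
    N = t.shape[0]
    b1 = sum(t[i] @ t[i] for i in range(N)) / N
    b0 = sum(t[i] @ t[j] for i in range(N) for j in range(N) if i != j) / (N**2 - N)
    var1 = sigma**2 * b1 + sum((alpha * t[i] @ t[i] - alpha * b1) ** 2 for i in range(N)) / N
    var0 = sigma**2 * b1 + sum(
        (alpha * t[i] @ t[j] - alpha * b0) ** 2
        for i in range(N) for j in range(N) if i != j
    ) / (N**2 - N)
    return b1, b0, var1, var0


class TestDistributionParams:
    def test_two_orthogonal_equal_norm_templates(self):
        t = TemplateSet(np.array([[2.0, 0.0], [0.0, 2.0]]), 1.0)
        p = class_distribution_params(t, 2, alpha=1.0, sigma=0.5)
        q = 4.0
        assert p.b1 == pytest.approx(q)
        assert p.b0 == pytest.approx(0.0)
        assert p.var1 == pytest.approx(0.25 * q)
        assert p.var0 == pytest.approx(0.25 * q)

    def test_three_class_toy_matches_double_sum_oracle(self):
        t = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        p = class_distribution_params(TemplateSet(t, 1.0), 2, alpha=1.0, sigma=1.0)
        b1, b0, var1, var0 = brute_force_params(t, 1.0, 1.0)
        assert (p.b1, p.b0) == pytest.approx((b1, b0))
        assert (p.var1, p.var0) == pytest.approx((var1, var0))
        # hand values: b1 = 4/3, b0 = 2/3, var1 = var0 = 14/9
        assert p.b1 == pytest.approx(4 / 3)
        assert p.b0 == pytest.approx(2 / 3)
        assert p.var1 == pytest.approx(14 / 9)
        assert p.var0 == pytest.approx(14 / 9)

    def test_random_templates_match_oracle(self, rng):
        t = rng.standard_normal((5, 12))
        p = class_distribution_params(TemplateSet(t, 1.0), 12, alpha=1.7, sigma=0.3)
        oracle = brute_force_params(t, 1.7, 0.3)
        assert (p.b1, p.b0, p.var1, p.var0) == pytest.approx(oracle)

    def test_zero_alpha_collapses_spread_terms(self, rng):
        t = rng.standard_normal((4, 6))
        p = class_distribution_params(TemplateSet(t, 1.0), 6, alpha=0.0, sigma=0.7)
        assert p.var1 == pytest.approx(0.49 * p.b1)
        assert p.var0 == pytest.approx(0.49 * p.b1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            class_distribution_params(TemplateSet(np.ones((1, 4)), 1.0), 4, 1.0, 1.0)


class TestLogLikelihoodRatio:
    def test_midpoint_is_zero_with_equal_variances(self):
        p = DistributionParams(1.0, 1.0, b1=3.0, b0=1.0, var1=2.0, var0=2.0, window_len=1)
        assert log_likelihood_ratio(1.0 * (3.0 + 1.0) / 2, p) == pytest.approx(0.0)

    def test_symmetry_about_midpoint(self):
        p = DistributionParams(2.0, 1.0, b1=3.0, b0=1.0, var1=1.5, var0=1.5, window_len=1)
        at_target = log_likelihood_ratio(2.0 * 3.0, p)
        at_nontarget = log_likelihood_ratio(2.0 * 1.0, p)
        assert at_target > 0
        assert at_nontarget == pytest.approx(-at_target)

    def test_matches_independent_gaussian_densities(self, rng):
        for _ in range(50):
            p = random_params(rng)
            f = rng.normal(0, 5)
            oracle = scipy.stats.norm.logpdf(
                f, p.alpha * p.b1, np.sqrt(p.var1)
            ) - scipy.stats.norm.logpdf(f, p.alpha * p.b0, np.sqrt(p.var0))
            assert log_likelihood_ratio(f, p) == pytest.approx(oracle, abs=1e-10)

    def test_non_positive_variance_rejected(self):
        p = DistributionParams(1.0, 1.0, 1.0, 0.0, var1=0.0, var0=1.0, window_len=1)
        with pytest.raises(ValueError):
            log_likelihood_ratio(0.0, p)


class TestQuadraticTest:
    def test_equal_variances_give_zero_curvature(self):
        p = DistributionParams(1.0, 1.0, 2.0, 1.0, var1=1.3, var0=1.3, window_len=1)
        q = quadratic_coefficients(p, zeta=1.0, n_classes=4)
        assert q.a == 0.0

    def test_sign_agrees_with_llr_oracle(self, rng):
        """The quadratic form must reproduce the direct likelihood-ratio test."""
        n_bad = 0
        for _ in range(500):
            p = random_params(rng)
            zeta = 10.0 ** rng.uniform(-3, 3)
            N = rng.integers(2, 40)
            q = quadratic_coefficients(p, zeta, N)
            f = rng.normal(p.alpha * p.b0, 3 * np.sqrt(p.var0), size=100)
            lhs = q.a * f**2 + q.b * f + q.c
            rhs = log_likelihood_ratio(f, p) - np.log((N - 1) * zeta)
            margin = 1e-9 * (np.abs(lhs) + 1)
            n_bad += int((np.sign(lhs) != np.sign(rhs))[np.abs(lhs) > margin].sum())
        assert n_bad == 0

    def test_zeta_enters_only_through_c(self, rng):
        p = random_params(rng)
        q1 = quadratic_coefficients(p, 1.0, 8)
        q2 = quadratic_coefficients(p, 2.0, 8)
        assert (q1.a, q1.b) == (q2.a, q2.b)
        assert q2.c - q1.c == pytest.approx(-2.0 * p.var0 * p.var1 * np.log(2.0))

    def test_invalid_zeta_rejected(self, rng):
        with pytest.raises(ValueError):
            quadratic_coefficients(random_params(rng), 0.0, 4)


class TestDecisionBoundary:
    def test_equal_variance_two_class_midpoint(self):
        """zeta = 1, N = 2, sigma0 = sigma1: the boundary is the Gaussian
        intersection, i.e. the midpoint of the two means."""
        p = DistributionParams(1.0, 1.0, b1=3.0, b0=1.0, var1=2.0, var0=2.0, window_len=1)
        q = quadratic_coefficients(p, zeta=1.0, n_classes=2)
        eta = decision_boundary(q)
        assert eta == pytest.approx(1.0 * (3.0 + 1.0) / 2, abs=1e-9)

    def test_simple_quadratic_takes_plus_branch(self):
        from cvepstop.bds import QuadraticCoeffs

        q = QuadraticCoeffs(a=1.0, b=0.0, c=-4.0, zeta=1.0, n_classes=2)
        assert decision_boundary(q) == pytest.approx(2.0)

    def test_monotone_in_zeta(self, rng):
        """Raising the false-positive cost moves the boundary toward the
        target distribution."""
        zetas = [1e-3, 1e-1, 1.0, 1e1, 1e3]
        for _ in range(100):
            p = random_params(rng)
            etas = []
            for z in zetas:
                q = quadratic_coefficients(p, z, 8)
                etas.append(decision_boundary(q))
            finite = [e for e in etas if np.isfinite(e)]
            assert all(b >= a - 1e-9 for a, b in zip(etas, etas[1:])) or not finite

    def test_no_real_root_yields_sentinel(self):
        from cvepstop.bds import QuadraticCoeffs

        assert decision_boundary(QuadraticCoeffs(1.0, 0.0, 1.0, 1.0, 2)) == -np.inf
        assert decision_boundary(QuadraticCoeffs(-1.0, 0.0, -1.0, 1.0, 2)) == np.inf

    def test_degenerate_model_rejected(self):
        from cvepstop.bds import QuadraticCoeffs

        with pytest.raises(ValueError, match="degenerate"):
            decision_boundary(QuadraticCoeffs(0.0, 0.0, 1.0, 1.0, 2))


class TestCalibrate:
    def test_eta_per_window_and_zeta_only_changes_eta(self, small_dataset):
        from cvepstop.reconvolution import fit_reconvolution_cca, predict_templates

        ds = small_dataset
        w, r = fit_reconvolution_cca(ds.trials, ds.labels, ds.structures)
        templates = predict_templates(r, ds.structures, ds.config.sample_rate)
        grid = make_grid(0.1, ds.n_samples / 120.0, 120.0)
        m1 = calibrate_bds(ds.trials, ds.labels, w, templates, grid, zeta=1.0)
        m2 = calibrate_bds(ds.trials, ds.labels, w, templates, grid, zeta=100.0)
        assert m1.eta.size == grid.size
        for p1, p2 in zip(m1.params, m2.params):
            assert p1 == p2
        assert not np.allclose(m1.eta, m2.eta)

    def test_parameter_recovery_on_synthetic_data(self, small_dataset):
        """Projecting with the true spatial pattern and matching against the
        true templates recovers alpha and the virtual-channel noise std."""
        ds = small_dataset
        a = ds.ground_truth["spatial_pattern"]
        x = np.tensordot(a, ds.trials, axes=(0, 1)).ravel()
        t = ds.ground_truth["templates"][ds.labels].ravel()
        alpha, sigma = estimate_alpha_sigma(x, t)
        sigma_virtual = np.hypot(ds.ground_truth["sigma"], ds.ground_truth["sigma_bg"])
        assert alpha == pytest.approx(ds.ground_truth["alpha"], rel=0.05)
        assert sigma == pytest.approx(sigma_virtual, rel=0.05)


def toy_model(eta_values, alpha=1.0, b1=4.0, sample_rate=10.0):
    grid = np.arange(10, 10 * (len(eta_values) + 1), 10)
    params = [
        DistributionParams(alpha, 1.0, b1, 1.0, 2.0, 1.5, int(g)) for g in grid
    ]
    return StoppingModel(
        grid=grid, params=params, eta=np.array(eta_values, dtype=float),
        zeta=1.0, max_len=int(grid[-1]), n_classes=3, sample_rate=sample_rate,
    )


def sv(scores, window_len):
    return ScoreVector(np.array(scores, dtype=float), "inner", window_len)


class TestDecide:
    def test_immediate_stop_on_first_window(self):
        model = toy_model([4.0, 4.0])
        d = decide([sv([5.0, 1.0, 1.0], 10), sv([0, 0, 0], 20)], model)
        assert (d.stop_window, d.predicted, d.forced) == (0, 0, False)
        assert d.stop_time == pytest.approx(1.0)

    def test_forced_stop_emits_argmax(self):
        model = toy_model([np.inf, np.inf])
        d = decide([sv([1.0, 2.0, 0.0], 10), sv([1.0, 3.0, 0.0], 20)], model)
        assert (d.stop_window, d.predicted, d.forced) == (1, 1, True)
        assert len(d.score_trace) == 2

    def test_multiple_passing_scores_pick_highest_target_likelihood(self):
        # target mean alpha*b1 = 4.0; eta = 3.0; passing scores 3.1 and 3.55:
        # 3.55 is closer to the target mean, so class 2 wins despite the tie rule
        model = toy_model([3.0])
        d = decide([sv([0.0, 3.1, 3.55], 10)], model)
        assert d.predicted == 2
        assert not d.forced

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            decide([], toy_model([1.0]))


def monte_carlo_risk_check(p, zeta, N, rng, n=100_000, n_grid=200):
    """Check that the analytic boundary minimizes the empirical Bayes risk
    R(thr) = zeta*p0*P(f0 > thr) + p1*P(f1 < thr).

    Passes if the empirical argmin lies within one grid step of eta, or if
    the risk at eta is within Monte-Carlo standard error of the grid
    minimum (the risk curve is flat near its minimum, so the empirical
    argmin wobbles even when eta is exactly optimal).
    """
    q = quadratic_coefficients(p, zeta, N)
    eta = decision_boundary(q)
    if not np.isfinite(eta):
        return True
    f1 = rng.normal(p.alpha * p.b1, np.sqrt(p.var1), n)
    f0 = rng.normal(p.alpha * p.b0, np.sqrt(p.var0), n)
    lo = min(p.alpha * p.b0 - 4 * np.sqrt(p.var0), eta)
    hi = max(p.alpha * p.b1 + 4 * np.sqrt(p.var1), eta)
    thr = np.linspace(lo, hi, n_grid)
    p1, p0 = 1.0 / N, (N - 1.0) / N
    risk = (
        zeta * p0 * (f0[:, None] > thr).mean(axis=0)
        + p1 * (f1[:, None] < thr).mean(axis=0)
    )
    k_min = int(np.argmin(risk))
    step = thr[1] - thr[0]
    if abs(thr[k_min] - eta) <= step:
        return True
    risk_at_eta = (
        zeta * p0 * (f0 > eta).mean() + p1 * (f1 < eta).mean()
    )
    se = np.sqrt((zeta * p0) ** 2 * 0.25 / n + p1**2 * 0.25 / n)
    return risk_at_eta - risk[k_min] <= 4 * se


class TestRiskOptimality:
    def test_boundary_minimizes_monte_carlo_risk(self, rng):
        for _ in range(5):
            p = random_params(rng)
            N = int(rng.integers(2, 10))
            zeta = 10.0 ** rng.uniform(-1, 1)
            assert monte_carlo_risk_check(p, zeta, N, rng)


def test_make_grid_covers_trial_in_100ms_steps():
    grid = make_grid(0.1, 4.2, 120.0)
    assert grid[0] == 12
    assert grid[-1] == 504
    assert len(grid) == 42
    assert (np.diff(grid) == 12).all()
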