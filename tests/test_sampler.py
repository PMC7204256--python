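"""Sampler tests: conditional-distribution oracles, adaptation, diagnostics,
label-switch filtering, thresholding and phenotype correction."""

import numpy as np
import pytest
from scipy import stats

from phenofix import (
    GenotypeMatrix,
    KinshipMatrix,
    MCMCConfig,
    ModelParams,
    PhenotypeVector,
    PriorSpec,
    aggregate_and_flag,
    correct_phenotype,
    geweke_z,
    run_chain,
)
from phenofix.sampler import (
    adapt_proposal_scales,
    detect_and_filter_label_switch,
    gibbs_update_sigma_u2,
    gibbs_update_u,
    initialize_state,
    mh_update_params,
    sample_latent_liability,
    sample_misclassification_indicators,
)


class TestInitialization:
    def test_seeded_reproducibility(self):
        a = initialize_state(PriorSpec(), 5, 3, np.random.default_rng(7))
        b = initialize_state(PriorSpec(), 5, 3, np.random.default_rng(7))
        assert a.alpha == b.alpha and a.lambda_ == b.lambda_
        assert np.array_equal(a.beta, b.beta)

    def test_prior_draws_and_fixed_components(self, rng):
        draws = [initialize_state(PriorSpec(), 4, 2, rng) for _ in range(10_000)]
        alphas = np.array([d.alpha for d in draws])
        # Beta(10,1): mean 10/11, var 10/(11^2*12)
        se = np.sqrt(10 / (121 * 12) / 10_000)
        assert abs(alphas.mean() - 10 / 11) < 3 * se
        assert all(d.sigma_u2 == 0.1 for d in draws)
        assert all(np.all(d.u == 0) for d in draws)


class TestIndicators:
    def _params(self, alpha, lambda_, n):
        return ModelParams(alpha=alpha, lambda_=lambda_, beta=np.zeros(1),
                           u=np.zeros(n), sigma_u2=0.1)

    def test_tiny_lambda_marks_no_cases(self, rng):
        y = np.ones(200, dtype=int)
        sigma = rng.uniform(0.2, 0.8, 200)
        marked, y_lat = sample_misclassification_indicators(
            self._params(0.9, 1e-14, 200), y, sigma, rng)
        assert not marked.any() and np.array_equal(y_lat, y)

    def test_alpha_near_one_marks_no_controls(self, rng):
        y = np.zeros(200, dtype=int)
        sigma = rng.uniform(0.2, 0.8, 200)
        marked, _ = sample_misclassification_indicators(
            self._params(1 - 1e-14, 0.1, 200), y, sigma, rng)
        assert not marked.any()

    def test_bernoulli_rate_matches_posterior(self, rng):
        """Empirical mark frequency equals the case posterior (here 0.1)."""
        n = 100_000
        y = np.ones(n, dtype=int)
        sigma = np.full(n, 0.5)
        marked, y_lat = sample_misclassification_indicators(
            self._params(0.9, 0.1, n), y, sigma, rng)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(marked.mean() - 0.1) < 3 * se
        assert np.array_equal(y_lat[marked], np.zeros(marked.sum(), dtype=int))


class TestLatentLiability:
    def test_half_normal_mean(self, rng):
        X = np.zeros((50_000, 1))
        l = sample_latent_liability(np.ones(50_000, int), X, [0.0],
                                    np.zeros(50_000), rng)
        assert np.all(l > 0)
        assert abs(l.mean() - np.sqrt(2 / np.pi)) < 3 * l.std() / np.sqrt(l.size)

    def test_far_from_boundary_truncation_inactive(self, rng):
        X = np.zeros((20_000, 1))
        l = sample_latent_liability(np.ones(20_000, int), X, [0.0],
                                    np.full(20_000, 10.0), rng)
        assert abs(l.mean() - 10.0) < 0.05 and abs(l.std() - 1.0) < 0.05

    def test_extreme_truncation_is_finite_and_signed(self, rng):
        """Mean deep inside the rejected tail: inverse-CDF sampling must not
        hang or overflow, and signs must respect the latent labels."""
        X = np.zeros((1000, 1))
        u = np.full(1000, -30.0)
        l = sample_latent_liability(np.ones(1000, int), X, [0.0], u, rng)
        assert np.all(np.isfinite(l)) and np.all(l > 0)
        l2 = sample_latent_liability(np.zeros(1000, int), X, [0.0], -u, rng)
        assert np.all(np.isfinite(l2)) and np.all(l2 <= 0)


class TestGibbsU:
    def test_identity_kinship_conditional(self, rng):
        """A = I, gamma = 1: u_i ~ N((l_i - X_i beta)/2, 1/2) independently."""
        n, reps = 4, 40_000
        l = np.array([1.0, -0.5, 2.0, 0.0])
        X = np.zeros((n, 1))
        draws = np.empty((reps, n))
        for r in range(reps):
            draws[r] = gibbs_update_u(l, X, [0.0], np.zeros(n), np.eye(n), 1.0, rng)
        assert np.allclose(draws.mean(0), l / 2, atol=4 * np.sqrt(0.5 / reps) + 1e-3)
        assert np.allclose(draws.var(0), 0.5, atol=0.02)

    def test_infinite_variance_limit(self, rng):
        """gamma -> 0 removes shrinkage: u_i ~ N(l_i - X_i beta, 1)."""
        n, reps = 3, 30_000
        l = np.array([2.0, -1.0, 0.5])
        X = np.zeros((n, 1))
        draws = np.empty((reps, n))
        for r in range(reps):
            draws[r] = gibbs_update_u(l, X, [0.0], np.zeros(n), np.eye(n), 1e12, rng)
        assert np.allclose(draws.mean(0), l, atol=0.03)
        assert np.allclose(draws.var(0), 1.0, atol=0.04)

    def test_scan_targets_exact_conditional_mvn(self, rng):
        """Long-run distribution of the sequential scan on a correlated
        3-sample kinship equals the closed-form conditional MVN
        N((I + gamma A^-1)^-1 r, (I + gamma A^-1)^-1)."""
        A = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        A_inv = np.linalg.inv(A)
        gamma = 1.0 / 2.0
        l = np.array([1.5, -0.5, 0.8])
        X = np.zeros((3, 1))
        prec = np.eye(3) + gamma * A_inv
        cov_exact = np.linalg.inv(prec)
        mean_exact = cov_exact @ l
        u = np.zeros(3)
        burn, keep = 500, 40_000
        samples = np.empty((keep, 3))
        for it in range(burn + keep):
            u = gibbs_update_u(l, X, [0.0], u, A_inv, 2.0, rng)
            if it >= burn:
                samples[it - burn] = u
        assert np.allclose(samples.mean(0), mean_exact, atol=0.03)
        assert np.allclose(np.cov(samples.T), cov_exact, atol=0.04)


class TestGibbsSigmaU2:
    def test_mode_at_S_over_q(self, rng):
        """Density (s2)^(-q/2) exp(-S/(2 s2)) peaks at S/q; check via a
        histogram of draws around the mode."""
        q, S = 4, 8.0
        # log-density stationary point: d/ds2 [-(q/2) log s2 - S/(2 s2)] = 0
        assert S / q == pytest.approx(2.0)
        u = np.array([2.0, 0.0, 2.0, 0.0])  # S = u'u = 8 with A = I
        draws = np.array([
            gibbs_update_sigma_u2(u, np.eye(4), 4, 100.0, rng) for _ in range(20_000)
        ])
        hist, edges = np.histogram(draws, bins=np.geomspace(0.1, 100, 60))
        centers = np.sqrt(edges[1:] * edges[:-1])
        widths = np.diff(edges)
        mode_est = centers[np.argmax(hist / widths)]
        assert 1.0 < mode_est < 4.0

    def test_truncation_and_degenerate_input(self, rng):
        u = np.full(10, 50.0)
        draws = [gibbs_update_sigma_u2(u, np.eye(10), 10, 100.0, rng)
                 for _ in range(2000)]
        assert max(draws) <= 100.0
        assert gibbs_update_sigma_u2(np.zeros(5), np.eye(5), 5, 100.0, rng,
                                     current=0.3) == 0.3

    def test_ks_against_numeric_cdf(self, rng):
        """Draws at q = 10, S = 20 match the truncated density integrated
        numerically (independent quadrature oracle)."""
        q, S = 10, 20.0
        u = np.sqrt(S / q) * np.ones(q)  # u'u = S with A = I
        draws = np.array([
            gibbs_update_sigma_u2(u, np.eye(q), q, 100.0, rng)
            for _ in range(5000)
        ])
        grid = np.geomspace(1e-4, 100.0, 20_000)
        logpdf = -(q / 2) * np.log(grid) - S / (2 * grid)
        pdf = np.exp(logpdf - logpdf.max())
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
        cdf /= cdf[-1]
        transformed = np.interp(draws, grid, cdf)
        stat = stats.kstest(transformed, "uniform").pvalue
        assert stat > 0.01


class TestAdaptation:
    def test_on_target_leaves_scales_unchanged(self):
        scales = {"alpha": 0.1, "beta": np.array([0.2, 0.3])}
        out = adapt_proposal_scales(scales, 0.2, target=0.2, batch=1)
        assert out["alpha"] == pytest.approx(0.1)
        assert np.allclose(out["beta"], [0.2, 0.3])

    def test_direction_of_update(self):
        scales = {"alpha": 0.1}
        up = adapt_proposal_scales(scales, 1.0, target=0.2, batch=1)
        down = adapt_proposal_scales(scales, 0.0, target=0.2, batch=2)
        assert up["alpha"] > 0.1 > down["alpha"]

    def test_adapted_chain_settles_near_target(self, small_dataset):
        X, Y = small_dataset
        cfg = MCMCConfig(n_iter=6000, burn_in=4000, seed=3, adapt_interval=100)
        tr = run_chain(Y, X, np.eye(Y.n), PriorSpec(), cfg)
        assert 0.1 < tr.acceptance_rate < 0.35


class TestLabelSwitchFilter:
    def test_no_switch_discards_nothing(self):
        keep, discarded, usable = detect_and_filter_label_switch(
            np.full(100, 0.9), np.full(100, 0.1), burn_in=20)
        assert discarded == 0 and usable and keep[20:].all()

    def test_exact_discard_count(self):
        alpha = np.full(100, 0.9)
        lam = np.full(100, 0.1)
        lam[50:60] = 0.95  # 10 switched iterations after burn-in
        keep, discarded, usable = detect_and_filter_label_switch(alpha, lam, burn_in=20)
        assert discarded == 10 and usable
        assert not keep[50:60].any()

    def test_majority_switch_flags_unusable(self):
        alpha = np.full(100, 0.2)
        lam = np.full(100, 0.8)
        _, discarded, usable = detect_and_filter_label_switch(alpha, lam, burn_in=0)
        assert discarded == 100 and not usable


class TestGeweke:
    def test_identical_halves_give_zero(self):
        # periodic series: the early-segment mean equals the late-segment
        # mean exactly, so the numerator (and hence z) is identically zero
        x = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 200)
        assert geweke_z(x) == pytest.approx(0.0, abs=1e-12)

    def test_gross_drift_detected(self):
        x = np.concatenate([np.zeros(500), np.full(500, 10.0)])
        x += np.random.default_rng(0).normal(0, 0.01, 1000)
        assert abs(geweke_z(x)) > 10

    def test_iid_calibration(self):
        """|z| < 1.96 in at least 93% of replicates for white noise."""
        rng = np.random.default_rng(42)
        hits = sum(
            abs(geweke_z(rng.standard_normal(10_000))) < 1.96 for _ in range(300)
        )
        assert hits / 300 >= 0.93

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.arange(50))


class TestMHUpdate:
    def test_proposals_respect_support_and_accounting(self, small_dataset, rng):
        X, Y = small_dataset
        D = np.column_stack([np.ones(Y.n), X.values])
        params = initialize_state(PriorSpec(), Y.n, D.shape[1], rng)
        scales = {"alpha": 0.05, "lambda": 0.05, "beta": np.full(D.shape[1], 0.1)}
        n_acc = 0
        for _ in range(300):
            params, acc, lp = mh_update_params(params, Y.values, D, PriorSpec(),
                                               scales, rng)
            assert 0.0 < params.alpha < 1.0 and 0.0 < params.lambda_ < 1.0
            assert np.isfinite(lp)
            n_acc += acc
        assert 0 < n_acc < 300


class TestRunChain:
    def test_single_retained_iteration_denominator(self, small_dataset):
        X, Y = small_dataset
        cfg = MCMCConfig(n_iter=202, burn_in=201, seed=5)
        tr = run_chain(Y, X, np.eye(Y.n), PriorSpec(), cfg)
        assert tr.denominator <= 1
        probs = tr.avg_misclassification_prob()
        assert set(np.unique(probs)).issubset({0.0, 1.0})

    def test_seeded_bit_reproducibility(self, small_dataset):
        X, Y = small_dataset
        cfg = MCMCConfig(n_iter=800, burn_in=300, seed=11)
        tr1 = run_chain(Y, X, np.eye(Y.n), PriorSpec(), cfg)
        tr2 = run_chain(Y, X, np.eye(Y.n), PriorSpec(), cfg)
        assert np.array_equal(tr1.avg_misclassification_prob(),
                              tr2.avg_misclassification_prob())
        assert np.array_equal(tr1.alpha, tr2.alpha)

    def test_averaging_excludes_burnin_and_switch(self, small_dataset):
        X, Y = small_dataset
        cfg = MCMCConfig(n_iter=1000, burn_in=400, seed=2)
        tr = run_chain(Y, X, np.eye(Y.n), PriorSpec(), cfg)
        post = tr.alpha[400:] > tr.lambda_[400:]
        assert tr.denominator == int(post.sum())
        assert tr.discarded_switch_iterations == int((~post).sum())

    def test_mixed_model_ablation_matches_on_structure_free_data(self, rng):
        """With no genetic structure the no-mixed-model ablation ranks samples
        like the full model (high rank correlation of avg probabilities)."""
        n = 150
        g = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        liab = g @ np.array([1.2, 1.0, 0.8]) + rng.standard_normal(n)
        y_true = (liab > np.quantile(liab, 0.7)).astype(int)
        y = y_true.copy()
        controls = np.flatnonzero(y_true == 0)
        y[rng.choice(controls, size=10, replace=False)] = 1
        X = GenotypeMatrix.from_counts(g)
        cfg_full = MCMCConfig(n_iter=4000, burn_in=1500, seed=0)
        cfg_abl = MCMCConfig(n_iter=4000, burn_in=1500, seed=0,
                             disable_mixed_model=True)
        tr_full = run_chain(y, X, np.eye(n), PriorSpec(), cfg_full)
        tr_abl = run_chain(y, X, None, PriorSpec(), cfg_abl)
        assert tr_full.usable and tr_abl.usable
        cases = y == 1
        rho = stats.spearmanr(tr_full.avg_misclassification_prob()[cases],
                              tr_abl.avg_misclassification_prob()[cases]).statistic
        assert rho > 0.9


class TestAggregateAndCorrect:
    def test_percentile_flags_exactly_one_of_hundred(self, rng):
        probs = rng.permutation(np.linspace(0.01, 0.99, 100))
        y = np.ones(100, int)
        y[0] = 0  # keep one control to have a valid phenotype downstream
        probs[0] = 0.0
        res = aggregate_and_flag([probs], y, t_percentile=99.0)
        assert res.flagged.sum() == 1
        assert probs[res.flagged][0] == probs[y == 1].max()

    def test_ties_flag_nothing(self):
        y = np.array([1] * 10 + [0] * 5)
        probs = np.full(15, 0.4)
        res = aggregate_and_flag([probs], y, t_percentile=99.0)
        assert res.flagged.sum() == 0

    def test_multi_run_average_equals_mean_vector(self, rng):
        y = np.array([1] * 20 + [0] * 10)
        runs = [rng.uniform(size=30) for _ in range(10)]
        res = aggregate_and_flag(runs, y, t_percentile=95.0)
        mean_res = aggregate_and_flag([np.mean(runs, axis=0)], y, t_percentile=95.0)
        assert np.allclose(res.avg_prob, mean_res.avg_prob)
        assert np.array_equal(res.flagged, mean_res.flagged)

    def test_no_usable_chains_raises(self):
        with pytest.raises(RuntimeError, match="chains"):
            aggregate_and_flag([], np.array([1, 0]), t_percentile=99.0)

    def test_correct_phenotype_examples(self):
        out = correct_phenotype(np.array([1, 1, 0]), np.array([True, False, False]))
        assert np.array_equal(out.values, [0, 1, 0])
        out2 = correct_phenotype(np.array([1, 0, 1]), np.zeros(3, bool))
        assert np.array_equal(out2.values, [1, 0, 1])

    def test_flag_on_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            correct_phenotype(np.array([1, 0, 1]), np.array([False, True, False]))

    def test_case_conservation(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=50)
            if y.sum() in (0, 50):
                continue
            cases = np.flatnonzero(y == 1)
            flags = np.zeros(50, bool)
            flags[rng.choice(cases, size=rng.integers(0, cases.size + 1),
                             replace=False)] = True
            if flags.sum() == y.sum():
                flags[cases[0]] = False  # keep at least one case
            out = correct_phenotype(y, flags)
            assert out.n_cases + flags.sum() == y.sum()
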