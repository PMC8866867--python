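"""Logistic fits, joint 2df test, interaction test, stratum odds ratios, scans."""

import numpy as np
import pytest
from scipy import optimize, stats

import gxescreen as gx
from gxescreen.association import (DegenerateDesignError, STATUS_DEGENERATE,
                                   STATUS_OK)
from tests.conftest import make_cohort


def neg_loglik(beta, x, y):
    eta = x @ beta
    return -(y * eta - np.logaddexp(0.0, eta)).sum()


def numeric_ml_loglik(x, y):
    """Independent likelihood maximization via Nelder-Mead polish of BFGS."""
    res = optimize.minimize(neg_loglik, np.zeros(x.shape[1]), args=(x, y),
                            method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    res2 = optimize.minimize(neg_loglik, res.x, args=(x, y),
                             method="Nelder-Mead",
                             options={"xatol": 1e-12, "fatol": 1e-14,
                                      "maxiter": 5000})
    return -min(res.fun, res2.fun)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        x = np.ones((100, 1))
        fit = gx.fit_logistic(x, y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.log_likelihood == pytest.approx(100 * np.log(0.5), rel=1e-10)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # exposed: 30 cases / 10 controls; unexposed: 20 cases / 40 controls
        e = np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        fit = gx.fit_logistic(np.column_stack([np.ones(100), e]), y)
        assert fit.coefficients[1] == pytest.approx(np.log(6.0), abs=1e-8)

    def test_matches_statsmodels_on_noisy_design(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        x = np.column_stack([np.ones(200), rng.standard_normal((200, 3))])
        y = rng.binomial(1, 0.4, 200).astype(float)
        fit = gx.fit_logistic(x, y)
        ref = sm.Logit(y, x).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-5)

    def test_perfect_separation_flagged(self):
        x = np.column_stack([np.ones(20), np.r_[np.ones(10), np.zeros(10)]])
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = gx.fit_logistic(x, y)
        assert not fit.converged

    def test_collinear_column_named(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(30)
        x = np.column_stack([np.ones(30), a, 2 * a])
        y = rng.binomial(1, 0.5, 30).astype(float)
        with pytest.raises(DegenerateDesignError, match="collinear"):
            gx.fit_logistic(x, y)

    def test_one_class_outcome_rejected(self):
        with pytest.raises(DegenerateDesignError, match="single class"):
            gx.fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(8)
        y = rng.binomial(1, 0.5, 80).astype(float)
        xs = [np.column_stack([np.ones(80), rng.standard_normal((80, 2))])
              for _ in range(5)]
        bb, cb, llb, conv = gx.fit_logistic_batch(np.stack(xs), y)
        assert conv.all()
        for i, x in enumerate(xs):
            fit = gx.fit_logistic(x, y)
            np.testing.assert_allclose(bb[i], fit.coefficients, atol=1e-7)
            assert llb[i] == pytest.approx(fit.log_likelihood, abs=1e-8)


class TestJoint2dfTest:
    def _tiny_cohort(self):
        # 12 samples, covariate-free
        calls = np.array([[0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0, 1]])
        status = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        exposure = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        return make_cohort(calls, status, exposure)

    def test_monomorphic_variant_degenerate(self):
        calls = np.zeros((1, 12), dtype=int)
        cohort = make_cohort(calls, [1] * 6 + [0] * 6, [1, 0] * 6)
        lrt, p = gx.joint_2df_test(cohort, "v1", "alcohol")
        assert lrt is None and p is None

    def test_lrt_matches_numeric_maximization_oracle(self):
        cohort = self._tiny_cohort()
        lrt, p = gx.joint_2df_test(cohort, "v1", "alcohol")
        g = cohort.genotypes.calls[0].astype(float)
        y = cohort.samples.status.astype(float)
        e = cohort.samples.exposure("alcohol").astype(float)
        x_full = np.column_stack([np.ones(12), e, g, g * e])
        x_red = np.column_stack([np.ones(12), e])
        oracle = 2 * (numeric_ml_loglik(x_full, y) - numeric_ml_loglik(x_red, y))
        assert lrt == pytest.approx(oracle, abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(oracle, 2), abs=1e-6)

    def test_full_model_never_fits_worse(self):
        cohort = gx.simulate_cohort(gx.SimulationConfig(
            n_variants=30, n_cases=80, n_controls=80, seed=31))
        for v in cohort.genotypes.variants:
            lrt, _ = gx.joint_2df_test(cohort, v.id, "alcohol",
                                       cohort.samples.covariates())
            assert lrt is None or lrt >= 0


class TestInteractionTest:
    def test_constant_exposure_degenerate(self):
        calls = np.array([[0, 1, 2, 1, 0, 2, 1, 0]])
        cohort = make_cohort(calls, [1, 1, 1, 1, 0, 0, 0, 0], [0] * 8)
        with pytest.raises(DegenerateDesignError):
            gx.interaction_test(cohort, "v1", "alcohol")

    def test_equals_difference_of_stratum_slopes(self):
        rng = np.random.default_rng(17)
        n = 400
        g = rng.binomial(2, 0.35, n)
        e = rng.binomial(1, 0.5, n)
        logit = -0.3 + 0.2 * g + 0.8 * g * e
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        cohort = make_cohort(g[None, :], y, e)
        beta, se, p = gx.interaction_test(cohort, "v1", "alcohol")
        slopes = {}
        for s in (0, 1):
            sel = e == s
            fit = gx.fit_logistic(
                np.column_stack([np.ones(sel.sum()), g[sel]]), y[sel].astype(float))
            slopes[s] = fit.coefficients[1]
        assert beta == pytest.approx(slopes[1] - slopes[0], abs=1e-8)

    def test_wald_and_lrt_variants_agree_asymptotically(self):
        rng = np.random.default_rng(23)
        agree = 0
        for rep in range(300):
            n = 538
            g = rng.binomial(2, 0.3, n).astype(float)
            e = rng.binomial(1, 0.3, n).astype(float)
            y = rng.binomial(1, 0.6, n).astype(float)
            cohort = make_cohort(g[None, :].astype(int), y.astype(int),
                                 e.astype(int))
            try:
                _, _, p_w = gx.interaction_test(cohort, "v1", "alcohol")
                _, _, p_l = gx.interaction_test(cohort, "v1", "alcohol",
                                                method="lrt")
            except DegenerateDesignError:
                agree += 1
                continue
            agree += (p_w < 0.05) == (p_l < 0.05)
        assert agree >= 294  # >= 98% rejection agreement

    def test_reparameterization_identity(self):
        rng = np.random.default_rng(29)
        n = 600
        g = rng.binomial(2, 0.4, n)
        e = rng.binomial(1, 0.4, n)
        y = rng.binomial(1, 0.5, n)
        cohort = make_cohort(g[None, :], y, e)
        beta, _, _ = gx.interaction_test(cohort, "v1", "alcohol")
        or_e, or_u, _, _, _ = gx.stratum_specific_or(cohort, "v1", "alcohol")
        assert np.exp(beta) == pytest.approx(or_e / or_u, rel=1e-6)

    def test_pc_location_shift_leaves_pvalues_unchanged(self):
        rng = np.random.default_rng(37)
        n = 300
        g = rng.binomial(2, 0.3, n)
        e = rng.binomial(1, 0.4, n)
        y = rng.binomial(1, 0.5, n)
        cov = rng.standard_normal((n, 3))
        cohort = make_cohort(g[None, :], y, e)
        _, p1 = gx.joint_2df_test(cohort, "v1", "alcohol", cov)
        _, p2 = gx.joint_2df_test(cohort, "v1", "alcohol", cov + 7.5)
        assert p1 == pytest.approx(p2, abs=1e-8)
        _, _, q1 = gx.interaction_test(cohort, "v1", "alcohol", cov)
        _, _, q2 = gx.interaction_test(cohort, "v1", "alcohol", cov + 7.5)
        assert q1 == pytest.approx(q2, abs=1e-8)


class TestStratumSpecificOr:
    def test_identical_strata_give_equal_ors(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0] * 2)
        y = np.array([1, 1, 0, 1, 0, 1, 0, 0] * 2)
        e = np.r_[np.ones(8, int), np.zeros(8, int)]
        cohort = make_cohort(g[None, :], y, e)
        or_e, or_u, _, _, crossover = gx.stratum_specific_or(cohort, "v1", "alcohol")
        assert or_e == pytest.approx(or_u, rel=1e-6)
        assert not crossover

    def test_matches_one_parameter_grid_oracle(self):
        # per-genotype cases/controls: 10/20, 20/20, 20/10 in the exposed stratum
        g = np.repeat([0, 0, 1, 1, 2, 2], [10, 20, 20, 20, 20, 10])
        y = np.concatenate([np.ones(10), np.zeros(20), np.ones(20), np.zeros(20),
                            np.ones(20), np.zeros(10)]).astype(int)
        e = np.ones_like(g)
        e_extra = np.zeros(20, int)  # small unexposed stratum so the op is defined
        g2 = np.r_[g, np.tile([0, 1, 2, 1], 5)]
        y2 = np.r_[y, np.tile([1, 0, 1, 0], 5)]
        e2 = np.r_[e, e_extra]
        cohort = make_cohort(g2[None, :], y2, e2)
        or_e, _, _, _, _ = gx.stratum_specific_or(cohort, "v1", "alcohol")

        # grid oracle: profile the intercept at each candidate slope
        def prof_ll(slope):
            from scipy.optimize import minimize_scalar
            yy, gg = y.astype(float), g.astype(float)
            f = minimize_scalar(
                lambda b0: neg_loglik(np.array([b0, slope]),
                                      np.column_stack([np.ones_like(gg), gg]), yy),
                bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-12})
            return -f.fun

        grid = np.linspace(-1.0, 1.5, 2501)
        best = grid[np.argmax([prof_ll(s) for s in grid])]
        assert np.log(or_e) == pytest.approx(best, abs=2e-3)

    def test_empty_stratum_rejected(self):
        g = np.array([[0, 1, 2, 1, 0, 2]])
        cohort = make_cohort(g, [1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 1, 1])
        with pytest.raises(DegenerateDesignError):
            gx.stratum_specific_or(cohort, "v1", "alcohol")


class TestGenomeScan:
    def test_null_scan_complete_and_statused(self):
        cohort = gx.simulate_cohort(gx.SimulationConfig(
            n_variants=100, n_cases=120, n_controls=100, seed=43))
        results = gx.genome_scan(cohort, "alcohol",
                                 covariates=cohort.samples.covariates())
        assert len(results) == 100
        for r in results:
            assert r.status in (STATUS_OK, STATUS_DEGENERATE)
            if r.status == STATUS_OK:
                assert r.p_joint is not None and 0 <= r.p_joint <= 1

    def test_scan_is_deterministic(self):
        cohort = gx.simulate_cohort(gx.SimulationConfig(
            n_variants=40, n_cases=80, n_controls=70, seed=47))
        a = gx.genome_scan(cohort, "alcohol", exhaustive=True)
        b = gx.genome_scan(cohort, "alcohol", exhaustive=True)
        for ra, rb in zip(a, b):
            assert (ra.p_joint, ra.p_GE, ra.beta_GE) == (rb.p_joint, rb.p_GE,
                                                         rb.beta_GE)

    def test_scan_matches_single_variant_path(self):
        cohort = gx.simulate_cohort(gx.SimulationConfig(
            n_variants=15, n_cases=100, n_controls=90, seed=53))
        cov = cohort.samples.covariates()
        results = gx.genome_scan(cohort, "alcohol", covariates=cov,
                                 exhaustive=True)
        for r in results[:5]:
            lrt, p = gx.joint_2df_test(cohort, r.variant.id, "alcohol", cov)
            assert r.lrt_joint == pytest.approx(lrt, abs=1e-6)
            beta, se, pge = gx.interaction_test(cohort, r.variant.id, "alcohol", cov)
            assert r.beta_GE == pytest.approx(beta, abs=1e-6)
            assert r.p_GE == pytest.approx(pge, abs=1e-6)

    def test_scan_handles_missing_calls(self):
        cohort = gx.simulate_cohort(gx.SimulationConfig(
            n_variants=10, n_cases=90, n_controls=80, seed=59))
        noisy = gx.attach_imputation_artifacts(cohort, soft_fraction=0.15, seed=60)
        filtered, _ = gx.apply_variant_filters(
            noisy, gx.QcThresholds(hwe_alpha=0.0, maf_min=0.0, quality_min=0.0))
        assert (filtered.genotypes.calls == gx.MISSING).any()
        cov = filtered.samples.covariates()
        results = gx.genome_scan(filtered, "alcohol", covariates=cov,
                                 exhaustive=True)
        for r in results:
            if r.status != STATUS_OK:
                continue
            lrt, _ = gx.joint_2df_test(filtered, r.variant.id, "alcohol", cov)
            assert r.lrt_joint == pytest.approx(lrt, abs=1e-6)
            assert r.n_used == int((filtered.genotypes.calls[
                [v.id for v in filtered.genotypes.variants].index(r.variant.id)]
                != gx.MISSING).sum())

    def test_strong_interaction_ranks_first(self):
        hits = 0
        for rep in range(100):
            cfg = gx.SimulationConfig(
                n_variants=100, n_cases=344, n_controls=194, n_pcs=0,
                maf_range=(0.2, 0.5),
                causal_effects={"var000050": (0.0, 1.5)}, seed=70_000 + rep)
            cohort = gx.simulate_cohort(cfg)
            results = gx.genome_scan(cohort, "alcohol", exhaustive=True)
            ok = [r for r in results if r.status == STATUS_OK and r.p_GE is not None]
            best = min(ok, key=lambda r: r.p_GE)
            hits += best.variant.id == "var000050"
        assert hits >= 95
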