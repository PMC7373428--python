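"""Survival suite: KM/log-rank, Buckley-James AFT, the rescaling K-S test,
Weibull-Gamma frailty models, model selection, GOF, meta-analysis, hazards."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ironage.simulate import ArmSpec, LifespanSimConfig, gen_lifespan
from ironage.survival import (
    fisher_combine,
    fit_buckley_james,
    fit_weibull_gamma,
    gof_chisq,
    hazard_curve,
    km_curve,
    ks_rescaling_test,
    logrank,
    lrt_select,
    meta_combine,
    weibull_gamma_hazard,
    weibull_gamma_survival,
)


def _cohort(times, events, arm="a"):
    return pd.DataFrame({"day": times, "event": events,
                         "arm": [arm] * len(times)})


class TestKaplanMeier:
    def test_median_smallest_t_convention(self):
        c = _cohort(np.arange(1.0, 11.0), np.ones(10, int))
        assert km_curve(c).median == 5.0

    def test_time_scaling_equivariance(self):
        c = _cohort(np.arange(1.0, 11.0), np.ones(10, int))
        c2 = c.assign(day=c["day"] * 2)
        assert km_curve(c2).median == 2 * km_curve(c).median

    def test_all_censored_flagged(self):
        c = _cohort([3.0, 4.0], [0, 0])
        with pytest.raises(ValueError, match="event"):
            km_curve(c)

    def test_heavy_censoring_median_undefined(self):
        c = _cohort([1.0, 5.0, 5.0, 5.0, 5.0], [1, 0, 0, 0, 0])
        curve = km_curve(c)
        assert not curve.median_defined


class TestLogrank:
    def test_identical_arms_no_signal(self):
        base = _cohort(np.arange(1.0, 21.0), np.ones(20, int), arm="a")
        dup = base.assign(arm="b")
        chi2, df, p = logrank(pd.concat([base, dup], ignore_index=True))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1 and p == pytest.approx(1.0)

    def test_separated_arms_detected(self):
        arms = [ArmSpec("ctl"), ArmSpec("trt", lam=2.0)]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=200, seed=1))
        chi2, df, p = logrank(cohort)
        assert p < 0.001

    def test_single_arm_rejected(self):
        c = _cohort([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="two arms"):
            logrank(c)


class TestBuckleyJames:
    def test_reduces_to_ols_without_censoring(self):
        arms = [ArmSpec("ctl"), ArmSpec("trt", lam=1.5)]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=150, seed=2))
        fit = fit_buckley_james(cohort)
        y = np.log(cohort["day"].to_numpy())
        X = np.column_stack([np.ones(len(y)),
                             (cohort["arm"] == "trt").to_numpy(float)])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.coef, beta_ols, rtol=1e-12)
        assert fit.iterations == 1

    def test_matches_hand_iterated_oracle(self):
        # 5 observations, one censored; independent step-by-step iteration
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 1, 0, 1, 1])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        y = np.log(times)

        # --- oracle: explicit Buckley-James loop written independently ---
        def km_tail_mean(res, ev, c):
            """E[e | e > c] under KM of (res, ev), largest point an event."""
            order = np.argsort(res)
            r, d = res[order], ev[order].copy()
            d[-1] = 1
            n = len(r)
            surv = 1.0
            jumps = []
            for i in range(n):
                s_before = surv
                if d[i]:
                    surv *= 1 - 1 / (n - i)
                jumps.append((r[i], s_before - surv))
            tail = [(rj, mj) for rj, mj in jumps if rj > c]
            mass = sum(m for _, m in tail)
            return sum(r * m for r, m in tail) / mass if mass > 0 else c

        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for _ in range(200):
            res = y - X @ beta
            y_imp = y.copy()
            for i in np.flatnonzero(events == 0):
                y_imp[i] = (X @ beta)[i] + km_tail_mean(res, events, res[i])
            new = np.linalg.lstsq(X, y_imp, rcond=None)[0]
            if np.max(np.abs(new - beta)) < 1e-10:
                beta = new
                break
            beta = new
        # --- end oracle ---

        cohort = pd.DataFrame({"day": times, "event": events,
                               "arm": np.where(x > 0, "b", "a")})
        fit = fit_buckley_james(cohort, tol=1e-10)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-8)

    def test_pure_scaling_coefficient_is_log_lambda(self):
        lam = 1.7
        arms = [ArmSpec("ctl"), ArmSpec("trt", lam=lam)]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=1000, seed=3))
        fit = fit_buckley_james(cohort)
        assert fit.coef[1] == pytest.approx(np.log(lam), abs=0.05)

    def test_censored_fit_converges(self):
        arms = [ArmSpec("ctl"), ArmSpec("trt", lam=1.5)]
        cohort, _ = gen_lifespan(LifespanSimConfig(
            arms=arms, n_per_arm=300, censor_day=12.0, seed=4))
        assert (cohort["event"] == 0).any()
        fit = fit_buckley_james(cohort)
        assert fit.converged
        # the scaling coefficient survives right-censoring
        assert fit.coef[1] == pytest.approx(np.log(1.5), abs=0.1)


class TestRescalingTest:
    def test_null_not_rejected_for_identical_arms(self):
        base = _cohort(np.exp(np.random.default_rng(5).normal(2, 0.3, 120)),
                       np.ones(120, int), arm="a")
        c = pd.concat([base, base.assign(arm="b")], ignore_index=True)
        res = ks_rescaling_test(c, n_perm=300, seed=6)
        assert res.p >= 0.05

    def test_pure_scaling_not_rejected(self):
        arms = [ArmSpec("ctl"), ArmSpec("trt", lam=2.0)]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=300, seed=7))
        res = ks_rescaling_test(cohort, n_perm=300, seed=8)
        assert res.p > 0.05

    def test_shape_departure_detected(self):
        arms = [ArmSpec("ctl"),
                ArmSpec("trt", lam=1.5, dlog_k=np.log(2.0))]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=300, seed=9))
        res = ks_rescaling_test(cohort, n_perm=300, seed=10)
        assert res.p < 0.05

    def test_temperature_scaling_not_rejected(self):
        # temperature acting as a pure time rescaler: no departure signal
        arms = [ArmSpec("c20"), ArmSpec("c25", lam=0.55)]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=300, seed=11))
        res = ks_rescaling_test(cohort, n_perm=300, seed=12)
        assert res.p > 0.05

    def test_requires_two_arms_and_event_flags(self):
        c = _cohort([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="two arms"):
            ks_rescaling_test(c)
        c2 = pd.DataFrame({"day": [1.0, 2.0], "arm": ["a", "b"]})
        with pytest.raises(ValueError, match="event"):
            ks_rescaling_test(c2)

    def test_low_n_perm_warns(self):
        arms = [ArmSpec("a"), ArmSpec("b")]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=30, seed=13))
        with pytest.warns(UserWarning, match="n_perm"):
            ks_rescaling_test(cohort, n_perm=50, seed=14)

    def test_fisher_combination_matches_scipy(self):
        p = [0.02, 0.4, 0.11, 0.8]
        chi2, df, comb = fisher_combine(p)
        ref = sps.combine_pvalues(p, method="fisher")
        assert chi2 == pytest.approx(ref.statistic)
        assert comb == pytest.approx(ref.pvalue)


class TestWeibullGamma:
    def test_marginal_survival_closed_form(self):
        # sigma2 = 1, k = 1, b = 1: S(t) = 1/(1+t), so S(2) = 1/3
        assert weibull_gamma_survival(2.0, 1.0, 1.0, 1.0) == pytest.approx(
            1.0 / 3.0, rel=1e-9)

    def test_sigma2_floor_is_weibull_limit(self):
        t = np.linspace(0.5, 20, 50)
        s_floor = weibull_gamma_survival(t, 10.0, 3.0, 1e-12)
        s_weib = np.exp(-(t / 10.0) ** 3)
        np.testing.assert_allclose(s_floor, s_weib, rtol=1e-6)

    def test_pure_weibull_data_recovery(self):
        cohort, _ = gen_lifespan(LifespanSimConfig(
            arms=[ArmSpec("a", k=3.0, b=9.0, sigma2=0.0)],
            n_per_arm=2000, seed=15))
        fit = fit_weibull_gamma(cohort)
        assert np.exp(fit.params["log_k"]) == pytest.approx(3.0, rel=0.05)
        assert np.exp(fit.params["log_b"]) == pytest.approx(9.0, rel=0.05)
        assert np.exp(fit.params["log_sigma2"]) < 0.05

    def test_frailty_recovery_mean_over_seeds(self):
        # sigma2 has sizeable per-fit sampling noise; its MLE is checked as
        # a mean over seeds
        ks, bs, s2s = [], [], []
        for seed in (16, 17, 18):
            cohort, _ = gen_lifespan(LifespanSimConfig(
                arms=[ArmSpec("a", k=4.0, b=10.0, sigma2=0.5)],
                n_per_arm=2000, seed=seed))
            f = fit_weibull_gamma(cohort)
            ks.append(np.exp(f.params["log_k"]))
            bs.append(np.exp(f.params["log_b"]))
            s2s.append(np.exp(f.params["log_sigma2"]))
        assert np.mean(ks) == pytest.approx(4.0, rel=0.1)
        assert np.mean(bs) == pytest.approx(10.0, rel=0.1)
        assert np.mean(s2s) == pytest.approx(0.5, rel=0.15)

    def test_departure_spec_must_include_scaling(self):
        cohort, _ = gen_lifespan(LifespanSimConfig(
            arms=[ArmSpec("a")], n_per_arm=50, seed=19))
        with pytest.raises(ValueError, match="dlog_b"):
            fit_weibull_gamma(cohort, departures=("dlog_k",))


@pytest.fixture(scope="module")
def two_arm_scaling_cohort():
    arms = [ArmSpec("ctl", sigma2=0.3), ArmSpec("trt", sigma2=0.3, lam=1.6)]
    cohort, _ = gen_lifespan(
        LifespanSimConfig(arms=arms, n_per_arm=500, seed=20))
    return cohort


class TestModelSelection:
    def test_scaling_only_selected_under_pure_scaling(
            self, two_arm_scaling_cohort):
        c = two_arm_scaling_cohort
        fits = [fit_weibull_gamma(c, departures=d) for d in
                (("dlog_b",), ("dlog_b", "dlog_k"),
                 ("dlog_b", "dlog_k", "dlog_sigma2"))]
        best, table = lrt_select(fits)
        assert best.model_label == "scaling-only"

    def test_frailty_departure_detected(self):
        arms = [ArmSpec("ctl", sigma2=0.8),
                ArmSpec("trt", sigma2=0.8, lam=1.6, dlog_sigma2=-2.0)]
        cohort, _ = gen_lifespan(
            LifespanSimConfig(arms=arms, n_per_arm=500, seed=21))
        fits = [fit_weibull_gamma(cohort, departures=d) for d in
                (("dlog_b",), ("dlog_b", "dlog_sigma2"))]
        best, _ = lrt_select(fits)
        assert best.model_label == "+frailty"
        assert best.params["dlog_sigma2[trt]"] < 0

    def test_tie_breaks_to_simpler_model(self, two_arm_scaling_cohort):
        c = two_arm_scaling_cohort
        f1 = fit_weibull_gamma(c, departures=("dlog_b",))
        f2 = fit_weibull_gamma(c, departures=("dlog_b", "dlog_k"))
        f2.loglik = f1.loglik  # forced tie
        best, _ = lrt_select([f1, f2])
        assert best is f1

    def test_different_data_rejected(self, two_arm_scaling_cohort):
        c = two_arm_scaling_cohort
        f1 = fit_weibull_gamma(c, departures=("dlog_b",))
        f2 = fit_weibull_gamma(c.iloc[:-10], departures=("dlog_b", "dlog_k"))
        with pytest.raises(ValueError, match="identical data"):
            lrt_select([f1, f2])


class TestGoodnessOfFit:
    def test_model_quantile_data_gives_zero_chi2(self):
        # times placed at exact equal-probability quantiles of the model:
        # observed equals expected in every bin
        b, k, s2 = 8.0, 3.0, 0.4
        n_bins, per_bin = 5, 20
        u = (np.arange(n_bins * per_bin) + 0.5) / (n_bins * per_bin)
        # invert S(t): t = b * (((1-u)^(-s2) - 1)/s2)^(1/k)
        t = b * (((1 - u) ** (-s2) - 1) / s2) ** (1 / k)
        cohort = pd.DataFrame({"day": t, "event": 1, "arm": "a"})
        fit = fit_weibull_gamma(cohort)
        fit.params.update({"log_b": np.log(b), "log_k": np.log(k),
                           "log_sigma2": np.log(s2)})
        chi2, df, p = gof_chisq(fit, cohort, n_bins=n_bins)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == n_bins - 1

    def test_well_specified_model_not_rejected(self):
        cohort, _ = gen_lifespan(LifespanSimConfig(
            arms=[ArmSpec("a", k=4.0, b=9.0, sigma2=0.3)],
            n_per_arm=800, seed=22))
        fit = fit_weibull_gamma(cohort)
        chi2, df, p = gof_chisq(fit, cohort, n_bins=6)
        assert p > 0.01

    def test_misspecified_model_rejected(self):
        # bimodal mixture cannot be a Weibull-Gamma marginal
        rng = np.random.default_rng(23)
        t = np.concatenate([rng.normal(4, 0.3, 500),
                            rng.normal(16, 0.3, 500)])
        cohort = pd.DataFrame({"day": np.clip(t, 0.1, None), "event": 1,
                               "arm": "a"})
        fit = fit_weibull_gamma(cohort)
        chi2, df, p = gof_chisq(fit, cohort, n_bins=8)
        assert p < 0.001

    def test_too_few_events_rejected(self):
        cohort = pd.DataFrame({"day": np.linspace(1, 10, 12), "event": 1,
                               "arm": "a"})
        fit_params = {"log_b": np.log(5.0), "log_k": 0.0,
                      "log_sigma2": np.log(0.2)}
        from ironage.survival import WeibullGammaFit
        fit = WeibullGammaFit(params=fit_params, loglik=0.0, covariance=None,
                              param_names=list(fit_params),
                              model_label="scaling-only", arms=["a"],
                              converged=True, n=12)
        with pytest.raises(ValueError, match="bins"):
            gof_chisq(fit, cohort, n_bins=2)


class TestMetaAnalysis:
    def test_fixed_effect_closed_form(self):
        m = meta_combine([1.0, 2.0], [0.04, 0.04])
        assert m.fixed_effect == pytest.approx(1.5, rel=1e-12)
        assert m.fixed_se ** 2 == pytest.approx(0.02, rel=1e-12)

    def test_homogeneous_inputs_tau2_zero(self):
        m = meta_combine([1.3] * 5, [0.1] * 5)
        assert m.tau2 == 0.0
        assert m.random_effect == pytest.approx(m.fixed_effect)

    def test_fixed_effect_within_input_range(self):
        rng = np.random.default_rng(24)
        th = rng.normal(0, 1, 8)
        v = rng.uniform(0.01, 0.5, 8)
        m = meta_combine(th, v)
        assert th.min() <= m.fixed_effect <= th.max()

    def test_heterogeneity_recovered(self):
        # replicates drawn with true tau2: DL estimate close on average
        rng = np.random.default_rng(25)
        tau2_true, v = 0.1, 0.02
        est = []
        for _ in range(300):
            th = rng.normal(0, np.sqrt(tau2_true), 8) \
                + rng.normal(0, np.sqrt(v), 8)
            est.append(meta_combine(th, [v] * 8).tau2)
        assert np.mean(est) == pytest.approx(tau2_true, rel=0.2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            meta_combine([1.0, 2.0], [0.0, 0.1])


class TestHazardCurve:
    def test_exponential_data_flat_hazard(self):
        rng = np.random.default_rng(26)
        t = rng.exponential(8.0, 3000)
        cohort = pd.DataFrame({"day": t, "event": 1, "arm": "a"})
        hc = hazard_curve(cohort, bandwidth=2.0, seed=1)
        sel = (hc.ages > 2) & (hc.ages < 12)
        true_h = 1.0 / 8.0
        assert np.all(hc.ci_lower[sel] < true_h)
        assert np.all(hc.ci_upper[sel] > true_h)

    def test_frailty_hazard_decelerates(self):
        # strong frailty: population hazard rises then declines, tracking the
        # analytic marginal hazard
        b, k, s2 = 8.0, 3.0, 1.0
        cohort, _ = gen_lifespan(LifespanSimConfig(
            arms=[ArmSpec("a", k=k, b=b, sigma2=s2)], n_per_arm=6000,
            seed=27))
        hc = hazard_curve(cohort, bandwidth=1.0, seed=2)
        sel = hc.ages < 25
        peak_age = hc.ages[sel][np.nanargmax(hc.hazard[sel])]
        analytic = weibull_gamma_hazard(hc.ages[sel], b, k, s2)
        analytic_peak = hc.ages[sel][np.argmax(analytic)]
        assert abs(peak_age - analytic_peak) < 3.0
        # deceleration: hazard well past the peak is below the peak value
        late = hc.ages[sel] > analytic_peak + 5
        assert np.nanmax(hc.hazard[sel][late]) < np.nanmax(hc.hazard[sel])

    def test_time_scaling_halves_hazard(self):
        rng = np.random.default_rng(28)
        t = rng.weibull(3.0, 4000) * 8.0
        c1 = pd.DataFrame({"day": t, "event": 1, "arm": "a"})
        c2 = pd.DataFrame({"day": 2 * t, "event": 1, "arm": "a"})
        h1 = hazard_curve(c1, bandwidth=0.8, n_boot=0, seed=3)
        h2 = hazard_curve(c2, bandwidth=1.6, n_boot=0, seed=3)
        # compare h2(2t) ~ h1(t)/2 at a mid-range age
        age = 8.0
        i1 = np.argmin(np.abs(h1.ages - age))
        i2 = np.argmin(np.abs(h2.ages - 2 * age))
        assert h2.hazard[i2] == pytest.approx(h1.hazard[i1] / 2, rel=0.2)

    def test_bad_bandwidth_rejected(self):
        c = pd.DataFrame({"day": np.linspace(1, 10, 30), "event": 1,
                          "arm": "a"})
        with pytest.raises(ValueError, match="bandwidth"):
            hazard_curve(c, bandwidth=0.0)
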