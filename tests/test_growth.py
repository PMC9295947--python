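"""Model fitting, BIC selection, bands, separation, and rate-of-change fits."""

import numpy as np
import pytest
from scipy import optimize

from placenorm import (CohortConfig, band_separation, cohort_rate_pairs,
                       evaluate_model, fit_model, fit_rate_model, rate_pairs,
                       select_model_bic, simulate_cohort)
from placenorm.growth import GestationalModel
from placenorm.reference import RATE_SIGMOID_DERIVATIVE, T2STAR_SIGMOID

UN_PARAMS, UN_SD = T2STAR_SIGMOID["UN"]
UN_RATE_PARAMS = RATE_SIGMOID_DERIVATIVE["UN"][0]


class TestFitModel:
    def test_constant_data_fits_exactly(self):
        t = np.linspace(10, 40, 20)
        fit = fit_model(t, np.full(20, 5.0), "constant")
        assert fit.params[0] == pytest.approx(5.0)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_sigmoid_recovery_at_study_noise(self, un_sigmoid_sample):
        """Inflection week and late offset recovered within 3x the reference
        parameter uncertainties (0.8 wk and 1.3 ms) at n=500, SD 9.6 ms."""
        t, y = un_sigmoid_sample
        fit = fit_model(t, y, "sigmoid", random_state=0)
        assert fit.converged
        assert fit.params[2] == pytest.approx(29.3, abs=3 * 0.8)
        assert fit.params[3] == pytest.approx(84.6, abs=3 * 1.3)
        assert fit.rms_residual == pytest.approx(9.6, rel=0.10)

    def test_sigmoid_matches_multistart_simplex_oracle(self, un_sigmoid_sample):
        """Derivative-free Nelder-Mead refits from 50 random starts never find
        a better optimum; the best simplex parameters agree to 1e-3 relative."""
        t, y = un_sigmoid_sample
        fit = fit_model(t, y, "sigmoid", random_state=0)

        def sse(p):
            return float(np.sum((evaluate_model("sigmoid", p, t) - y) ** 2))

        rng = np.random.default_rng(1)
        best = None
        for _ in range(50):
            x0 = np.array([rng.uniform(-120, -10), rng.uniform(-0.6, -0.05),
                           rng.uniform(15, 38), rng.uniform(60, 110)])
            res = optimize.minimize(sse, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        assert sse(fit.params) <= best.fun * (1 + 1e-9)
        assert np.allclose(fit.params, best.x, rtol=1e-3)

    def test_parameter_recovery_is_unbiased_across_replicates(self):
        """Over 200 seeded replicates at study scale, the mean recovered
        inflection week is within 0.3 wk of truth and its spread is within a
        factor 3 of the reference uncertainty."""
        p3s = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            t = rng.uniform(11, 38, 500)
            y = evaluate_model("sigmoid", UN_PARAMS, t) + rng.normal(0, UN_SD, 500)
            p3s.append(fit_model(t, y, "sigmoid", multistart=3, random_state=rep).params[2])
        p3s = np.asarray(p3s)
        assert abs(p3s.mean() - 29.3) < 0.3
        assert p3s.std(ddof=1) < 3 * 0.8

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            GestationalModel([1, 2, 3], [1, 2, 3], form="sigmoid")


class TestModelSelection:
    def test_sigmoid_preferred_on_sigmoid_data(self, un_sigmoid_sample):
        t, y = un_sigmoid_sample
        best, fits = select_model_bic(t, y, random_state=0)
        assert best.spec.form == "sigmoid"
        assert set(fits) == {"constant", "linear", "quadratic", "cubic", "sigmoid"}

    def test_linear_preferred_on_linear_data(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(11, 38, 500)
        y = 10.0 - 0.5 * t + rng.normal(0, 2.0, 500)
        best, fits = select_model_bic(t, y, candidates=("linear", "sigmoid"), random_state=0)
        assert best.spec.form == "linear"
        assert fits["linear"].bic < fits["sigmoid"].bic

    def test_noiseless_constant_selects_constant(self):
        t = np.linspace(10, 40, 50)
        best, _ = select_model_bic(t, np.full(50, 7.0),
                                   candidates=("constant", "linear", "quadratic"))
        assert best.spec.form == "constant"

    def test_nested_polynomials_never_increase_rss(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(10, 40, 200)
        y = 3.0 + 0.5 * t - 0.01 * t**2 + rng.normal(0, 1, 200)
        rss = [fit_model(t, y, f).rms_residual ** 2 * 200
               for f in ("constant", "linear", "quadratic", "cubic")]
        assert all(b <= a + 1e-9 for a, b in zip(rss, rss[1:]))


class TestBands:
    def test_band_ordering_everywhere(self, un_sigmoid_sample):
        t, y = un_sigmoid_sample
        band = fit_model(t, y, "sigmoid", random_state=0).confidence_band()
        assert np.all(band.pi_lo <= band.ci_lo)
        assert np.all(band.ci_lo <= band.mean)
        assert np.all(band.mean <= band.ci_hi)
        assert np.all(band.ci_hi <= band.pi_hi)

    def test_ci_shrinks_and_pi_approaches_residual_limit_at_large_n(self):
        rng = np.random.default_rng(11)
        t = rng.uniform(11, 38, 50000)
        y = evaluate_model("sigmoid", UN_PARAMS, t) + rng.normal(0, UN_SD, 50000)
        fit = fit_model(t, y, "sigmoid", multistart=2, random_state=0)
        band = fit.confidence_band()
        ci_half = (band.ci_hi - band.ci_lo) / 2
        pi_half = (band.pi_hi - band.pi_lo) / 2
        assert ci_half.max() < 0.2 * UN_SD
        assert np.allclose(pi_half, 1.959963984540054 * np.sqrt(fit.resid_var), rtol=0.02)

    def test_ci_agrees_with_parametric_bootstrap(self):
        """Delta-method CI half-width at the inflection matches a 2000-draw
        parametric bootstrap quantile band within 15%."""
        rng = np.random.default_rng(21)
        t = rng.uniform(11, 38, 120)
        y = evaluate_model("sigmoid", UN_PARAMS, t) + rng.normal(0, UN_SD, 120)
        fit = fit_model(t, y, "sigmoid", random_state=0)
        grid = np.array([29.3])
        band = fit.confidence_band(grid)
        half = float(band.ci_hi[0] - band.mean[0])

        mu = fit.predict(t)
        sd = np.sqrt(fit.resid_var)
        boot = []
        for b in range(2000):
            brng = np.random.default_rng(50_000 + b)
            yb = mu + brng.normal(0, sd, t.size)
            boot.append(fit_model(t, yb, "sigmoid", multistart=0, random_state=0).predict(grid)[0])
        lo, hi = np.percentile(boot, [2.5, 97.5])
        boot_half = (hi - lo) / 2
        assert half == pytest.approx(boot_half, rel=0.15)


class TestBandSeparation:
    def test_identical_fits_never_separate(self, un_sigmoid_sample):
        t, y = un_sigmoid_sample
        fit = fit_model(t, y, "sigmoid", random_state=0)
        assert band_separation(fit, fit) == []

    def test_distant_constants_separate_everywhere(self):
        rng = np.random.default_rng(3)
        t = np.linspace(10, 40, 200)
        fa = fit_model(t, 50 + rng.normal(0, 1, 200), "constant")
        fb = fit_model(t, 60 + rng.normal(0, 1, 200), "constant")
        intervals = band_separation(fa, fb)
        assert intervals == [(10.0, 40.0)]

    def test_un_vs_pa_separates_in_mid_gestation(self):
        """Curves regenerated from the reference UN and PA sigmoid models at
        study scale separate over a mid-gestation interval inside [10, 40]."""
        cfg = CohortConfig(n_subjects=316, seed=77)
        df = simulate_cohort(cfg)
        fits = {}
        for g in ("UN", "PA"):
            sub = df[df["group"] == g]
            fits[g] = fit_model(sub["ga_weeks"], sub["t2star_ms"], "sigmoid", random_state=0)
        intervals = band_separation(fits["UN"], fits["PA"])
        assert intervals, "expected a separation interval"
        lo = min(i[0] for i in intervals)
        hi = max(i[1] for i in intervals)
        assert 10.0 <= lo < hi <= 40.0
        # mid-gestation is covered
        assert any(a <= 22 and b >= 26 for a, b in intervals)


class TestRatePairs:
    def test_pair_arithmetic(self):
        pairs = rate_pairs([20.0, 30.0], [80.0, 50.0])
        assert pairs.tolist() == [[25.0, -3.0]]

    def test_three_scans_give_two_pairs(self):
        pairs = rate_pairs([12.0, 27.0, 33.0], [80.0, 60.0, 40.0])
        assert pairs.shape == (2, 2)

    def test_duplicate_gestational_age_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rate_pairs([20.0, 20.0], [80.0, 70.0])

    def test_noiseless_rates_bracketed_by_analytic_derivative(self):
        # mean value theorem: each finite-difference rate equals the
        # derivative somewhere inside the interval, so it lies within the
        # derivative's range over that interval
        p1, p2, p3, p4 = UN_PARAMS
        ts = np.array([14.0, 26.5, 33.0])
        ys = evaluate_model("sigmoid", UN_PARAMS, ts)
        pairs = rate_pairs(ts, ys)
        for (t1, t2), (_, rate) in zip(zip(ts[:-1], ts[1:]), pairs):
            grid = np.linspace(t1, t2, 500)
            d = evaluate_model("sigmoid_derivative", (p1, p2, p3), grid)
            assert d.min() - 1e-9 <= rate <= d.max() + 1e-9


class TestRateModel:
    def test_noiseless_dense_pairs_fit_exactly(self):
        t = np.linspace(11, 38, 200)
        y = evaluate_model("sigmoid_derivative", UN_RATE_PARAMS, t)
        fit = fit_rate_model(np.column_stack([t, y]), random_state=0)
        assert fit.rms_residual ** 2 * t.size < 1e-8

    def test_inflection_recovered_from_simulated_subjects(self):
        """Rate pairs from 300 simulated 2-3-scan subjects recover the
        reference rate-model inflection 30.1 wk within 3x its 0.6 wk
        uncertainty."""
        cfg = CohortConfig(
            n_subjects=300, group_probs=(1.0, 0.0, 0.0),
            scans_per_subject_probs=(0.0, 0.233, 0.767), seed=99,
        )
        pairs = cohort_rate_pairs(simulate_cohort(cfg))
        assert len(pairs) >= 10
        fit = fit_rate_model(pairs, random_state=0)
        assert fit.params[2] == pytest.approx(30.1, abs=3 * 0.6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_rate_model(np.zeros((5, 2)))


def test_fit_roundtrips_through_json(tmp_path, un_sigmoid_sample):
    t, y = un_sigmoid_sample
    fit = fit_model(t, y, "sigmoid", random_state=0)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    from placenorm import GestationalFit
    back = GestationalFit.from_json(path)
    assert back.spec.form == "sigmoid"
    assert np.allclose(back.params, fit.params)
    assert np.allclose(back.cov_params, fit.cov_params)
    assert back.bic == pytest.approx(fit.bic)
    assert "sigmoid" in fit.summary()
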