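import numpy as np
import pytest

from peroxevo.kinetics import (KineticCurve, KineticsError, StabilityCurve,
                               catalytic_efficiency, fit_michaelis_menten,
                               fit_two_site, fold_change, generate_melting_curve,
                               generate_mm_curve, generate_t50_curve,
                               generate_two_site_curve, rate_from_absorbance,
                               relative_efficiency_profile,
                               residual_activity_profile, round_sig,
                               select_kinetic_model, t50_from_curve,
                               tm_from_melting)


class TestRateConversion:
    def test_beer_lambert_worked_example(self):
        # Mn3+-tartrate at 238 nm, eps 6500: dA 0.0065/s, 0.1 uM enzyme -> 10/s
        assert rate_from_absorbance(0.0065, 6500, 1.0, 0.1) == pytest.approx(10.0)

    def test_doubling_enzyme_halves_turnover(self):
        a = rate_from_absorbance(0.01, 9300, 1.0, 0.1)
        b = rate_from_absorbance(0.01, 9300, 1.0, 0.2)
        assert a == pytest.approx(2 * b)

    def test_zero_epsilon_rejected(self):
        with pytest.raises(KineticsError):
            rate_from_absorbance(0.01, 0.0, 1.0, 0.1)


class TestMichaelisMenten:
    def test_noiseless_recovery_is_exact(self):
        fit = fit_michaelis_menten(generate_mm_curve(62.0, 106.0))
        assert fit.km[0] == pytest.approx(62.0, rel=1e-6)
        assert fit.kcat[0] == pytest.approx(106.0, rel=1e-6)
        assert fit.efficiency[0] == pytest.approx(1000 * 106 / 62, rel=1e-6)

    def test_noisy_recovery_median_error(self):
        km_err, kcat_err = [], []
        for seed in range(20):
            curve = generate_mm_curve(62.0, 106.0, noise_sd_frac=0.02,
                                      replicates=3, seed=seed)
            fit = fit_michaelis_menten(curve)
            km_err.append(abs(fit.km[0] - 62.0) / 62.0)
            kcat_err.append(abs(fit.kcat[0] - 106.0) / 106.0)
        assert np.median(km_err) < 0.05 and np.median(kcat_err) < 0.05

    def test_grid_search_sse_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            km, kcat = rng.uniform(10, 500), rng.uniform(5, 200)
            curve = generate_mm_curve(km, kcat, noise_sd_frac=0.03, seed=1)
            fit = fit_michaelis_menten(curve)
            kms = np.geomspace(km / 3, km * 3, 240)
            kcats = np.linspace(kcat * 0.5, kcat * 1.5, 240)
            sse = np.array([[np.sum((curve.v - kc * curve.s / (k + curve.s)) ** 2)
                             for k in kms] for kc in kcats])
            i, j = np.unravel_index(sse.argmin(), sse.shape)
            assert fit.rss <= sse[i, j] * 1.005

    def test_too_few_points(self):
        with pytest.raises(KineticsError, match="5 distinct"):
            fit_michaelis_menten(KineticCurve([1, 2, 3, 4], [1, 2, 2.5, 3]))

    def test_unsaturated_curve_warns(self):
        curve = generate_mm_curve(1000.0, 10.0,
                                  concentrations=np.linspace(1, 50, 8))
        fit = fit_michaelis_menten(curve)
        assert any("not saturated" in w for w in fit.warnings)


class TestTwoSite:
    def test_noiseless_biphasic_recovery(self):
        # the high/low efficiency DMP sites of the ancestral VP
        curve = generate_two_site_curve(5.3, 4.5, 32500.0, 31.0)
        fit = fit_two_site(curve)
        assert fit.km[0] == pytest.approx(5.3, rel=0.01)
        assert fit.kcat[0] == pytest.approx(4.5, rel=0.01)
        assert fit.km[1] == pytest.approx(32500.0, rel=0.01)
        assert fit.kcat[1] == pytest.approx(31.0, rel=0.01)

    def test_sites_ordered_by_km(self):
        fit = fit_two_site(generate_two_site_curve(32500.0, 31.0, 5.3, 4.5))
        assert fit.km[0] < fit.km[1]

    def test_single_site_data_prefers_single_model(self):
        curve = generate_mm_curve(62.0, 106.0,
                                  concentrations=np.geomspace(5, 2000, 12),
                                  noise_sd_frac=0.02, replicates=3, seed=5)
        assert select_kinetic_model(curve).model == "single"

    def test_identical_km_ill_conditioned(self):
        curve = generate_two_site_curve(50.0, 10.0, 50.0, 10.0)
        fit = fit_two_site(curve)
        assert any("ill-conditioned" in w for w in fit.warnings)

    def test_degenerate_site_reduces_to_single(self):
        curve = generate_mm_curve(62.0, 106.0,
                                  concentrations=np.geomspace(5, 2000, 12))
        single = fit_michaelis_menten(curve)
        double = fit_two_site(curve)
        # one site must carry the whole signal
        main = int(np.argmax(double.kcat))
        assert double.km[main] == pytest.approx(single.km[0], rel=1e-3)
        assert double.kcat[main] == pytest.approx(single.kcat[0], rel=1e-3)


class TestEfficiencyArithmetic:
    @pytest.mark.parametrize("km,kcat,expect", [
        (62.0, 106.0, 1710.0),     # Mn2+ oxidation by the ancestral VP
        (1000.0, 1.0, 1.0),
        (3170.0, 539.0, 170.0),    # low-efficiency ABTS site of the first ancestor
    ])
    def test_examples(self, km, kcat, expect):
        assert round_sig(catalytic_efficiency(km, kcat), 3) == pytest.approx(expect)

    def test_nonpositive_km(self):
        with pytest.raises(KineticsError):
            catalytic_efficiency(0.0, 5.0)

    @pytest.mark.parametrize("a,b,expect", [
        (700.0, 62.0, 11),    # Km(Mn) drop from first ancestor to ancestral VP
        (205.0, 28.0, 7),     # VA efficiency gain to the extant LiP
        (3.3, 3.3, 1),
    ])
    def test_fold_change_rounded(self, a, b, expect):
        assert fold_change(a, b, mode="rounded") == expect

    def test_fold_change_zero_denominator(self):
        with pytest.raises(KineticsError):
            fold_change(1.0, 0.0)


class TestProfiles:
    def test_relative_efficiency_normalization(self):
        import pandas as pd
        eff = pd.DataFrame({"Mn2+": [260.0, 617.0, 1710.0]},
                           index=["CaPo", "CaCD", "AVP"])
        rel = relative_efficiency_profile(eff)
        assert rel["Mn2+"].tolist() == pytest.approx([15.2, 36.1, 100.0], abs=0.05)

    def test_single_enzyme_is_100(self):
        import pandas as pd
        rel = relative_efficiency_profile(pd.DataFrame({"VA": [24.0]}, index=["AVP"]))
        assert rel["VA"].iloc[0] == 100.0

    def test_absent_activity_is_zero(self):
        import pandas as pd
        eff = pd.DataFrame({"VA": [np.nan, 205.0]}, index=["CaPo", "LiPH8"])
        rel = relative_efficiency_profile(eff)
        assert rel["VA"].tolist() == [0.0, 100.0]

    def test_all_zero_substrate_rejected(self):
        import pandas as pd
        with pytest.raises(KineticsError):
            relative_efficiency_profile(pd.DataFrame({"VA": [0.0, 0.0]}))

    def test_residual_activity(self):
        out = residual_activity_profile({"pH5": 8.0, "pH3": 4.0, "pH9": 0.0}, "pH5")
        assert out == {"pH5": 100.0, "pH3": 50.0, "pH9": 0.0}

    def test_residual_activity_bad_reference(self):
        with pytest.raises(KineticsError):
            residual_activity_profile({"pH5": 0.0}, "pH5")


class TestStabilityMidpoints:
    def test_linear_midpoint(self):
        assert t50_from_curve(StabilityCurve([50.0, 60.0], [100.0, 0.0])) == 55.0

    def test_t50_from_logistic_curve(self):
        t50 = t50_from_curve(generate_t50_curve(63.0))
        assert t50 == pytest.approx(63.0, abs=0.5)

    def test_no_crossing_is_error(self):
        with pytest.raises(KineticsError, match="no T50"):
            t50_from_curve(StabilityCurve([25.0, 45.0, 65.0], [100.0, 95.0, 85.0]))

    def test_tm_noiseless(self):
        tm = tm_from_melting(generate_melting_curve(66.0))
        assert tm == pytest.approx(66.0, abs=0.1)

    def test_tm_noisy_recovery(self):
        errs = [abs(tm_from_melting(generate_melting_curve(
            69.0, noise_sd_frac=0.02, seed=s)) - 69.0) for s in range(10)]
        assert max(errs) < 1.0

    def test_flat_profile_is_error(self):
        with pytest.raises(KineticsError, match="flat|transition"):
            tm_from_melting(StabilityCurve(np.arange(20.0, 90.0, 5.0),
                                           np.full(14, -20.0)))

    def test_axis_rescaling_invariance(self):
        m = generate_melting_curve(71.0)
        assert tm_from_melting(m) == pytest.approx(
            tm_from_melting(StabilityCurve(m.x, m.y * 7.5)), abs=1e-6)
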