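"""Fetal-growth numerics: Hadlock EFW, percentile standards, Z-score models,
growth velocity, customised centiles, birthweight percentiles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from popscreen._errors import (
    DomainError,
    FitError,
    MissingInputError,
    RangeError,
)
from popscreen.growth import (
    BiometrySet,
    EFWEquation,
    GrowthStandard,
    MaternalProfile,
    ac_growth_velocity,
    birthweight_percentile,
    cm_to_mm,
    customised_percentile,
    efw_percentile,
    fit_zscore_model,
    hadlock_efw,
    mm_to_cm,
)


class TestHadlockEFW:
    def test_matches_hand_evaluation_of_registered_polynomial(self):
        # independent hand evaluation of the registered log10 polynomial
        hc, ac, fl = 30.0, 26.0, 5.5
        expected = 10.0 ** (
            1.326 - 0.00326 * ac * fl + 0.0107 * hc + 0.0438 * ac + 0.158 * fl
        )
        got = hadlock_efw(BiometrySet(ga_weeks=31.0, hc_cm=hc, ac_cm=ac, fl_cm=fl))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_four_parameter_variant_hand_evaluation(self):
        bpd, hc, ac, fl = 8.2, 30.0, 26.0, 5.5
        expected = 10.0 ** (
            1.3596 + 0.0064 * hc + 0.0424 * ac + 0.174 * fl
            + 0.00061 * bpd * ac - 0.00386 * ac * fl
        )
        b = BiometrySet(ga_weeks=31.0, bpd_cm=bpd, hc_cm=hc, ac_cm=ac, fl_cm=fl)
        assert hadlock_efw(b, "hadlock_efw_bpd_hc_ac_fl") == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_abdominal_circumference(self):
        lo = hadlock_efw(BiometrySet(ga_weeks=31, hc_cm=30, ac_cm=26, fl_cm=5.5))
        hi = hadlock_efw(BiometrySet(ga_weeks=31, hc_cm=30, ac_cm=27, fl_cm=5.5))
        assert lo < hi

    def test_unit_round_trip_identity(self):
        vals = dict(hc_cm=30.0, ac_cm=26.0, fl_cm=5.5)
        round_tripped = {k: float(mm_to_cm(cm_to_mm(v))) for k, v in vals.items()}
        a = hadlock_efw(BiometrySet(ga_weeks=31.0, **vals))
        b = hadlock_efw(BiometrySet(ga_weeks=31.0, **round_tripped))
        assert a == pytest.approx(b, rel=1e-9)

    def test_missing_measure_raises(self):
        with pytest.raises(MissingInputError):
            hadlock_efw(BiometrySet(ga_weeks=31.0, hc_cm=30.0, ac_cm=26.0))

    def test_nonpositive_measure_rejected_at_construction(self):
        with pytest.raises(DomainError):
            BiometrySet(ga_weeks=31.0, hc_cm=30.0, ac_cm=-26.0, fl_cm=5.5)

    def test_ga_outside_domain_rejected(self):
        with pytest.raises(DomainError):
            BiometrySet(ga_weeks=11.0, hc_cm=30.0, ac_cm=26.0, fl_cm=5.5)

    def test_scale_to_weight_inverts_equation(self):
        eq = EFWEquation.from_registry("hadlock_efw_hc_ac_fl")
        measures = {"hc_cm": 30.0, "ac_cm": 26.0, "fl_cm": 5.5}
        lam = eq.scale_to_weight(measures, 1800.0)
        scaled = {k: v * lam for k, v in measures.items()}
        assert float(eq.weight_g(scaled)) == pytest.approx(1800.0, rel=1e-10)


class TestEFWPercentile:
    def test_median_maps_to_fiftieth_at_machine_precision(self, toy_efw_std):
        for ga in np.linspace(14.5, 41.5, 12):
            pct = efw_percentile(toy_efw_std.location(ga), ga, toy_efw_std)
            assert pct == pytest.approx(50.0, abs=1e-9)

    def test_one_sd_above_median_is_8413(self, toy_efw_std):
        ga = 30.0
        efw = toy_efw_std.location(ga) + toy_efw_std.scale(ga)
        assert efw_percentile(efw, ga, toy_efw_std) == pytest.approx(84.13, abs=0.005)

    def test_matches_direct_normal_cdf_oracle(self):
        # against the shipped standard, bypassing the registry plumbing
        std = GrowthStandard.from_registry("hadlock_weight_for_ga")
        ga, efw = 33.7, 1900.0
        loc = math.exp(0.578 + 0.332 * ga - 0.00354 * ga * ga)
        expected = 100.0 * stats.norm.cdf((efw - loc) / (0.127 * loc))
        assert efw_percentile(efw, ga, std) == pytest.approx(expected, rel=1e-12)

    def test_ga_outside_domain_names_the_domain(self, toy_efw_std):
        with pytest.raises(RangeError, match=r"\[14.0, 42.0\]"):
            efw_percentile(1500.0, 43.5, toy_efw_std)

    @given(st.floats(min_value=-4.5, max_value=4.5), st.floats(min_value=20.0, max_value=40.0))
    def test_strictly_increasing_in_efw(self, z, ga):
        std = GrowthStandard(
            name="t", kind="efw_for_ga", working_scale="natural", ga_domain=(14, 42),
            _location=lambda g, s: 100.0 * g, _scale=lambda g, s: 10.0 * g,
        )
        efw = float(std.location(ga) + z * std.scale(ga))
        assert efw_percentile(efw + 1.0, ga, std) > efw_percentile(efw, ga, std)


class TestZScoreModel:
    def test_recovers_generating_curves(self):
        # measure = m(ga) + N(0, s(ga)) with known m, s; held-out Z within 0.1
        rng = np.random.default_rng(42)
        n = 5000
        ga = rng.uniform(19, 38, n)
        m = 20.0 + 8.0 * ga - 0.05 * ga**2
        s = 0.5 + 0.04 * ga
        y = m + rng.normal(0.0, s)
        model = fit_zscore_model(ga, y, degree=2)
        ga0 = np.array([22.0, 28.0, 34.0])
        y0 = (20.0 + 8.0 * ga0 - 0.05 * ga0**2) + 1.3 * (0.5 + 0.04 * ga0)
        z = model.zscore(ga0, y0)
        assert np.all(np.abs(z - 1.3) < 0.1)

    def test_mean_curve_recovery_within_two_percent_centrally(self):
        rng = np.random.default_rng(3)
        n = 5000
        ga = rng.uniform(19, 38, n)
        m = 20.0 + 8.0 * ga - 0.05 * ga**2
        y = m + rng.normal(0.0, 0.5 + 0.04 * ga)
        model = fit_zscore_model(ga, y, degree=2)
        lo, hi = np.quantile(ga, [0.05, 0.95])
        grid = np.linspace(lo, hi, 100)
        truth = 20.0 + 8.0 * grid - 0.05 * grid**2
        rel_err = np.abs(model.mean(grid) - truth) / truth
        assert rel_err.max() < 0.02

    def test_point_on_mean_curve_has_zero_z(self):
        rng = np.random.default_rng(0)
        ga = rng.uniform(20, 36, 500)
        y = 10.0 * ga + rng.normal(0, 5.0, 500)
        model = fit_zscore_model(ga, y, degree=1)
        assert float(model.zscore(28.0, model.mean(28.0))) == pytest.approx(0.0, abs=1e-12)
        two_sd = model.mean(28.0) + 2.0 * model.sd(28.0)
        assert float(model.zscore(28.0, two_sd)) == pytest.approx(2.0, abs=1e-12)

    def test_self_sample_standardisation(self):
        rng = np.random.default_rng(5)
        ga = rng.uniform(19, 38, 3000)
        y = 3.0 * ga + rng.normal(0, 0.1 * ga)
        model = fit_zscore_model(ga, y, degree=2)
        z = model.zscore(ga, y)
        assert abs(float(np.mean(z))) <= 0.05
        assert 0.9 <= float(np.std(z)) <= 1.1

    def test_degenerate_designs_raise(self):
        with pytest.raises(FitError):
            fit_zscore_model(np.full(200, 28.0), np.random.default_rng(0).normal(size=200))
        with pytest.raises(FitError):
            fit_zscore_model(np.linspace(20, 36, 50), np.linspace(1, 2, 50))


class TestGrowthVelocity:
    @pytest.mark.parametrize(
        "z20,zlast,expected", [(0.5, 0.5, 0.0), (1.0, -0.5, -1.5), (-2.0, -0.25, 1.75)]
    )
    def test_difference(self, z20, zlast, expected):
        assert ac_growth_velocity(z20, zlast) == pytest.approx(expected)

    def test_missing_scan_raises(self):
        with pytest.raises(MissingInputError):
            ac_growth_velocity(np.nan, 1.0)


class TestCustomisedPercentile:
    COEFFS = {
        "kind": "customised_efw",
        "base_term_weight_g": 3480.0,
        "height_coef_g_per_cm": 8.0,
        "weight_coef_g_per_kg": 7.5,
        "ethnicity_offsets_g": {"white": 0.0, "south_asian": -180.0},
        "proportion_curve": {
            "type": "hadlock_normalised",
            "coefficients": [0.578, 0.332, -0.00354],
            "term_ga": 40.0,
        },
        "cv": 0.11,
    }

    def test_identical_profiles_identical_percentiles(self):
        m = MaternalProfile(height_cm=170, weight_kg=70)
        a = customised_percentile(2000.0, 33.0, m, self.COEFFS)
        b = customised_percentile(2000.0, 33.0, m, self.COEFFS)
        assert a == b

    def test_zero_adjustments_reduce_to_population_percentile(self):
        # with no maternal offsets, a base weight equal to the reference's
        # term median and the reference CV, customisation degenerates to the
        # population percentile under the same proportionality curve
        std = GrowthStandard.from_registry("hadlock_weight_for_ga")
        coeffs = dict(self.COEFFS)
        coeffs.update(
            base_term_weight_g=float(std.location(40.0)),
            height_coef_g_per_cm=0.0,
            weight_coef_g_per_kg=0.0,
            cv=0.127,
        )
        m = MaternalProfile(height_cm=150, weight_kg=90)
        got = customised_percentile(1600.0, 31.5, m, coeffs)
        assert float(got) == pytest.approx(float(efw_percentile(1600.0, 31.5, std)), rel=1e-9)

    def test_taller_mother_lowers_percentile(self):
        short = MaternalProfile(height_cm=155, weight_kg=65)
        tall = MaternalProfile(height_cm=178, weight_kg=65)
        assert customised_percentile(2000.0, 33.0, tall, self.COEFFS) < customised_percentile(
            2000.0, 33.0, short, self.COEFFS
        )


class TestBirthweightPercentile:
    def test_tabulated_median_is_fiftieth(self, toy_bw_std):
        assert float(birthweight_percentile(3600.0, 36.0, "male", toy_bw_std)) == pytest.approx(
            50.0
        )

    def test_sexes_differ_where_table_differs(self, toy_bw_std):
        m = birthweight_percentile(3400.0, 36.0, "male", toy_bw_std)
        f = birthweight_percentile(3400.0, 36.0, "female", toy_bw_std)
        assert float(m) != float(f)

    def test_linear_interpolation_between_weeks(self, toy_bw_std):
        # table is linear, so the midpoint location is the average of the
        # two tabulated weeks (hand interpolation oracle)
        mid = float(toy_bw_std.location(36.5, "male"))
        assert mid == pytest.approx((3600.0 + 3700.0) / 2.0)

    def test_ga_outside_table_raises(self, toy_bw_std):
        with pytest.raises(RangeError):
            birthweight_percentile(3000.0, 23.0, "male", toy_bw_std)

    def test_strictly_increasing_in_weight(self, toy_bw_std):
        grid = np.linspace(2000, 4500, 20)
        pct = [float(birthweight_percentile(w, 38.2, "female", toy_bw_std)) for w in grid]
        assert np.all(np.diff(pct) > 0)
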