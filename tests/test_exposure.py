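import numpy as np
import pytest
from hypothesis import given, strategies as st

import activehia as ah
from activehia.community import ValidationError
from activehia.exposure import WalkabilityInputs, WalkabilityMapping


def _inputs(int_d, res_d, far, landuse, means=(10, 5, 0.5, 0.5), sds=(2, 2, 0.2, 0.2)):
    return WalkabilityInputs(int_d, res_d, far, landuse, means, sds)


class TestWalkabilityScore:
    def test_components_at_means_score_zero(self):
        x = _inputs(10, 5, 0.5, (0.5, 0.2, 0.2, 0.1))
        ent = ah.landuse_entropy((0.5, 0.2, 0.2, 0.1))
        x = _inputs(10, 5, 0.5, (0.5, 0.2, 0.2, 0.1), means=(10, 5, 0.5, ent))
        assert ah.walkability_score(x) == pytest.approx(0.0)

    def test_intersection_density_carries_double_weight(self):
        ent = ah.landuse_entropy((0.25,) * 4)
        x = _inputs(12, 5, 0.5, (0.25,) * 4, means=(10, 5, 0.5, ent))  # Z_int = 1
        assert ah.walkability_score(x) == pytest.approx(2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValidationError, match="SD"):
            _inputs(10, 5, 0.5, (0.5, 0.5), sds=(0.0, 2, 0.2, 0.2))

    def test_urban_corridor_fixture_reproduces_reference_scores(self):
        fx = ah.brrc_walkability_fixture()
        before = ah.walkability_score(fx["before"])
        after = ah.walkability_score(fx["after"])
        assert before == pytest.approx(-3.61, abs=5e-3)
        assert after == pytest.approx(0.96, abs=5e-3)
        assert after - before == pytest.approx(4.57, abs=1e-2)


class TestLanduseEntropy:
    @pytest.mark.parametrize(
        "shares, expected",
        [((0.25, 0.25, 0.25, 0.25), 1.0), ((1.0, 0.0, 0.0, 0.0), 0.0), ((0.5, 0.5, 0.0, 0.0), 0.5)],
    )
    def test_reference_values(self, shares, expected):
        assert ah.landuse_entropy(shares) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="2 use classes"):
            ah.landuse_entropy((1.0,))


class TestWalkabilityShift:
    def test_null_score_change_is_null_shift(self, urban_profile):
        base = urban_profile.baseline_exposure
        sh = ah.walkability_to_shift(1.0, 1.0, base, WalkabilityMapping(0.05, 4.0))
        assert sh.after == base

    def test_calibrated_fixture_moves_mass_low_to_high(self, brrc_shift):
        a = brrc_shift.after
        assert (a.p_none, a.p_low, a.p_high) == pytest.approx((0.407, 0.212, 0.381), abs=5e-4)
        assert a.mean_minutes == pytest.approx(30.4, abs=0.05)

    def test_excess_transfer_capped_with_warning(self):
        base = ah.ExposureDistribution(0.8, 0.1, 0.1, 10.0)
        with pytest.warns(UserWarning, match="capping"):
            sh = ah.walkability_to_shift(0.0, 10.0, base, WalkabilityMapping(0.05, 1.0))
        assert sh.after.p_low == pytest.approx(0.0)
        assert sh.after.p_high == pytest.approx(0.2)

    def test_negative_transfer_rejected(self, urban_profile):
        with pytest.raises(ValidationError):
            ah.walkability_to_shift(2.0, 1.0, urban_profile.baseline_exposure,
                                    WalkabilityMapping(0.05, 1.0))


class TestSidewalkShift:
    def test_equal_densities_give_null_shift(self, suburban_profile):
        base = suburban_profile.baseline_exposure
        sh = ah.sidewalk_shift(ah.SidewalkDensities(2.0, 2.0), base)
        assert sh.after.p_none == pytest.approx(base.p_none)

    def test_reference_density_change_reproduces_published_shares(self):
        base = ah.ExposureDistribution(0.843, 0.123, 0.034, 12.5)
        sh = ah.sidewalk_shift(ah.SidewalkDensities(0.8, 3.8), base)
        assert round(100 * sh.after.p_none, 1) == 83.4
        assert round(100 * sh.after.p_high, 1) == 3.6

    def test_mass_conservation_is_exact(self):
        base = ah.ExposureDistribution(0.843, 0.123, 0.034, 12.5)
        sh = ah.sidewalk_shift(ah.SidewalkDensities(0.8, 3.8), base)
        d_none = sh.after.p_none - base.p_none
        d_walk = (sh.after.p_low - base.p_low) + (sh.after.p_high - base.p_high)
        assert d_none == pytest.approx(-d_walk, abs=1e-15)

    @given(st.floats(0.0, 8.0), st.floats(0.0, 8.0))
    def test_monotone_in_density_change_and_stays_on_simplex(self, d1, d2):
        base = ah.ExposureDistribution(0.843, 0.123, 0.034, 12.5)
        lo, hi = sorted((d1, d2))
        sh_lo = ah.sidewalk_shift(ah.SidewalkDensities(0.0, lo), base)
        sh_hi = ah.sidewalk_shift(ah.SidewalkDensities(0.0, hi), base)
        assert sh_hi.after.p_none <= sh_lo.after.p_none + 1e-12
        assert np.isclose(sh_hi.after.shares.sum(), 1.0)
        assert np.all(sh_hi.after.shares >= 0)


class TestPEF:
    @pytest.mark.parametrize(
        "scores, expected",
        [((1, 1, 1, 1), "low"), ((3, 3, 1, 1), "medium"), ((3, 3, 3, 3), "high"),
         ((2, 2, 2, 1), "medium"), ((3, 3, 2, 2), "high")],
    )
    def test_class_thresholds(self, scores, expected):
        assert ah.pef_class(ah.PEFAssessment(*scores)) == expected

    def test_invalid_subscore_rejected(self):
        with pytest.raises(ValidationError):
            ah.PEFAssessment(0, 1, 1, 1)

    def test_unchanged_class_is_null_shift(self):
        base = ah.ExposureDistribution(0.854, 0.121, 0.025, 10.4)
        sh = ah.pef_shift(ah.PEFAssessment(1, 1, 1, 1), ah.PEFAssessment(2, 1, 1, 1), base)
        assert sh.after == base

    def test_one_class_step_adds_13_8_minutes_per_affected_person(self):
        base = ah.ExposureDistribution(0.854, 0.121, 0.025, 10.4)
        sh = ah.pef_shift(ah.PEFAssessment(1, 1, 1, 1), ah.PEFAssessment(3, 3, 1, 1), base,
                          buffer_fraction=1.0)
        assert sh.after.mean_minutes - base.mean_minutes == pytest.approx(0.92 / 4 * 60)

    def test_buffer_fraction_scales_population_mean_increase(self):
        base = ah.ExposureDistribution(0.854, 0.121, 0.025, 10.4)
        full = ah.pef_shift(ah.PEFAssessment(1, 1, 1, 1), ah.PEFAssessment(3, 3, 1, 1), base, 1.0)
        quarter = ah.pef_shift(ah.PEFAssessment(1, 1, 1, 1), ah.PEFAssessment(3, 3, 1, 1), base, 0.25)
        full_gain = full.after.mean_minutes - base.mean_minutes
        assert quarter.after.mean_minutes - base.mean_minutes == pytest.approx(0.25 * full_gain)
        # unaffected 75% of mass dilutes the category change by the same factor
        assert quarter.after.p_none - base.p_none == pytest.approx(
            0.25 * (full.after.p_none - base.p_none)
        )

    def test_buffer_distribution_stays_on_simplex(self):
        base = ah.ExposureDistribution(0.854, 0.121, 0.025, 10.4)
        sh = ah.pef_shift(ah.PEFAssessment(1, 1, 1, 1), ah.PEFAssessment(3, 3, 3, 3), base, 0.25)
        assert np.isclose(sh.after.shares.sum(), 1.0)
        assert np.all(sh.after.shares >= 0)
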