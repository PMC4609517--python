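import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import activehia as ah
from activehia.community import ValidationError

# Full shipped table: (outcome, sex, category) -> (central, lower, upper)
REFERENCE_TABLE = {
    ("mortality", "combined", "low"): (0.95, 0.92, 0.98),
    ("mortality", "combined", "high"): (0.90, 0.85, 0.96),
    ("CHD", "male", "low"): (0.99, 0.91, 1.08),
    ("CHD", "male", "high"): (0.99, 0.90, 1.10),
    ("CHD", "female", "low"): (0.95, 0.83, 1.08),
    ("CHD", "female", "high"): (0.80, 0.69, 0.92),
    ("type2_diabetes", "combined", "low"): (0.77, 0.58, 1.02),
    ("type2_diabetes", "combined", "high"): (0.69, 0.54, 0.88),
    ("hypertension", "combined", "low"): (0.76, 0.61, 0.94),
    ("hypertension", "combined", "high"): (0.69, 0.58, 0.83),
    ("stroke", "male", "low"): (0.94, 0.83, 1.06),
    ("stroke", "male", "high"): (0.88, 0.77, 1.02),
    ("stroke", "female", "low"): (0.88, 0.77, 1.01),
    ("stroke", "female", "high"): (0.87, 0.75, 1.01),
}


class TestMortalityRR:
    def test_zero_minutes_is_reference_risk(self):
        assert ah.mortality_rr(0) == 1.0

    @pytest.mark.parametrize("minutes, expected", [(75, 0.95), (150, 0.90)])
    def test_category_evaluation_points(self, minutes, expected):
        assert round(ah.mortality_rr(minutes), 2) == expected

    @given(st.floats(0, 400), st.floats(0, 400))
    def test_multiplicative_in_dose(self, a, b):
        assert ah.mortality_rr(a + b) == pytest.approx(
            ah.mortality_rr(a) * ah.mortality_rr(b)
        )

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 600, 200)
        assert np.all(np.diff(ah.mortality_rr(grid)) < 0)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValidationError):
            ah.mortality_rr(10, base_rr=0.0)


class TestCategoricalRR:
    @pytest.mark.parametrize("key, vals", REFERENCE_TABLE.items())
    def test_shipped_table_fidelity(self, rr_default, key, vals):
        outcome, sex, cat = key
        for bound, expected in zip(("central", "lower", "upper"), vals):
            assert rr_default.rr(outcome, sex, cat, bound) == expected

    def test_reference_category_is_always_one(self, rr_default):
        for outcome in ("mortality", "CHD", "stroke"):
            for sex in ("male", "female", "combined"):
                assert rr_default.rr(outcome, sex, "none", "upper") == 1.0

    def test_combined_rows_serve_sex_specific_lookups(self, rr_default):
        assert rr_default.rr("hypertension", "female", "high") == 0.69

    def test_missing_outcome_names_the_gap(self, rr_default):
        with pytest.raises(KeyError, match="asthma"):
            rr_default.rr("asthma", "combined", "high")

    def test_ci_order_normalized_on_ingest(self):
        df = pd.DataFrame(
            [{"outcome": "mortality", "sex": "combined", "category": "high",
              "central": 0.90, "lower": 0.96, "upper": 0.85}]  # printed (upper-lower)
        )
        rs = ah.RelativeRiskSet.from_frame(df)
        assert rs.rr("mortality", "combined", "high", "lower") == 0.85
        assert rs.rr("mortality", "combined", "high", "upper") == 0.96


class TestImpactFraction:
    def test_no_change_gives_zero(self, urban_profile):
        b = urban_profile.baseline_exposure
        assert ah.impact_fraction(b, b, np.array([1.0, 0.95, 0.90])) == 0.0

    def test_full_shift_to_high_category(self):
        assert ah.impact_fraction(
            np.array([1.0, 0, 0]), np.array([0, 0, 1.0]), np.array([1.0, 0.95, 0.90])
        ) == pytest.approx(0.10)

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    def test_null_effect_when_all_rr_equal(self, a, b):
        before = np.array([1 - a - b, a, b])
        after = np.array([b, a, 1 - a - b])
        assert ah.impact_fraction(before, after, np.ones(3)) == pytest.approx(0.0)

    def test_sign_matches_shift_direction(self):
        rr = np.array([1.0, 0.95, 0.90])
        protective = ah.impact_fraction([0.5, 0.3, 0.2], [0.2, 0.3, 0.5], rr)
        harmful = ah.impact_fraction([0.2, 0.3, 0.5], [0.5, 0.3, 0.2], rr)
        assert protective > 0 > harmful

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError, match="denominator"):
            ah.impact_fraction([1.0, 0, 0], [0, 1.0, 0], np.array([0.0, 1.0, 1.0]))


class TestContinuousBins:
    def test_three_bin_case_reproduces_categorical_points(self):
        d = ah.ExposureDistribution(0.4, 0.4, 0.2, 20.0)
        reps, shares, rr = ah.continuous_bins(d, n_bins=3, max_minutes=300)
        assert reps.tolist() == [0.0, 75.0, 150.0]
        assert shares.tolist() == [0.4, 0.4, 0.2]
        assert round(rr[1], 2) == 0.95 and round(rr[2], 2) == 0.90

    def test_shares_conserved_across_bins(self):
        d = ah.ExposureDistribution(0.407, 0.415, 0.178, 13.1)
        _, shares, _ = ah.continuous_bins(d)
        assert shares.sum() == pytest.approx(1.0)
        assert shares[0] == d.p_none

    def test_all_mass_at_zero_has_null_impact_against_itself(self):
        d = ah.ExposureDistribution(1.0, 0.0, 0.0, 0.0)
        _, shares, rr = ah.continuous_bins(d)
        assert 1.0 - (shares @ rr) / (shares @ rr) == 0.0

    def test_finer_bins_do_not_decrease_benefit_for_right_shifted_exposure(self):
        before = ah.ExposureDistribution(0.407, 0.415, 0.178, 13.1)
        after = ah.ExposureDistribution(0.407, 0.212, 0.381, 30.4)
        rr_cat = np.array([1.0, ah.mortality_rr(75), ah.mortality_rr(150)])
        pif_cat = ah.impact_fraction(before, after, rr_cat)
        _, sb, rrb = ah.continuous_bins(before)
        _, sa, _ = ah.continuous_bins(after)
        pif_cont = 1 - (sa @ rrb) / (sb @ rrb)
        assert pif_cont >= pif_cat

    def test_too_few_bins_rejected(self):
        d = ah.ExposureDistribution(0.4, 0.4, 0.2, 20.0)
        with pytest.raises(ValidationError):
            ah.continuous_bins(d, n_bins=1)
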