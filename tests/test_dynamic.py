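import numpy as np
import pytest

import activehia as ah
from activehia.community import ValidationError
from activehia.dynamic import TransitionProbabilities


def _uniform_transitions(mort=0.0, inc=0.05, p0=0.1, excess=0.0):
    shape = (3, 101, 2)
    return TransitionProbabilities(
        mortality=np.full(shape, mort),
        incidence={"hypertension": np.full(shape, inc)},
        excess={"hypertension": np.full(101, excess)},
        prevalence0={"hypertension": np.full(101, p0)},
    )


class TestBuildTransitions:
    def test_unit_rrs_make_categories_identical(self, tiny_profile):
        import pandas as pd

        rows = [
            {"outcome": o, "sex": "combined", "category": c, "central": 1.0, "lower": 1.0, "upper": 1.0}
            for o in ("mortality", "hypertension", "type2_diabetes")
            for c in ("low", "high")
        ]
        rr1 = ah.RelativeRiskSet.from_frame(pd.DataFrame(rows))
        tr = ah.build_transitions(tiny_profile, tiny_profile.baseline_exposure, rr1)
        assert np.allclose(tr.mortality[0], tr.mortality[1])
        assert np.allclose(tr.mortality[0], tr.mortality[2])
        for grid in tr.incidence.values():
            assert np.allclose(grid[0], grid[2])

    def test_high_category_mortality_is_reference_times_090(self, tiny_profile, rr_default):
        tr = ah.build_transitions(tiny_profile, tiny_profile.baseline_exposure, rr_default)
        adult = slice(18, None)
        ratio = tr.mortality[2, adult, 0] / tr.mortality[0, adult, 0]
        assert np.allclose(ratio, 0.90)

    def test_probabilities_within_unit_interval_on_full_grid(self, urban_profile, rr_default):
        tr = ah.build_transitions(urban_profile, urban_profile.baseline_exposure, rr_default)
        assert np.all((tr.mortality >= 0) & (tr.mortality <= 1))
        for grid in tr.incidence.values():
            assert np.all((grid >= 0) & (grid <= 1))

    def test_unknown_bound_rejected(self, tiny_profile, rr_default):
        with pytest.raises(ValidationError, match="bound"):
            ah.build_transitions(tiny_profile, tiny_profile.baseline_exposure, rr_default, "upper")


class TestRunScenario:
    def test_zero_rates_keep_population_static(self, tiny_profile, rr_default):
        tr = _uniform_transitions(mort=0.0, inc=0.0, p0=0.0)
        res = ah.run_scenario(tiny_profile, tiny_profile.baseline_exposure, rr_default,
                              horizon=40, transitions=tr)
        assert np.allclose(res.alive, tiny_profile.total_population)
        assert np.allclose(res.deaths, 0.0)

    def test_single_cohort_prevalence_matches_closed_form(self, rr_default):
        """Constant incidence i, no deaths: prevalence -> 1 - (1-p0)(1-i)^t."""
        pop = np.zeros((101, 2))
        pop[30] = 1000.0
        prof = ah.CommunityProfile(
            "cohort", pop, np.zeros((101, 2)), 0.0, [],
            ah.ExposureDistribution(0.4, 0.4, 0.2, 15.0), 0.0,
        )
        i, p0 = 0.05, 0.1
        tr = _uniform_transitions(mort=0.0, inc=i, p0=p0)
        res = ah.run_scenario(prof, prof.baseline_exposure, rr_default, horizon=30, transitions=tr)
        t = np.arange(1, 31)
        expected = (1 - (1 - p0) * (1 - i) ** t) * prof.total_population
        assert np.allclose(res.prevalent["hypertension"], expected)

    def test_mass_conservation_each_step(self, urban_profile, rr_default):
        res = ah.run_scenario(urban_profile, urban_profile.baseline_exposure, rr_default, 40)
        alive_prev = urban_profile.total_population
        for t in range(res.horizon):
            assert res.alive[t] == pytest.approx(
                alive_prev - res.deaths[t] + res.births[t], rel=1e-12
            )
            alive_prev = res.alive[t]

    def test_invalid_horizon_rejected(self, tiny_profile, rr_default):
        with pytest.raises(ValidationError, match="horizon"):
            ah.run_scenario(tiny_profile, tiny_profile.baseline_exposure, rr_default, horizon=0)


class TestHealthImpact:
    def test_null_intervention_gives_exact_zero_impact(self, urban_profile, rr_default):
        base = ah.run_scenario(urban_profile, urban_profile.baseline_exposure, rr_default, 20)
        same = ah.run_scenario(urban_profile, urban_profile.baseline_exposure, rr_default, 20)
        imp = ah.health_impact(base, same)
        assert np.all(imp.avoided_deaths == 0.0)
        for v in imp.avoided_incident.values():
            assert np.all(v == 0.0)

    def test_mismatched_horizons_rejected(self, tiny_profile, rr_default):
        a = ah.run_scenario(tiny_profile, tiny_profile.baseline_exposure, rr_default, 5)
        b = ah.run_scenario(tiny_profile, tiny_profile.baseline_exposure, rr_default, 6)
        with pytest.raises(ValidationError, match="horizon"):
            ah.health_impact(a, b)

    def test_protective_shift_accumulates_avoided_deaths(self, urban_profile, rr_default, brrc_shift):
        base = ah.run_scenario(urban_profile, brrc_shift.before, rr_default, 40)
        interv = ah.run_scenario(urban_profile, brrc_shift.after, rr_default, 40)
        imp = ah.health_impact(base, interv)
        cum = np.cumsum(imp.avoided_deaths)
        assert cum[-1] > 0
        # nondecreasing up to survivorship feedback, which stays below 0.5%
        # of the accumulated benefit in any single late year
        assert np.all(np.diff(cum) >= -5e-3 * cum[-1])
        assert imp.cumulative(40)["mortality"] > imp.cumulative(10)["mortality"]

    def test_more_protective_mortality_bound_never_decreases_avoided_deaths(
        self, urban_profile, rr_default, brrc_shift
    ):
        def cum_deaths(bound):
            base = ah.run_scenario(urban_profile, brrc_shift.before, rr_default, 15, bound)
            interv = ah.run_scenario(urban_profile, brrc_shift.after, rr_default, 15, bound)
            return ah.health_impact(base, interv).cumulative(15)["mortality"]

        # lower RR bound = stronger protection
        assert cum_deaths("lower_mortality") >= cum_deaths("central") >= cum_deaths("upper_mortality")

    def test_yearly_increments_decline_toward_steady_state(self, urban_profile, rr_default, brrc_shift):
        base = ah.run_scenario(urban_profile, brrc_shift.before, rr_default, 40)
        interv = ah.run_scenario(urban_profile, brrc_shift.after, rr_default, 40)
        imp = ah.health_impact(base, interv)
        for d in ("hypertension", "type2_diabetes"):
            series = imp.avoided_incident[d]
            assert series[35] < series[5]


class TestMicrosimOracle:
    def test_fixed_seed_reproducible(self, tiny_profile, rr_default):
        a = ah.microsim_oracle(tiny_profile, tiny_profile.baseline_exposure, rr_default,
                               2000, seed=11, horizon=5)
        b = ah.microsim_oracle(tiny_profile, tiny_profile.baseline_exposure, rr_default,
                               2000, seed=11, horizon=5)
        assert np.array_equal(a.deaths, b.deaths)
        assert np.array_equal(a.incident["hypertension"], b.incident["hypertension"])

    def test_unit_rr_scenarios_agree_within_mc_error(self, tiny_profile):
        import pandas as pd

        rows = [
            {"outcome": o, "sex": "combined", "category": c, "central": 1.0, "lower": 1.0, "upper": 1.0}
            for o in ("mortality", "hypertension", "type2_diabetes")
            for c in ("low", "high")
        ]
        rr1 = ah.RelativeRiskSet.from_frame(pd.DataFrame(rows))
        shifted = ah.ExposureDistribution(0.1, 0.4, 0.5, 40.0)
        a = ah.microsim_oracle(tiny_profile, tiny_profile.baseline_exposure, rr1, 20_000, 3, 10)
        b = ah.microsim_oracle(tiny_profile, shifted, rr1, 20_000, 3, 10)
        for t in range(10):
            se = np.sqrt(max(a.deaths[t], 1.0))
            assert abs(a.deaths[t] - b.deaths[t]) <= 4 * se
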