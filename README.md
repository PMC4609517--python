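# activehia

Quantitative health impact assessment (HIA) of built-environment changes that
increase walking for transportation.

Transportation agencies increasingly need to weigh the health consequences of
infrastructure decisions — a sidewalk plan, a streetscape upgrade, a dense
mixed-use corridor — alongside cost and congestion metrics. `activehia` links
such a proposal to population health in three steps:

1. **Behavior.** Three estimators translate a built-environment change into a
   shift of the population distribution over weekly transportation-walking
   categories (none / 1–149 / 150+ min per week): a walkability index
   `W = 2·Z_int + Z_res + Z_FAR + Z_landuse`, a sidewalk-density odds model
   `O_after / O_before = 1.023^(D_after − D_before)` (D in km of sidewalk per
   km²), and an ordinal pedestrian environment factor (PEF) worth 0.92 km of
   weekly walking distance per class step.
2. **Health.** Walking reduces all-cause mortality through the continuous
   dose-response `RR(y) = 0.89^(y/168)` and reduces coronary heart disease,
   type 2 diabetes, hypertension and stroke through categorical relative
   risks. Two engines propagate these risks over a 40-year horizon:
   a **dynamic** multistate Markov cohort model (age × sex × walking category,
   healthy/diseased/dead states per disease, yearly steps, births entering,
   incidence calibrated so the baseline scenario reproduces observed
   population rates), and a reconstructed **static** model that applies a
   constant potential impact fraction
   `PIF = 1 − Σ p′_c RR_c / Σ p_c RR_c` to an unperturbed projection every
   year. Comparing the two quantifies the static model's systematic
   overestimation, which grows with the horizon.
3. **Value.** Avoided deaths are valued at the value of a statistical life
   ($9.1M), avoided disease case-years at annual costs, discounted at 5%/yr
   against construction cost, yielding NPV, benefit–cost ratio and breakeven
   year. Confidence intervals come from five deterministic runs that move the
   mortality and disease relative risks to their 95% bounds in turn.

Disease incidence, rarely observed directly at community scale, is derived
from age-prevalence curves via the illness–death balance
`i(a) = [p′(a) + p(a)(1−p(a))Δm(a)] / (1−p(a))`.

A `generate_community` module produces synthetic input bundles with the
statistical structure of real census/vital-statistics/health-survey inputs,
so the entire pipeline is runnable and testable offline.

## Worked example

```python
from activehia import (RelativeRiskSet, brrc_walkability_fixture, compare_static_dynamic,
                       generate_community, health_impact, run_scenario, run_static,
                       walkability_score, walkability_to_shift)

profile = generate_community(seed=1, size=20_000, profile_kind="urban")
rr = RelativeRiskSet.default()
fx = brrc_walkability_fixture()
shift = walkability_to_shift(walkability_score(fx["before"]), walkability_score(fx["after"]),
                             profile.baseline_exposure, fx["mapping"])
impact = health_impact(run_scenario(profile, shift.before, rr, 40),
                       run_scenario(profile, shift.after, rr, 40))
static = run_static(profile, shift, rr, 40)
```

Running `python examples/03_dynamic_vs_static.py` (which executes exactly
this) prints:

```
year   dynamic deaths avoided  static deaths avoided
  10                     20.3                   29.7
  20                     29.9                   60.2
  40                     32.7                  120.7

cumulative static/dynamic ratio at year 40 (overestimation factor):
        mortality: 3.7x
              CHD: 1.4x
   type2_diabetes: 1.3x
     hypertension: 1.7x
           stroke: 1.7x
```

The dynamic estimate saturates (20.3 → 32.7 avoided deaths between years 10
and 40) as the cohort approaches its new steady state, while the memoryless
static model keeps adding a near-constant yearly benefit — by year 40 it
overstates avoided deaths 3.7-fold on identical inputs. The other examples
show community generation and IO (`01`), the three behavior estimators
(`02`), and valuation with five-run confidence intervals (`04`).

A thin CLI wraps the same pipeline:
`activehia generate|shift|simulate|value|compare|report`.

## Layout

- `src/activehia/` — library modules: `community`, `exposure`,
  `doseresponse`, `rates`, `dynamic`, `static`, `economics`, `pipeline`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model assumptions, parameters, numerical choices and
  limitations
- `tests/` — unit, property and end-to-end suites
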