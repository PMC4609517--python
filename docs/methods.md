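# Methods

This note documents the models implemented in `activehia`, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Population and exposure structure

The population lives on an integer age grid 0–100 (closed top bin) × sex
(male, female) × weekly transportation-walking category
(none / 1–149 / 150+ min per week; 150 min/week is the CDC minimum adult
physical-activity recommendation). Walking exposure modifies risks from age
18; younger ages carry relative risk 1 and inherit the scenario's category
distribution. An intervention is a one-time step change in the category
distribution at year 0 — categories are fixed attributes within a scenario,
with no year-to-year churn.

The survey mean of weekly walking minutes is stored independently of the
category shares: surveyed means are generally inconsistent with midpoint
arithmetic on the bins (a community can report a 13 min/week mean with 18%
of residents above 150 min/week), so the two are deliberately decoupled.
Where a shifted distribution needs an updated mean (the sidewalk estimator),
per-category means are back-solved from the baseline (shares, mean) pair
under the convention `m_high = 2·m_low` — the 150:75 midpoint ratio — with
the zero category contributing nothing. This is an approximation, flagged as
such, and is used for reporting only; the health models consume category
shares, not means.

## Behavior estimators

**Walkability.** `W = 2·Z_intersection + Z_residential + Z_FAR +
Z_landuse`, each Z a (value − mean)/SD normalization. Land-use diversity is
the normalized entropy `−Σ p_i ln p_i / ln k` over k use-class area shares —
the standard diversity measure for this index. The score→behavior mapping
(population share moved from the low to the high category, and added mean
minutes, per unit score) is configuration: the source regressions live in
the walkability literature, not in this package. The shipped urban-corridor
fixture is calibrated so a +4.57 score change moves 20.3 percentage points
from low to high and adds 17.3 min/week to the mean. Non-walkers are left
unchanged by this estimator (the index intensifies existing walkers), and
transfers are clipped at the available low-category mass with a warning.

**Sidewalk density.** Each km/km² of added sidewalk multiplies the odds of
taking any weekly walk trip by 1.023. The package solves the odds relation
for the post-construction walking probability and allocates new walkers to
the low/high categories in proportion to the baseline low:high split. Mass
conservation is exact by construction.

**Pedestrian environment factor.** Four subscores (sidewalk quality,
crossing ease, topography, street-grid density) on 1–3 scales sum to an
ordinal class: 4–6 low, 7–9 medium, 10–12 high. The thresholds are a package
choice consistent with the two anchoring facts available — all-minimal
subscores are "low", and raising two subscores from 1 to 3 reaches
"medium". One class step is worth 0.92 km of weekly walking distance per
affected resident; at the default 4 km/h walking speed that is
0.92/4 × 60 = 13.8 min/week, computed from first principles (sources that
round the speed conversion differently may print 13.6). Within the affected
buffer population (default 25%) the walking-category shares are scaled
proportionally so the buffer mean rises by exactly the added minutes; the
reported distribution is the buffer/non-buffer mixture.

## Dose-response and impact fractions

All-cause mortality uses the continuous curve `RR(y) = 0.89^(y/168)`
(multiplicative in dose, RR(0)=1), evaluated for the categorical engines at
75 min/week (low-category midpoint) and 150 min/week (high-category floor) —
the latter caps benefits for very active individuals. Disease outcomes use a
shipped categorical table (`data/relative_risks.csv`): sex-pooled rows for
mortality, type 2 diabetes and hypertension; sex-specific rows for CHD and
stroke. Confidence-interval bounds are normalized on ingest so
lower ≤ central ≤ upper regardless of the printed order (protective RRs are
often printed upper-first). The CI bounds of the mortality categories are
table entries, never recomputed from the continuous curve, whose CI base
values are not published.

The static model's arithmetic is the potential impact fraction
`PIF = 1 − Σ p′_c RR_c / Σ p_c RR_c`. A continuous variant
(`continuous_11bin`) re-bins exposure into a zero category plus ten
equal-width bins over (0, 300] min/week, evaluating the continuous curve at
bin midpoints (top bin at its lower edge, preserving the capping
convention); with three bins and a 300-minute maximum this reproduces the
categorical evaluation points 0/75/150 exactly. The 300-minute default
maximum is a package choice; the bin count and maximum are parameters.

## Incidence from prevalence

Chronic-disease incidence is recovered from the age-prevalence curve via the
illness–death balance for a no-remission disease:

    i(a) = [p′(a) + p(a)(1 − p(a)) Δm(a)] / (1 − p(a)),

with `p′` a central finite difference on the yearly grid and `Δm` the excess
mortality of prevalent cases. The derivation is validated by a round-trip
oracle (prevalence → incidence → forward-simulated cohort prevalence,
agreement within 1% absolute on smooth curves) rather than against any
external implementation. Negative values — possible when prevalence declines
faster than excess mortality can explain — are floored at zero with a
warning. Excess mortality defaults are flat in age (0 for hypertension,
0.5–1.5%/yr for the other diseases in the generator); age-varying profiles
are accepted everywhere arrays are.

Category-specific rates come from the calibration identity
`i_ref = i_pop / Σ p_c RR_c`, `i_c = RR_c · i_ref`, which conserves the
population marginal exactly at every age and is applied to both disease
incidence and all-cause mortality. Calibration always uses the *baseline*
exposure distribution, for both scenarios, so the baseline scenario
reproduces observed population rates by construction.

## Dynamic engine

A proportional multistate Markov cohort model in yearly steps. All-cause
death is an alive/dead chain; each disease is a parallel
healthy/diseased/dead chain sharing the all-cause mortality schedule, with
excess mortality added for prevalent cases. Diseases are simulated as
independent marginal models: reported outcomes are per-disease marginals,
and joint comorbidity states are not carried. Treating the observed
all-cause rate as the healthy-state rate (with excess added on top)
slightly overstates diseased mortality; with the small excess rates used
here the effect is second-order.

The within-year event order is fixed: (1) disease incidence, (2) deaths,
(3) aging by one year (the top bin accumulates), (4) births entering at age
0, healthy, split evenly by sex, in the scenario's category distribution
(inert until age 18). Changing this order perturbs results at O(rate²), so
it is part of the model contract. Mass is conserved exactly each step:
alive(t+1) + deaths = alive(t) + births.

Health impact is the yearly difference between the baseline and intervention
scenarios. With protective risks the cumulative avoided-death curve rises
and saturates; in late years the yearly increment can turn very slightly
negative (intervention survivors accumulate and eventually die), a genuine
feature of cohort models, bounded in the tests at below 0.5% of the
accumulated benefit per year.

A vectorized individual-level Monte-Carlo mirror with the same transition
grids serves as the correctness oracle; the proportional engine is its
expectation, and the two are required to agree within 3 Monte-Carlo
standard errors on yearly deaths and incident cases (50,000 individuals on
a three-age community).

## Static engine and comparison

Each year the static model multiplies the PIF by the expected deaths and
incident cases of an unperturbed projection. Two structural choices define
it: no quantity is carried between years except the demographic projection,
and the incidence expectation applies the population rate to the *whole*
projected population — prevalent cases are not removed from the at-risk
pool. The projection is the dynamic baseline scenario's own population
trajectory, so static-vs-dynamic comparisons isolate model structure, not
demography. Cumulative static/dynamic ratios are reported per outcome and
year; a non-positive dynamic cumulative yields NaN, never a propagated
infinity. At year 1 the mortality ratio is ≈1 by construction (the two
models share their first step up to O(rate²)); it then grows monotonically
as the dynamic model approaches its new steady state.

## Economics and uncertainty

Benefits: avoided deaths × VSL ($9.1M default, 2013 USDOT) plus avoided
disease burden × annual per-case costs. Because the costs are annual, the
default basis is avoided *prevalent case-years*; a per-incident-case mode
exists for sensitivity. Discounting is end-of-year at 5%/yr (3.5% and 7% as
sensitivity settings), construction cost undiscounted at year 0, no
maintenance costs. NPV + PV(costs) = PV(benefits) holds exactly (one shared
accumulation), and the breakeven year is the first year the cumulative
benefit-cost ratio reaches 1.

Uncertainty propagates through exactly five deterministic runs: central;
mortality RR at its lower/upper 95% bound (diseases central); all disease
RRs at lower/upper bounds (mortality central). Mortality CIs come from runs
2–3, disease CIs from runs 4–5. The single economic CI pairs the
lower-mortality-RR run with the lower-disease-RR run and the two upper runs
(each composite valued jointly, then sorted); this composition is a package
decision, flagged to users, since mortality and disease bounds are varied in
separate runs but a single NPV/BCR interval is reported. Note that for
protective risks the *lower* RR bound produces the *larger* benefit.

## Synthetic communities

`generate_community` emulates the statistical structure of small US
community inputs: a pyramid flat through midlife and tapering after 55, a
Gompertz-like mortality schedule (8×10⁻⁵·e^(0.088a), male rates 25% higher,
an infant bump), a 12/1000 crude birth rate, and age-quadratic prevalence
for CHD, type 2 diabetes, hypertension and stroke rising through adulthood.
Three profile kinds set the baseline walking distribution and construction
cost: urban (40.7/41.5/17.8%, mean 13.1 min/week, $3.48M), suburban
(84.3/12.3/3.4%, 12.5 min, $7.25M) and rural (85.4/12.1/2.5%, 10.4 min,
$686,157). Annual disease costs default to 9,400 / 6,600 / 1,000 / 7,200
USD per prevalent case-year (CHD / diabetes / hypertension / stroke),
chosen once as plausible cost-of-illness magnitudes. Only the pyramid draw
is stochastic; all rates are deterministic defaults, so bundles are
reproducible byte-for-byte for a fixed seed.

What the generator does *not* emulate: spatial (block-group) structure,
survey weighting and measurement error, migration, cohort trends in
mortality or disease, and correlations between walking behavior and
demography. Passing tests therefore demonstrate the correctness and
structural behavior of the models — calibration identities, oracle
equivalence, static-overestimation mechanics — not the empirical accuracy
of any specific community's published results, which would require the
original survey, census and GIS extracts.

## Problem sizes and numerical choices

Default runs use communities of 10,000–20,000 residents, a 40-year horizon,
and 50,000 Monte-Carlo individuals for oracle checks — sizes chosen so the
full suite executes in seconds while keeping Monte-Carlo standard errors
small relative to the effects tested. Simplex sums are validated to 1e-9;
calibration recombination is exact to machine precision; probabilities are
validated to [0,1] after every adjustment, and diseased death probabilities
are clipped at 1 with an explicit error if the excess pushes past it.

## Known limitations

- Parallel marginal disease chains ignore comorbidity and competing-risk
  interactions between the four diseases.
- The behavior estimators are linear/log-linear transfers with externally
  supplied coefficients; no activity substitution or self-selection.
- One health pathway only: physical activity. Air-pollution exposure and
  crash risk are out of scope.
- The static model is a reconstruction of the published design of
  single-year assessment tools, not a byte-level reimplementation of any
  specific tool; likewise the dynamic engine is not a replica of existing
  Java implementations.
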