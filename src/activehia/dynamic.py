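"""Proportional multistate Markov cohort engine (dynamic model).

The population is stratified by integer age (0-100, closed top bin), sex,
and walking-exposure category.  All-cause death is modeled as a two-state
alive/dead chain with category-specific annual death probabilities; each
chronic disease is a parallel three-state healthy/diseased/dead chain with
category-specific incidence and disease-specific excess mortality among
prevalent cases.  Diseases are simulated as independent marginal models
sharing the all-cause mortality schedule — the reported outcomes are
per-disease marginals, so no joint comorbidity states are carried.

Category-specific rates come from calibrating observed population rates to
the relative risks: i_ref = i_pop / Σ p_c RR_c, i_c = RR_c · i_ref, so the
baseline scenario reproduces the observed population rates exactly.  Walking
exposure is a fixed attribute within a scenario (the intervention is a
one-time step change in the category distribution at year 0); risks are
modified from age 18, younger ages carry RR 1.

Within each simulated year the event order is fixed: (1) disease incidence,
(2) deaths, (3) aging by one year, (4) births entering at age 0 (healthy, in
the scenario's category distribution).  Changing this order perturbs results
at second order in the rates, so it is part of the model contract.

A vectorized individual-level Monte-Carlo mirror
(:func:`microsim_oracle`) with the same transition probabilities serves as a
validation oracle: its expectation equals the proportional engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import (
    ADULT_AGE,
    AGES,
    CATEGORIES,
    SEXES,
    CommunityProfile,
    ExposureDistribution,
    ValidationError,
)
from .doseresponse import RelativeRiskSet
from .rates import AgeRateFunction, calibrate_category_incidence, incidence_from_prevalence

__all__ = [
    "BOUND_RUNS",
    "TransitionProbabilities",
    "ScenarioResult",
    "HealthImpact",
    "build_transitions",
    "run_scenario",
    "health_impact",
    "microsim_oracle",
]

#: The five bound configurations of the confidence-interval procedure:
#: central; mortality RR at its lower/upper CI bound with diseases central;
#: all disease RRs at their lower/upper bounds with mortality central.
BOUND_RUNS = (
    "central",
    "lower_mortality",
    "upper_mortality",
    "lower_disease",
    "upper_disease",
)

_N_AGE, _N_SEX, _N_CAT = len(AGES), len(SEXES), len(CATEGORIES)


def _bound_split(bound: str) -> tuple[str, str]:
    """Map a run label to (mortality RR bound, disease RR bound)."""
    table = {
        "central": ("central", "central"),
        "lower_mortality": ("lower", "central"),
        "upper_mortality": ("upper", "central"),
        "lower_disease": ("central", "lower"),
        "upper_disease": ("central", "upper"),
    }
    if bound not in table:
        raise ValidationError(f"bound must be one of {BOUND_RUNS}, got {bound!r}")
    return table[bound]


@dataclass(frozen=True)
class TransitionProbabilities:
    """Annual transition probabilities on the (category, age, sex) grid.

    ``mortality[c, a, s]`` is the all-cause death probability;
    ``incidence[d][c, a, s]`` the healthy→diseased probability for disease d;
    ``excess[d][a]`` the additional death probability of prevalent cases;
    ``prevalence0[d][a]`` the baseline prevalence used to seed year 0.
    """

    mortality: np.ndarray
    incidence: dict[str, np.ndarray]
    excess: dict[str, np.ndarray]
    prevalence0: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        arrays = [self.mortality, *self.incidence.values()]
        for arr in arrays:
            if arr.shape != (_N_CAT, _N_AGE, _N_SEX):
                raise ValidationError("transition grids must have shape (3, 101, 2)")
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError("transition probabilities must lie in [0, 1]")
        for d, xm in self.excess.items():
            if np.any(self.mortality + xm[None, :, None] > 1.0 + 1e-12):
                raise ValidationError(
                    f"diseased death probability exceeds 1 for disease {d}"
                )


def build_transitions(
    profile: CommunityProfile,
    exposure: ExposureDistribution,
    rr: RelativeRiskSet,
    bound: str = "central",
) -> TransitionProbabilities:
    """Calibrate category-specific transition probabilities for one RR bound.

    ``exposure`` is the distribution against which population rates are
    calibrated (normally the baseline distribution, for both scenarios, so
    that the baseline scenario reproduces observed rates).  Ages below 18
    carry identical probabilities in every category.
    """
    mort_bound, dis_bound = _bound_split(bound)
    young = AGES < ADULT_AGE

    rr_mort = rr.by_category("mortality", "combined", mort_bound)
    mortality = np.empty((_N_CAT, _N_AGE, _N_SEX))
    for s in range(_N_SEX):
        pop_m = AgeRateFunction("mortality", profile.mortality_rate[:, s])
        cal = calibrate_category_incidence(pop_m, exposure, rr_mort)
        for c, cat in enumerate(CATEGORIES):
            col = np.where(young, profile.mortality_rate[:, s], cal[cat])
            mortality[c, :, s] = col
    if np.any(mortality > 1.0):
        raise ValidationError("calibrated mortality exceeds 1; check RRs and rates")

    incidence: dict[str, np.ndarray] = {}
    excess: dict[str, np.ndarray] = {}
    prevalence0: dict[str, np.ndarray] = {}
    for dz in profile.diseases:
        p0 = dz.prevalence()
        xm = np.full(_N_AGE, dz.excess_mortality)
        i_pop = incidence_from_prevalence(
            AgeRateFunction("prevalence", p0),
            AgeRateFunction("mortality", profile.mortality_rate.mean(axis=1)),
            AgeRateFunction("excess_mortality", xm),
        )
        grid = np.empty((_N_CAT, _N_AGE, _N_SEX))
        for s, sex in enumerate(SEXES):
            rr_dz = rr.by_category(dz.name, sex, dis_bound)
            cal = calibrate_category_incidence(i_pop, exposure, rr_dz)
            for c, cat in enumerate(CATEGORIES):
                grid[c, :, s] = np.where(young, i_pop.values, cal[cat])
        if np.any(grid > 1.0):
            raise ValidationError(f"calibrated incidence exceeds 1 for {dz.name}")
        incidence[dz.name] = grid
        excess[dz.name] = xm
        prevalence0[dz.name] = p0
    return TransitionProbabilities(mortality, incidence, excess, prevalence0)


@dataclass
class ScenarioResult:
    """Yearly outputs of one scenario run (years 1..horizon).

    ``deaths``/``alive``/``births`` are totals from the all-cause model;
    ``incident[d]`` and ``prevalent[d]`` are per-disease new and end-of-year
    prevalent case counts from the parallel disease models.
    """

    horizon: int
    deaths: np.ndarray
    alive: np.ndarray
    births: np.ndarray
    incident: dict[str, np.ndarray]
    prevalent: dict[str, np.ndarray]
    alive_by_age: np.ndarray = field(default=None, repr=False)  # (horizon, 101, 2) start-of-year


def _age_shift(arr: np.ndarray) -> np.ndarray:
    """Advance everyone one year of age; the closed top bin accumulates."""
    out = np.zeros_like(arr)
    out[:, 1:, :] = arr[:, :-1, :]
    out[:, -1, :] += arr[:, -1, :]
    return out


def run_scenario(
    profile: CommunityProfile,
    exposure: ExposureDistribution,
    rr: RelativeRiskSet,
    horizon: int = 40,
    bound: str = "central",
    transitions: TransitionProbabilities | None = None,
) -> ScenarioResult:
    """Run the proportional engine for one scenario.

    ``exposure`` allocates the population across walking categories (the
    scenario's fixed distribution); rate calibration always uses the
    profile's baseline distribution so both scenarios share one calibrated
    rate set.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be >= 1")
    trans = transitions or build_transitions(profile, profile.baseline_exposure, rr, bound)

    shares = exposure.shares
    A = profile.population[None, :, :] * shares[:, None, None]  # alive, all-cause model
    H: dict[str, np.ndarray] = {}
    D: dict[str, np.ndarray] = {}
    for d, p0 in trans.prevalence0.items():
        D[d] = A * p0[None, :, None]
        H[d] = A - D[d]

    deaths = np.zeros(horizon)
    alive = np.zeros(horizon)
    births_out = np.zeros(horizon)
    alive_by_age = np.zeros((horizon, _N_AGE, _N_SEX))
    incident = {d: np.zeros(horizon) for d in H}
    prevalent = {d: np.zeros(horizon) for d in H}

    for t in range(horizon):
        alive_by_age[t] = A.sum(axis=0)
        # (1) disease incidence
        for d in H:
            new = H[d] * trans.incidence[d]
            H[d] = H[d] - new
            D[d] = D[d] + new
            incident[d][t] = new.sum()
        # (2) deaths
        dA = A * trans.mortality
        A = A - dA
        deaths[t] = dA.sum()
        for d in H:
            xm = trans.excess[d][None, :, None]
            H[d] = H[d] * (1.0 - trans.mortality)
            D[d] = D[d] * np.clip(1.0 - trans.mortality - xm, 0.0, 1.0)
        # (3) aging
        A = _age_shift(A)
        for d in H:
            H[d] = _age_shift(H[d])
            D[d] = _age_shift(D[d])
        # (4) births, healthy, split evenly by sex, scenario category shares
        b = A.sum() * profile.birth_rate / 1000.0
        newborn = b * 0.5 * shares[:, None]
        A[:, 0, :] += newborn
        for d in H:
            H[d][:, 0, :] += newborn
        births_out[t] = b
        alive[t] = A.sum()
        for d in H:
            prevalent[d][t] = D[d].sum()

    return ScenarioResult(
        horizon=horizon,
        deaths=deaths,
        alive=alive,
        births=births_out,
        incident=incident,
        prevalent=prevalent,
        alive_by_age=alive_by_age,
    )


@dataclass
class HealthImpact:
    """Yearly avoided outcomes: baseline scenario minus intervention scenario."""

    horizon: int
    avoided_deaths: np.ndarray
    avoided_incident: dict[str, np.ndarray]
    avoided_prevalent: dict[str, np.ndarray]

    def cumulative(self, year: int) -> dict[str, float]:
        """Cumulative avoided deaths and incident cases through ``year``."""
        if not 1 <= year <= self.horizon:
            raise ValidationError(f"year must lie in 1..{self.horizon}")
        out = {"mortality": float(self.avoided_deaths[:year].sum())}
        for d, v in self.avoided_incident.items():
            out[d] = float(v[:year].sum())
        return out


def health_impact(baseline: ScenarioResult, intervention: ScenarioResult) -> HealthImpact:
    """Difference of two scenario runs on a common horizon."""
    if baseline.horizon != intervention.horizon:
        raise ValidationError("baseline and intervention horizons must match")
    if set(baseline.incident) != set(intervention.incident):
        raise ValidationError("scenarios model different disease sets")
    return HealthImpact(
        horizon=baseline.horizon,
        avoided_deaths=baseline.deaths - intervention.deaths,
        avoided_incident={
            d: baseline.incident[d] - intervention.incident[d] for d in baseline.incident
        },
        avoided_prevalent={
            d: baseline.prevalent[d] - intervention.prevalent[d] for d in baseline.prevalent
        },
    )


# --------------------------------------------------------------------------
# Monte-Carlo validation oracle
# --------------------------------------------------------------------------


def microsim_oracle(
    profile: CommunityProfile,
    exposure: ExposureDistribution,
    rr: RelativeRiskSet,
    n_individuals: int,
    seed: int,
    horizon: int = 40,
    bound: str = "central",
) -> ScenarioResult:
    """Individual-level Monte-Carlo with the engine's transition probabilities.

    Samples ``n_individuals`` from the profile's population cells, simulates
    the same parallel all-cause and per-disease chains with the same yearly
    event order, and returns raw counts (scale by ``n / profile population``
    to compare with the proportional engine, whose expectation it matches).
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    trans = build_transitions(profile, profile.baseline_exposure, rr, bound)

    cellw = profile.population.ravel() / profile.population.sum()
    cells = rng.choice(profile.population.size, size=n_individuals, p=cellw)
    age = (cells // _N_SEX).astype(np.int64)
    sex = (cells % _N_SEX).astype(np.int64)
    cat = rng.choice(_N_CAT, size=n_individuals, p=exposure.shares)
    alive = np.ones(n_individuals, dtype=bool)

    dz_names = list(trans.prevalence0)
    state: dict[str, np.ndarray] = {}  # 0 healthy, 1 diseased, 2 dead
    for d in dz_names:
        diseased = rng.random(n_individuals) < trans.prevalence0[d][age]
        state[d] = diseased.astype(np.int8)

    deaths = np.zeros(horizon)
    alive_out = np.zeros(horizon)
    births_out = np.zeros(horizon)
    incident = {d: np.zeros(horizon) for d in dz_names}
    prevalent = {d: np.zeros(horizon) for d in dz_names}

    for t in range(horizon):
        # (1) incidence
        u = rng.random(age.size)
        for d in dz_names:
            healthy = state[d] == 0
            p = trans.incidence[d][cat, age, sex]
            hit = healthy & (rng.random(age.size) < p)
            state[d][hit] = 1
            incident[d][t] = hit.sum()
        # (2) deaths
        pm = trans.mortality[cat, age, sex]
        dies = alive & (u < pm)
        deaths[t] = dies.sum()
        alive &= ~dies
        for d in dz_names:
            px = pm + np.where(state[d] == 1, trans.excess[d][age], 0.0)
            gone = (state[d] != 2) & (rng.random(age.size) < np.clip(px, 0, 1))
            state[d][gone] = 2
        # (3) aging
        age = np.minimum(age + 1, _N_AGE - 1)
        # (4) births
        n_birth = rng.poisson(alive.sum() * profile.birth_rate / 1000.0)
        if n_birth > 0:
            age = np.concatenate([age, np.zeros(n_birth, dtype=np.int64)])
            sex = np.concatenate([sex, rng.integers(0, _N_SEX, n_birth)])
            cat = np.concatenate([cat, rng.choice(_N_CAT, size=n_birth, p=exposure.shares)])
            alive = np.concatenate([alive, np.ones(n_birth, dtype=bool)])
            for d in dz_names:
                state[d] = np.concatenate([state[d], np.zeros(n_birth, dtype=np.int8)])
        births_out[t] = n_birth
        alive_out[t] = alive.sum()
        for d in dz_names:
            prevalent[d][t] = (state[d] == 1).sum()

    return ScenarioResult(
        horizon=horizon,
        deaths=deaths,
        alive=alive_out,
        births=births_out,
        incident=incident,
        prevalent=prevalent,
    )
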