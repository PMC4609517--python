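"""Economic valuation, discounting, benefit-cost summaries and the five-run
relative-risk confidence-interval procedure.

Avoided premature deaths are valued at the value of a statistical life (VSL,
default $9.1M per death, the 2013 USDOT figure); avoided disease burden is
valued with annual per-case costs (treatment plus productivity losses).
Because disease costs are annual, the default valuation basis is avoided
prevalent case-years (baseline minus intervention prevalent counts each
year); a per-incident-case mode is also provided.  Benefits are discounted
end-of-year at a configurable rate (default 5%/yr; 3.5% and 7% are the
standard sensitivity settings), with the construction cost incurred
undiscounted at year 0.  Ongoing maintenance costs are not modeled.

Uncertainty in the relative risks propagates through five deterministic
model runs: central values; mortality RR at its lower then upper 95% bound
(diseases central); all disease RRs at their lower then upper bounds
(mortality central).  Mortality CIs come from runs 2-3, disease CIs from
runs 4-5, and the single economic CI pairs run 2 with run 4 and run 3 with
run 5 (each composite valued jointly, then sorted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .community import ValidationError
from .dynamic import BOUND_RUNS, HealthImpact

__all__ = [
    "EconomicConfig",
    "EconomicResult",
    "value_impacts",
    "mortality_benefit_share",
    "five_run_ci",
    "FiveRunResult",
]

CASE_MODES = ("prevalent_years", "incident")


@dataclass(frozen=True)
class EconomicConfig:
    """Valuation parameters (all monetary values in USD)."""

    vsl: float = 9.1e6
    discount_rate: float = 0.05
    construction_cost: float = 0.0
    horizon: int = 40
    case_mode: str = "prevalent_years"

    def __post_init__(self) -> None:
        if self.vsl < 0 or self.construction_cost < 0:
            raise ValidationError("costs and VSL must be >= 0")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.case_mode not in CASE_MODES:
            raise ValidationError(f"case_mode must be one of {CASE_MODES}")


@dataclass
class EconomicResult:
    """Discounted benefit stream and benefit-cost summaries.

    ``cumulative_npv[t]`` is cumulative discounted benefits through year t+1
    minus discounted costs; ``breakeven_year`` is the first year the
    cumulative benefit-cost ratio reaches 1, or None.
    """

    horizon: int
    discounted_benefits: np.ndarray
    cumulative_npv: np.ndarray
    cumulative_bcr: np.ndarray
    breakeven_year: int | None
    pv_benefits: float
    pv_costs: float
    pv_mortality: float
    pv_morbidity: float

    @property
    def npv(self) -> float:
        return float(self.cumulative_npv[-1])

    @property
    def bcr(self) -> float:
        return float(self.cumulative_bcr[-1])


def value_impacts(
    impact: HealthImpact,
    disease_costs: dict[str, float],
    config: EconomicConfig,
) -> EconomicResult:
    """Value yearly avoided outcomes and discount them to the present.

    Yearly benefit = avoided deaths x VSL plus, per disease, avoided
    prevalent case-years (or incident cases) x annual cost.  The first
    post-construction year is discounted by (1+r)^-1; the construction cost
    enters undiscounted at year 0.
    """
    horizon = min(impact.horizon, config.horizon)
    t = np.arange(1, horizon + 1)
    disc = (1.0 + config.discount_rate) ** (-t.astype(float))

    mort_stream = config.vsl * impact.avoided_deaths[:horizon]
    morb_stream = np.zeros(horizon)
    cases = (
        impact.avoided_prevalent
        if config.case_mode == "prevalent_years"
        else impact.avoided_incident
    )
    for d, series in cases.items():
        cost = disease_costs.get(d, 0.0)
        if cost < 0:
            raise ValidationError(f"negative annual cost for {d}")
        morb_stream += cost * series[:horizon]

    benefits = (mort_stream + morb_stream) * disc
    pv_costs = float(config.construction_cost)
    cum_benefits = np.cumsum(benefits)
    # share one accumulation so NPV + PV(costs) == PV(benefits) holds exactly
    pv_benefits = float(cum_benefits[-1]) if horizon else 0.0
    cumulative_npv = cum_benefits - pv_costs
    if pv_costs > 0:
        cumulative_bcr = cum_benefits / pv_costs
    else:
        cumulative_bcr = np.full(horizon, np.inf)
    reached = np.nonzero(cumulative_bcr >= 1.0)[0]
    breakeven = int(reached[0] + 1) if reached.size else None

    return EconomicResult(
        horizon=horizon,
        discounted_benefits=benefits,
        cumulative_npv=cumulative_npv,
        cumulative_bcr=cumulative_bcr,
        breakeven_year=breakeven,
        pv_benefits=pv_benefits,
        pv_costs=pv_costs,
        pv_mortality=float((mort_stream * disc).sum()),
        pv_morbidity=float((morb_stream * disc).sum()),
    )


def mortality_benefit_share(result: EconomicResult) -> float:
    """Share of the present value of health benefits attributable to mortality."""
    if result.pv_benefits <= 0:
        raise ValidationError("benefit share undefined for non-positive total benefits")
    return result.pv_mortality / result.pv_benefits


# --------------------------------------------------------------------------
# Five-run confidence intervals
# --------------------------------------------------------------------------


@dataclass
class FiveRunResult:
    """Central estimates plus RR-bound confidence intervals.

    ``impacts`` holds the five :class:`HealthImpact` runs keyed by bound
    label.  ``outcome_ci[outcome][year]`` is (central, lower, upper)
    cumulative avoided counts; ``econ_central``/``econ_ci`` summarize the
    valuation (``econ_ci`` maps 'npv'/'bcr' to (lower, upper)).
    """

    impacts: dict[str, HealthImpact]
    outcome_ci: dict[str, dict[int, tuple[float, float, float]]]
    econ_central: EconomicResult | None = None
    econ_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    econ_breakeven_ci: tuple[int | None, int | None] | None = None

    @property
    def n_runs(self) -> int:
        return len(self.impacts)


def _composite(mortality_run: HealthImpact, disease_run: HealthImpact) -> HealthImpact:
    """Mortality stream from one run, disease streams from another."""
    return HealthImpact(
        horizon=mortality_run.horizon,
        avoided_deaths=mortality_run.avoided_deaths,
        avoided_incident=disease_run.avoided_incident,
        avoided_prevalent=disease_run.avoided_prevalent,
    )


def five_run_ci(
    run: Callable[[str], HealthImpact],
    years: tuple[int, ...] = (10, 20, 40),
    value: Callable[[HealthImpact], EconomicResult] | None = None,
) -> FiveRunResult:
    """Execute the five bound configurations and assemble confidence intervals.

    ``run(bound)`` must be deterministic given the bound label.  Exactly five
    runs are executed (not a 2^k factorial): mortality-outcome CIs come from
    the two mortality-bound runs, disease-outcome CIs from the two
    disease-bound runs, and the economic CI from valuing the
    (lower-mortality, lower-disease) and (upper-mortality, upper-disease)
    composites jointly.
    """
    impacts: dict[str, HealthImpact] = {}
    for bound in BOUND_RUNS:
        try:
            impacts[bound] = run(bound)
        except Exception as exc:  # noqa: BLE001 - re-raise with the bound label
            raise RuntimeError(f"five-run CI: run failed for bound {bound!r}") from exc
    assert len(impacts) == 5

    central = impacts["central"]
    outcome_ci: dict[str, dict[int, tuple[float, float, float]]] = {}
    for year in years:
        if year > central.horizon:
            continue
        c = central.cumulative(year)
        m_lo = impacts["lower_mortality"].cumulative(year)
        m_hi = impacts["upper_mortality"].cumulative(year)
        d_lo = impacts["lower_disease"].cumulative(year)
        d_hi = impacts["upper_disease"].cumulative(year)
        for outcome, cval in c.items():
            pair = (m_lo, m_hi) if outcome == "mortality" else (d_lo, d_hi)
            lo, hi = sorted((pair[0][outcome], pair[1][outcome]))
            outcome_ci.setdefault(outcome, {})[year] = (cval, lo, hi)

    result = FiveRunResult(impacts=impacts, outcome_ci=outcome_ci)
    if value is not None:
        result.econ_central = value(central)
        econ_a = value(_composite(impacts["lower_mortality"], impacts["lower_disease"]))
        econ_b = value(_composite(impacts["upper_mortality"], impacts["upper_disease"]))
        result.econ_ci = {
            "npv": tuple(sorted((econ_a.npv, econ_b.npv))),
            "bcr": tuple(sorted((econ_a.bcr, econ_b.bcr))),
        }
        breakevens = (econ_a.breakeven_year, econ_b.breakeven_year)
        result.econ_breakeven_ci = breakevens
    return result
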