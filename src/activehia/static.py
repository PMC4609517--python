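"""Static (HEAT-style) impact model extended to morbidity, and the
static-vs-dynamic comparison.

The static model applies a constant potential impact fraction (PIF) to each
year's expected baseline deaths and incident cases: benefits do not accrue
from year to year for any individual, and disease prevalence is not carried
— the incidence expectation applies the population rate to the whole
projected population.  The demographic projection (births and baseline
deaths only, no intervention feedback) is the same one underlying the
dynamic baseline scenario, so comparisons isolate model structure rather
than demography.

For mortality the PIF can alternatively be computed in ``continuous_11bin``
mode: exposure mass is placed into eleven fine dose bins (a zero category
plus ten equal-width minute bins) and the continuous dose-response curve is
evaluated per bin, removing the categorical model's benefit cap at 150
min/week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AGES, SEXES, CommunityProfile, ValidationError
from .doseresponse import RelativeRiskSet, continuous_bins, impact_fraction
from .dynamic import HealthImpact, run_scenario
from .exposure import ExposureShift
from .rates import AgeRateFunction, incidence_from_prevalence

__all__ = ["StaticResult", "run_static", "compare_static_dynamic"]

DOSE_MODES = ("categorical", "continuous_11bin")


@dataclass
class StaticResult:
    """Yearly avoided outcomes from the static model (years 1..horizon)."""

    horizon: int
    avoided_deaths: np.ndarray
    avoided_incident: dict[str, np.ndarray]
    pif_mortality: float
    pif_disease: dict[str, dict[str, float]]  # disease -> sex -> PIF

    def cumulative(self, year: int) -> dict[str, float]:
        if not 1 <= year <= self.horizon:
            raise ValidationError(f"year must lie in 1..{self.horizon}")
        out = {"mortality": float(self.avoided_deaths[:year].sum())}
        for d, v in self.avoided_incident.items():
            out[d] = float(v[:year].sum())
        return out


def _mortality_pif(shift: ExposureShift, rr: RelativeRiskSet, dose_mode: str, bound: str) -> float:
    if dose_mode == "categorical":
        return impact_fraction(
            shift.before, shift.after, rr.by_category("mortality", "combined", bound)
        )
    reps, sh_before, rr_bins = continuous_bins(shift.before)
    _, sh_after, _ = continuous_bins(shift.after)
    denom = float(sh_before @ rr_bins)
    if denom == 0:
        raise ValidationError("zero denominator in continuous-bin impact fraction")
    return 1.0 - float(sh_after @ rr_bins) / denom


def run_static(
    profile: CommunityProfile,
    shift: ExposureShift,
    rr: RelativeRiskSet,
    horizon: int = 40,
    dose_mode: str = "categorical",
    bound: str = "central",
) -> StaticResult:
    """Run the static model: constant per-year impact fractions, no memory.

    Per year t, avoided deaths are PIF_mortality times the expected deaths of
    the unperturbed demographic projection, and avoided cases of each disease
    are the (sex-resolved) PIF times the expected incident cases with the
    population incidence rate applied to the whole projected population.
    """
    if dose_mode not in DOSE_MODES:
        raise ValidationError(f"dose_mode must be one of {DOSE_MODES}, got {dose_mode!r}")
    mort_bound = {"lower_mortality": "lower", "upper_mortality": "upper"}.get(bound, "central")
    dis_bound = {"lower_disease": "lower", "upper_disease": "upper"}.get(bound, "central")

    pif_mort = _mortality_pif(shift, rr, dose_mode, mort_bound)
    pif_dis: dict[str, dict[str, float]] = {}
    for dz in profile.diseases:
        pif_dis[dz.name] = {
            sex: impact_fraction(
                shift.before, shift.after, rr.by_category(dz.name, sex, dis_bound)
            )
            for sex in SEXES
        }

    # population incidence rates (same derivation the dynamic engine calibrates from)
    i_pop: dict[str, np.ndarray] = {}
    for dz in profile.diseases:
        i_pop[dz.name] = incidence_from_prevalence(
            AgeRateFunction("prevalence", dz.prevalence()),
            AgeRateFunction("mortality", profile.mortality_rate.mean(axis=1)),
            AgeRateFunction("excess_mortality", np.full(len(AGES), dz.excess_mortality)),
        ).values

    # demographic projection shared with the dynamic baseline scenario
    baseline = run_scenario(profile, profile.baseline_exposure, rr, horizon=horizon, bound=bound)

    avoided_deaths = pif_mort * baseline.deaths
    avoided_incident: dict[str, np.ndarray] = {}
    for dz in profile.diseases:
        per_year = np.zeros(horizon)
        for t in range(horizon):
            n_by_age = baseline.alive_by_age[t]  # (101, 2) start-of-year
            for s, sex in enumerate(SEXES):
                expected = float(n_by_age[:, s] @ i_pop[dz.name])
                per_year[t] += pif_dis[dz.name][sex] * expected
        avoided_incident[dz.name] = per_year

    return StaticResult(
        horizon=horizon,
        avoided_deaths=avoided_deaths,
        avoided_incident=avoided_incident,
        pif_mortality=pif_mort,
        pif_disease=pif_dis,
    )


def compare_static_dynamic(static: StaticResult, dynamic: HealthImpact) -> pd.DataFrame:
    """Cumulative static/dynamic ratio per outcome and year.

    Returns a tidy frame (year, outcome, cumulative_static, cumulative_dynamic,
    ratio); where the dynamic cumulative impact is not positive the ratio is
    NaN (undefined), never an infinity.
    """
    if static.horizon != dynamic.horizon:
        raise ValidationError("static and dynamic horizons must match")
    rows = []
    outcomes = {"mortality": (static.avoided_deaths, dynamic.avoided_deaths)}
    for d in static.avoided_incident:
        if d not in dynamic.avoided_incident:
            raise ValidationError(f"dynamic impact lacks disease {d}")
        outcomes[d] = (static.avoided_incident[d], dynamic.avoided_incident[d])
    for name, (s_series, d_series) in outcomes.items():
        cs = np.cumsum(s_series)
        cd = np.cumsum(d_series)
        ratio = np.where(cd > 0, cs / np.where(cd > 0, cd, 1.0), np.nan)
        for t in range(static.horizon):
            rows.append(
                {
                    "year": t + 1,
                    "outcome": name,
                    "cumulative_static": cs[t],
                    "cumulative_dynamic": cd[t],
                    "ratio": ratio[t],
                }
            )
    return pd.DataFrame(rows)
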