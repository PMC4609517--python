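"""Age-specific rate machinery: prevalence fits, incidence from prevalence,
and exposure-category calibration.

Chronic-disease incidence is rarely observed directly at community scale;
it can, however, be recovered from the age-prevalence curve and mortality via
the illness-death model's balance equation.  For a chronic (no-remission)
disease with prevalence p(a) and excess mortality Δm(a) among prevalent
cases, the stationary balance gives

    i(a) = [p'(a) + p(a) (1 - p(a)) Δm(a)] / (1 - p(a)),

which :func:`incidence_from_prevalence` evaluates on the integer age grid
with a central finite difference for p'.  The round trip (prevalence →
incidence → forward-simulated cohort prevalence) is exercised in the test
suite as the method's correctness oracle.

:func:`calibrate_category_incidence` splits a population rate across walking
categories carrying relative risks so that the category-weighted mean
reproduces the population rate exactly: i_ref = i_pop / Σ_c p_c RR_c and
i_c = RR_c · i_ref.  The same identity stratifies all-cause mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import AGES, CATEGORIES, ExposureDistribution, ValidationError

__all__ = [
    "AgeRateFunction",
    "fit_prevalence",
    "incidence_from_prevalence",
    "calibrate_category_incidence",
]

_KINDS = ("prevalence", "incidence", "mortality", "excess_mortality")


@dataclass(frozen=True)
class AgeRateFunction:
    """Values of one rate (or prevalence) on the integer age grid 0..100."""

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != AGES.shape:
            raise ValidationError(f"values must cover ages 0..100, got shape {v.shape}")
        if np.any(v < 0):
            raise ValidationError(f"{self.kind} values must be >= 0")
        if self.kind == "prevalence" and np.any(v > 1):
            raise ValidationError("prevalence must be <= 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeRateFunction):
            return NotImplemented
        return self.kind == other.kind and np.array_equal(self.values, other.values)


def fit_prevalence(ages, observed_prevalence) -> tuple[tuple[float, float, float], AgeRateFunction]:
    """Least-squares quadratic prevalence fit p(a) = c0 + c1 a + c2 a².

    Returns the coefficients and the fitted curve on the full age grid,
    clipped to [0, 1] (and to 0 below age 18, where the walking exposure and
    the chronic diseases modeled here are out of scope).
    """
    a = np.asarray(ages, dtype=float)
    y = np.asarray(observed_prevalence, dtype=float)
    if a.shape != y.shape:
        raise ValidationError("ages and observed_prevalence must align")
    if np.unique(a).size < 3:
        raise ValidationError("quadratic fit requires >= 3 distinct ages")
    X = np.vander(a, 3, increasing=True)  # columns 1, a, a^2
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValidationError("rank-deficient design in prevalence fit")
    c0, c1, c2 = (float(c) for c in coef)
    grid = np.clip(c0 + c1 * AGES + c2 * AGES.astype(float) ** 2, 0.0, 1.0)
    grid = np.where(AGES < 18, 0.0, grid)
    return (c0, c1, c2), AgeRateFunction("prevalence", grid)


def incidence_from_prevalence(
    prevalence: AgeRateFunction,
    mortality_healthy: AgeRateFunction,
    excess_mortality: AgeRateFunction,
) -> AgeRateFunction:
    """Derive incidence from prevalence and mortality via the illness-death balance.

    i(a) = [p'(a) + p(a)(1-p(a)) Δm(a)] / (1-p(a)), with p' a central finite
    difference (one-sided at the grid ends) and Δm the excess mortality of
    the diseased over the healthy (``mortality_healthy`` fixes the common
    baseline hazard and cancels from the balance).  Negative values are
    floored at 0 with a warning.
    """
    p = prevalence.values
    dm = excess_mortality.values
    if np.any(p >= 1.0):
        raise ValidationError("prevalence must be < 1 at every age")
    dp = np.gradient(p)  # central differences, one-sided at ends
    i = (dp + p * (1.0 - p) * dm) / (1.0 - p)
    if np.any(i < -1e-12):
        import warnings

        warnings.warn(
            "negative incidence values floored at 0 (declining prevalence "
            "steeper than mortality can explain)",
            stacklevel=2,
        )
    return AgeRateFunction("incidence", np.clip(i, 0.0, None))


def calibrate_category_incidence(
    pop_rate: AgeRateFunction,
    exposure: ExposureDistribution,
    rr_by_category,
) -> dict[str, np.ndarray]:
    """Split a population rate into per-category rates carrying the RRs.

    Returns ``{category: rate array}`` with i_c = RR_c · i_pop / Σ_c p_c RR_c,
    so the exposure-weighted mean equals the population rate at every age.
    Works identically for incidence and all-cause mortality.
    """
    if isinstance(rr_by_category, dict):
        rr = np.array([rr_by_category[c] for c in CATEGORIES])
    else:
        rr = np.asarray(rr_by_category, dtype=float)
    p = exposure.shares
    denom = float(p @ rr)
    if denom <= 0:
        raise ValidationError("exposure-weighted RR sum must be > 0")
    ref = pop_rate.values / denom
    return {c: rr[k] * ref for k, c in enumerate(CATEGORIES)}
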