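"""Built-environment → walking-behavior estimators.

Three estimators translate a proposed infrastructure change into an
:class:`ExposureShift` (a before/after pair of walking-category
distributions), one per kind of evidence typically available:

* :func:`walkability_to_shift` — a multidimensional walkability index
  (2*Z_intersection + Z_residential + Z_FAR + Z_landuse) drives a linear
  transfer of population from the low to the high walking category and a
  linear increase in mean weekly minutes, with coefficients supplied by
  configuration (the source regressions live in the walkability literature).
* :func:`sidewalk_shift` — sidewalk density D_s (km of sidewalk per km^2)
  changes the odds that a resident takes any weekly walk trip by a factor
  1.023 per unit density: odds_after = odds_before * 1.023**(D_after - D_before).
  New walkers are allocated to the low/high categories in proportion to the
  baseline split among walkers.
* :func:`pef_shift` — an ordinal pedestrian environment factor (PEF: sidewalk
  quality, crossing ease, topography, street-grid density, each scored 1-3)
  maps one ordinal class step to +0.92 km of weekly walking distance; at a
  4 km/h walking speed that is 13.8 added minutes per affected resident.

Every estimator maps a null built-environment change to a null shift, keeps
the after-distribution on the probability simplex, and conserves mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .community import CATEGORIES, ExposureDistribution, ValidationError

__all__ = [
    "WalkabilityInputs",
    "SidewalkDensities",
    "PEFAssessment",
    "ExposureShift",
    "WalkabilityMapping",
    "walkability_score",
    "landuse_entropy",
    "walkability_to_shift",
    "sidewalk_shift",
    "pef_class",
    "pef_shift",
    "brrc_walkability_fixture",
]

SIDEWALK_ODDS_PER_KM_KM2 = 1.023


@dataclass(frozen=True)
class WalkabilityInputs:
    """Raw walkability components plus the normalization stats forming Z-scores.

    ``landuse_components`` are area shares by use class; their normalized
    entropy is the land-use-diversity component.  ``means``/``sds`` hold the
    normalization statistics for (intersection_density, residential_density,
    retail_FAR, landuse_entropy), in that order.
    """

    intersection_density: float
    residential_density: float
    retail_FAR: float
    landuse_components: tuple[float, ...]
    means: tuple[float, float, float, float]
    sds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if min(self.intersection_density, self.residential_density, self.retail_FAR) < 0:
            raise ValidationError("walkability densities must be >= 0")
        if any(sd <= 0 for sd in self.sds):
            raise ValidationError("normalization SDs must be > 0")
        shares = np.asarray(self.landuse_components, float)
        if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
            raise ValidationError("land-use shares must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SidewalkDensities:
    """Sidewalk density (km per km^2) before and after construction."""

    d_before: float
    d_after: float

    def __post_init__(self) -> None:
        if self.d_before < 0 or self.d_after < 0:
            raise ValidationError("sidewalk densities must be >= 0")


@dataclass(frozen=True)
class PEFAssessment:
    """Pedestrian environment factor subscores, each on a 1-3 scale."""

    sidewalk_quality: int
    crossing_ease: int
    topography: int
    grid_density: int

    def __post_init__(self) -> None:
        for v in self.subscores:
            if v not in (1, 2, 3):
                raise ValidationError("PEF subscores must be integers in {1, 2, 3}")

    @property
    def subscores(self) -> tuple[int, int, int, int]:
        return (self.sidewalk_quality, self.crossing_ease, self.topography, self.grid_density)


@dataclass(frozen=True)
class ExposureShift:
    """Before/after walking-category distributions for one intervention.

    ``buffer_fraction`` is the proportion of the population affected by the
    intervention (1 unless the estimator restricted its reach); ``after`` is
    always the whole-population mixture.
    """

    before: ExposureDistribution
    after: ExposureDistribution
    buffer_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.buffer_fraction <= 1:
            raise ValidationError("buffer_fraction must lie in (0, 1]")
        if self.after.mean_minutes < self.before.mean_minutes - 1e-9:
            raise ValidationError(
                "interventions modeled here cannot reduce mean walking minutes"
            )


# --------------------------------------------------------------------------
# Walkability index
# --------------------------------------------------------------------------


def landuse_entropy(proportions) -> float:
    """Normalized land-use entropy −Σ pᵢ ln pᵢ / ln k ∈ [0, 1] over k use classes."""
    p = np.asarray(proportions, dtype=float)
    if p.size < 2:
        raise ValidationError("landuse_entropy requires at least 2 use classes")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("land-use shares must be >= 0 and sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def walkability_score(inputs: WalkabilityInputs) -> float:
    """2·Z_intersection + Z_residential + Z_FAR + Z_landuse with Z = (x − mean)/SD."""
    raw = np.array(
        [
            inputs.intersection_density,
            inputs.residential_density,
            inputs.retail_FAR,
            landuse_entropy(inputs.landuse_components),
        ]
    )
    z = (raw - np.asarray(inputs.means)) / np.asarray(inputs.sds)
    return float(np.array([2.0, 1.0, 1.0, 1.0]) @ z)


@dataclass(frozen=True)
class WalkabilityMapping:
    """Linear walkability-score → behavior coefficients (from external studies).

    ``low_to_high_per_unit``: proportion of total population moved from the
    low to the high category per unit score increase; ``minutes_per_unit``:
    added mean weekly minutes per unit score increase.
    """

    low_to_high_per_unit: float
    minutes_per_unit: float

    def __post_init__(self) -> None:
        if self.low_to_high_per_unit < 0 or self.minutes_per_unit < 0:
            raise ValidationError("walkability mapping coefficients must be >= 0")


def walkability_to_shift(
    score_before: float,
    score_after: float,
    baseline: ExposureDistribution,
    mapping: WalkabilityMapping,
) -> ExposureShift:
    """Shift exposure by a walkability-score change.

    Mass moves from the low to the high category (non-walkers are unchanged —
    the index captures intensification among existing walkers); the transfer
    is clipped at the available low-category mass, with a warning.
    """
    delta = score_after - score_before
    if delta < 0:
        raise ValidationError("negative walkability change not modeled")
    transfer = mapping.low_to_high_per_unit * delta
    if transfer > baseline.p_low + 1e-12:
        warnings.warn(
            f"requested low→high transfer {transfer:.4f} exceeds available "
            f"low-category mass {baseline.p_low:.4f}; capping",
            stacklevel=2,
        )
        transfer = baseline.p_low
    after = ExposureDistribution(
        baseline.p_none,
        baseline.p_low - transfer,
        baseline.p_high + transfer,
        baseline.mean_minutes + mapping.minutes_per_unit * delta,
    )
    return ExposureShift(before=baseline, after=after)


def brrc_walkability_fixture() -> dict:
    """Shipped urban-corridor walkability fixture (component values + mapping).

    Returns a dict with WalkabilityInputs ``before``/``after`` and the
    calibrated :class:`WalkabilityMapping` for the urban demo community.
    """
    with resources.files("activehia.data").joinpath("brrc_walkability.yaml").open() as fh:
        cfg = yaml.safe_load(fh)

    def build(block) -> WalkabilityInputs:
        return WalkabilityInputs(
            intersection_density=block["intersection_density"],
            residential_density=block["residential_density"],
            retail_FAR=block["retail_FAR"],
            landuse_components=tuple(block["landuse_components"]),
            means=tuple(cfg["normalization"]["means"]),
            sds=tuple(cfg["normalization"]["sds"]),
        )

    return {
        "before": build(cfg["before"]),
        "after": build(cfg["after"]),
        "mapping": WalkabilityMapping(**cfg["mapping"]),
    }


# --------------------------------------------------------------------------
# Sidewalk density odds model
# --------------------------------------------------------------------------


def sidewalk_shift(
    d: SidewalkDensities,
    baseline: ExposureDistribution,
    odds_per_unit: float = SIDEWALK_ODDS_PER_KM_KM2,
) -> ExposureShift:
    """Shift exposure via the sidewalk-density walking-odds model.

    The probability of taking any weekly walk trip is P_walk = 1 − p_none;
    its odds are multiplied by ``odds_per_unit ** (d_after − d_before)``.
    New walkers split between the low and high categories in proportion to
    the baseline low:high split; the mean is updated with the implied
    per-category survey means of the baseline distribution.
    """
    p_walk = 1.0 - baseline.p_none
    if p_walk <= 0 and d.d_after <= d.d_before:
        raise ValidationError("no walkers at baseline and no density increase")
    factor = odds_per_unit ** (d.d_after - d.d_before)
    if p_walk >= 1.0:
        p_walk_after = 1.0
    else:
        odds_after = p_walk / (1.0 - p_walk) * factor
        p_walk_after = odds_after / (1.0 + odds_after)
    new_walkers = p_walk_after - p_walk

    if p_walk > 0:
        frac_high = baseline.p_high / p_walk
    else:
        frac_high = 0.0
    p_low_after = baseline.p_low + new_walkers * (1.0 - frac_high)
    p_high_after = baseline.p_high + new_walkers * frac_high

    m_low, m_high = baseline.implied_category_means()
    mean_after = p_low_after * m_low + p_high_after * m_high
    after = ExposureDistribution(
        1.0 - p_walk_after, p_low_after, p_high_after, max(mean_after, baseline.mean_minutes)
    )
    return ExposureShift(before=baseline, after=after)


# --------------------------------------------------------------------------
# Pedestrian environment factor
# --------------------------------------------------------------------------

_PEF_CLASSES = ("low", "medium", "high")


def pef_class(assessment: PEFAssessment) -> str:
    """Ordinal PEF class from the subscore sum: 4–6 low, 7–9 medium, 10–12 high."""
    total = sum(assessment.subscores)
    if total <= 6:
        return "low"
    if total <= 9:
        return "medium"
    return "high"


def pef_shift(
    before: PEFAssessment,
    after: PEFAssessment,
    baseline: ExposureDistribution,
    buffer_fraction: float = 1.0,
    walking_speed_kmh: float = 4.0,
    km_per_class_step: float = 0.92,
) -> ExposureShift:
    """Shift exposure via an ordinal PEF class change.

    Each class step adds ``km_per_class_step`` km of weekly walking distance
    per affected resident, i.e. ``km_per_class_step / walking_speed_kmh * 60``
    minutes (13.8 min for one step at the defaults).  Within the affected
    buffer population the walking-category shares are scaled proportionally
    upward so the buffer mean rises by exactly the added minutes; the
    population result is the buffer/non-buffer mixture.
    """
    if not 0 < buffer_fraction <= 1:
        raise ValidationError("buffer_fraction must lie in (0, 1]")
    steps = _PEF_CLASSES.index(pef_class(after)) - _PEF_CLASSES.index(pef_class(before))
    if steps <= 0:
        return ExposureShift(before=baseline, after=baseline, buffer_fraction=buffer_fraction)
    added = km_per_class_step * steps / walking_speed_kmh * 60.0
    if baseline.mean_minutes <= 0:
        raise ValidationError("cannot rescale a zero-mean baseline distribution")
    scale = (baseline.mean_minutes + added) / baseline.mean_minutes
    buf_low = baseline.p_low * scale
    buf_high = baseline.p_high * scale
    if buf_low + buf_high > 1.0:
        # cap: everyone in the buffer walks; proportions renormalized
        warnings.warn("PEF rescale exceeded the simplex; capping walker share at 1", stacklevel=2)
        norm = buf_low + buf_high
        buf_low, buf_high = buf_low / norm, buf_high / norm
    buf_none = 1.0 - buf_low - buf_high

    w = buffer_fraction
    after_dist = ExposureDistribution(
        (1 - w) * baseline.p_none + w * buf_none,
        (1 - w) * baseline.p_low + w * buf_low,
        (1 - w) * baseline.p_high + w * buf_high,
        baseline.mean_minutes + w * added,
    )
    return ExposureShift(before=baseline, after=after_dist, buffer_fraction=buffer_fraction)
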