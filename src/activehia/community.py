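"""Community input bundles: demography, vital rates, disease epidemiology, baseline walking.

A :class:`CommunityProfile` holds everything the downstream models need for one
community: an age-by-sex population pyramid on integer ages 0–100, age- and
sex-specific all-cause mortality, a crude birth rate, a list of chronic-disease
specifications (age-quadratic prevalence, annual cost, excess mortality), the
baseline distribution of weekly transportation-walking time over the three CDC
categories (none / 1–149 / 150+ min per week), and the construction cost of the
proposed infrastructure.

:func:`generate_community` builds synthetic bundles with the statistical
structure of small US communities (a plausible age pyramid, Gompertz-like
mortality, age-increasing chronic-disease prevalence, and a walking
distribution dominated by non-walkers), so the whole pipeline is runnable and
testable without any survey or census extract.  :func:`write_community` /
:func:`read_community` round-trip a profile through a directory of plain CSV
files plus a small YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGES",
    "SEXES",
    "CATEGORIES",
    "ADULT_AGE",
    "ValidationError",
    "ExposureDistribution",
    "DiseaseSpec",
    "CommunityProfile",
    "generate_community",
    "write_community",
    "read_community",
]

#: Integer age grid, closed top bin at 100.
AGES = np.arange(101)
SEXES = ("male", "female")
CATEGORIES = ("none", "low", "high")
#: Age from which walking exposure modifies risks; younger ages carry RR 1.
ADULT_AGE = 18

DISEASE_NAMES = ("CHD", "type2_diabetes", "hypertension", "stroke")


class ValidationError(ValueError):
    """An input bundle violates a structural invariant (named in the message)."""


@dataclass(frozen=True)
class ExposureDistribution:
    """Population shares over the three weekly transportation-walking categories.

    ``mean_minutes`` is the survey-reported average weekly walking time.  It is
    stored independently of the category shares: surveyed means are generally
    inconsistent with midpoint arithmetic on the category bins, so the two are
    deliberately decoupled.
    """

    p_none: float
    p_low: float
    p_high: float
    mean_minutes: float

    def __post_init__(self) -> None:
        shares = (self.p_none, self.p_low, self.p_high)
        if any(p < -1e-12 for p in shares):
            raise ValidationError(f"exposure proportions must be >= 0, got {shares}")
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValidationError(
                f"exposure proportions must sum to 1 (got {sum(shares):.12f})"
            )
        if self.mean_minutes < 0:
            raise ValidationError("mean_minutes must be >= 0")

    @property
    def shares(self) -> np.ndarray:
        """Category shares as an array ordered (none, low, high)."""
        return np.array([self.p_none, self.p_low, self.p_high])

    def implied_category_means(self, high_low_ratio: float = 2.0) -> tuple[float, float]:
        """Back-solve per-category mean minutes (m_low, m_high) from (shares, mean).

        The zero category contributes 0 minutes; the remaining single equation
        is closed with the convention ``m_high = high_low_ratio * m_low``
        (default 2, the 150:75 category-midpoint ratio).  This is an
        approximation used only to update survey means after a categorical
        shift.
        """
        w = self.p_low + high_low_ratio * self.p_high
        if w <= 0:
            return 0.0, 0.0
        m_low = self.mean_minutes / w
        return m_low, high_low_ratio * m_low


@dataclass(frozen=True)
class DiseaseSpec:
    """One chronic disease: age-quadratic prevalence, costs, excess mortality.

    ``prevalence_coeffs`` are (c0, c1, c2) of p(a) = c0 + c1*a + c2*a**2,
    evaluated on ages 18–100 and clipped to [0, 1]; prevalence is 0 below 18.
    ``excess_mortality`` is the additional annual death probability of a
    prevalent case over a healthy person of the same age (chronic diseases,
    no remission).
    """

    name: str
    prevalence_coeffs: tuple[float, float, float]
    annual_cost: float = 0.0
    excess_mortality: float = 0.0

    def __post_init__(self) -> None:
        if len(self.prevalence_coeffs) != 3:
            raise ValidationError(f"{self.name}: prevalence_coeffs must have 3 entries")
        if self.annual_cost < 0:
            raise ValidationError(f"{self.name}: annual_cost must be >= 0")
        if self.excess_mortality < 0:
            raise ValidationError(f"{self.name}: excess_mortality must be >= 0")

    def prevalence(self, ages: np.ndarray | None = None) -> np.ndarray:
        """Prevalence on the age grid, clipped to [0, 1], zero below age 18."""
        a = AGES if ages is None else np.asarray(ages)
        c0, c1, c2 = self.prevalence_coeffs
        p = np.clip(c0 + c1 * a + c2 * a**2, 0.0, 1.0)
        return np.where(a < ADULT_AGE, 0.0, p)


@dataclass
class CommunityProfile:
    """All baseline inputs for one community.

    ``population`` and ``mortality_rate`` are (101, 2) arrays indexed by
    (age 0..100, sex male/female); ``birth_rate`` is births per 1000
    population per year.
    """

    name: str
    population: np.ndarray
    mortality_rate: np.ndarray
    birth_rate: float
    diseases: list[DiseaseSpec]
    baseline_exposure: ExposureDistribution
    construction_cost: float = 0.0

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.mortality_rate = np.asarray(self.mortality_rate, dtype=float)
        for arr, nm in ((self.population, "population"), (self.mortality_rate, "mortality_rate")):
            if arr.shape != (len(AGES), len(SEXES)):
                raise ValidationError(f"{nm} must have shape (101, 2), got {arr.shape}")
        if np.any(self.population < 0):
            raise ValidationError("population counts must be >= 0")
        if np.any((self.mortality_rate < 0) | (self.mortality_rate > 1)):
            raise ValidationError("mortality_rate must lie in [0, 1]")
        if self.birth_rate < 0:
            raise ValidationError("birth_rate must be >= 0")
        if self.construction_cost < 0:
            raise ValidationError("construction_cost must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityProfile):
            return NotImplemented
        return (
            self.name == other.name
            and np.array_equal(self.population, other.population)
            and np.array_equal(self.mortality_rate, other.mortality_rate)
            and self.birth_rate == other.birth_rate
            and self.diseases == other.diseases
            and self.baseline_exposure == other.baseline_exposure
            and self.construction_cost == other.construction_cost
        )

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    def disease(self, name: str) -> DiseaseSpec:
        for d in self.diseases:
            if d.name == name:
                return d
        raise KeyError(f"no disease named {name!r} in profile {self.name!r}")


# --------------------------------------------------------------------------
# Synthetic generation
# --------------------------------------------------------------------------

# Baseline walking distributions by development context, matching the shares
# observed in small North Carolina communities (urban corridor, suburban town,
# rural main-street town): (p_none, p_low, p_high, mean weekly minutes).
_EXPOSURE_BY_KIND = {
    "urban": (0.407, 0.415, 0.178, 13.1),
    "suburban": (0.843, 0.123, 0.034, 12.5),
    "rural": (0.854, 0.121, 0.025, 10.4),
}

# Construction costs (USD) typical of the three project archetypes: an urban
# small-area plan, a suburban comprehensive sidewalk plan, a rural streetscape.
_COST_BY_KIND = {"urban": 3.48e6, "suburban": 7.25e6, "rural": 686_157.0}

# Age-quadratic prevalence coefficients (c0, c1, c2); all four increase with
# age over 18–100 and stay within [0, 1] after clipping.
_DISEASE_DEFAULTS = {
    # name: (c0, c1, c2, annual_cost USD/case-year, excess annual mortality)
    "CHD": (-0.030, 0.0008, 2.2e-5, 9400.0, 0.010),
    "type2_diabetes": (-0.040, 0.0024, 1.0e-5, 6600.0, 0.005),
    "hypertension": (-0.050, 0.0040, 3.0e-5, 1000.0, 0.0),
    "stroke": (-0.012, 0.0004, 1.0e-5, 7200.0, 0.015),
}


def _pyramid_weights() -> np.ndarray:
    """Relative population weights by age: flat through midlife, tapering late."""
    a = AGES.astype(float)
    w = np.ones_like(a)
    w[a > 55] = np.exp(-((a[a > 55] - 55.0) / 22.0) ** 2)
    w[a < 20] *= 0.9
    return w / w.sum()


def _mortality_schedule() -> np.ndarray:
    """Gompertz-like annual death probability by (age, sex), male rates higher."""
    a = AGES.astype(float)
    base = 8e-5 * np.exp(0.088 * a)
    base[0] += 0.006  # infant mortality bump
    m = np.stack([np.minimum(base * 1.25, 0.6), np.minimum(base * 0.95, 0.6)], axis=1)
    return m


def generate_community(
    seed: int,
    size: int,
    profile_kind: str,
    *,
    name: str | None = None,
) -> CommunityProfile:
    """Generate a synthetic community of ``size`` residents.

    ``profile_kind`` ∈ {urban, suburban, rural} sets the baseline walking
    distribution, construction cost and name defaults; the age pyramid,
    mortality schedule and disease prevalence functions are shared.  The
    pyramid is a multinomial draw (so bundles are reproducible for a fixed
    seed); rates and coefficients are deterministic defaults.
    """
    if profile_kind not in _EXPOSURE_BY_KIND:
        raise ValidationError(
            f"unknown profile_kind {profile_kind!r}; expected one of "
            f"{sorted(_EXPOSURE_BY_KIND)}"
        )
    if size < 100:
        raise ValidationError("size must be >= 100")

    rng = np.random.default_rng(seed)
    cell_w = np.outer(_pyramid_weights(), [0.49, 0.51]).ravel()
    counts = rng.multinomial(size, cell_w / cell_w.sum()).reshape(len(AGES), 2)

    p_none, p_low, p_high, mean_min = _EXPOSURE_BY_KIND[profile_kind]
    diseases = [
        DiseaseSpec(nm, (c0, c1, c2), annual_cost=cost, excess_mortality=xm)
        for nm, (c0, c1, c2, cost, xm) in _DISEASE_DEFAULTS.items()
    ]
    return CommunityProfile(
        name=name or f"{profile_kind}-synthetic",
        population=counts.astype(float),
        mortality_rate=_mortality_schedule(),
        birth_rate=12.0,
        diseases=diseases,
        baseline_exposure=ExposureDistribution(p_none, p_low, p_high, mean_min),
        construction_cost=_COST_BY_KIND[profile_kind],
    )


# --------------------------------------------------------------------------
# CSV/YAML round trip
# --------------------------------------------------------------------------


def write_community(profile: CommunityProfile, directory: str | Path) -> list[Path]:
    """Write a profile as population/mortality/prevalence/exposure CSVs + YAML."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pop = pd.DataFrame(
        [
            (int(a), s, profile.population[a, j])
            for a in AGES
            for j, s in enumerate(SEXES)
        ],
        columns=["age", "sex", "count"],
    )
    mort = pd.DataFrame(
        [
            (int(a), s, profile.mortality_rate[a, j])
            for a in AGES
            for j, s in enumerate(SEXES)
        ],
        columns=["age", "sex", "rate"],
    )
    prev = pd.DataFrame(
        [(dz.name, *dz.prevalence_coeffs) for dz in profile.diseases],
        columns=["disease", "c0", "c1", "c2"],
    )
    expo = pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "proportion": profile.baseline_exposure.shares,
        }
    )
    for fn, df in (
        ("population.csv", pop),
        ("mortality.csv", mort),
        ("prevalence.csv", prev),
        ("exposure.csv", expo),
    ):
        path = d / fn
        df.to_csv(path, index=False)
        written.append(path)

    meta = {
        "name": profile.name,
        "birth_rate": float(profile.birth_rate),
        "construction_cost": float(profile.construction_cost),
        "mean_minutes": float(profile.baseline_exposure.mean_minutes),
        "diseases": {
            dz.name: {
                "annual_cost": float(dz.annual_cost),
                "excess_mortality": float(dz.excess_mortality),
            }
            for dz in profile.diseases
        },
    }
    ypath = d / "community.yaml"
    ypath.write_text(yaml.safe_dump(meta, sort_keys=True))
    written.append(ypath)
    return written


def _require(path: Path) -> Path:
    if not path.exists():
        raise ValidationError(f"missing community file: {path.name}")
    return path


def read_community(directory: str | Path) -> CommunityProfile:
    """Read a profile written by :func:`write_community`, validating each field."""
    d = Path(directory)
    meta = yaml.safe_load(_require(d / "community.yaml").read_text())

    # round_trip float parsing: read(write(x)) must equal x bit-for-bit
    kw = {"float_precision": "round_trip"}
    pop_df = pd.read_csv(_require(d / "population.csv"), **kw)
    mort_df = pd.read_csv(_require(d / "mortality.csv"), **kw)
    prev_df = pd.read_csv(_require(d / "prevalence.csv"), **kw)
    expo_df = pd.read_csv(_require(d / "exposure.csv"), **kw)

    def to_grid(df: pd.DataFrame, value: str, fname: str) -> np.ndarray:
        grid = np.full((len(AGES), len(SEXES)), np.nan)
        try:
            ages = df["age"].to_numpy(dtype=int)
            sexes = np.array([SEXES.index(s) for s in df["sex"]])
            grid[ages, sexes] = df[value].to_numpy(dtype=float)
        except (KeyError, ValueError, IndexError) as exc:
            raise ValidationError(f"{fname}: malformed rows ({exc})") from exc
        if np.isnan(grid).any():
            raise ValidationError(f"{fname}: incomplete age x sex grid")
        return grid

    expo_map = dict(zip(expo_df["category"], expo_df["proportion"]))
    if set(expo_map) != set(CATEGORIES):
        raise ValidationError(f"exposure.csv: categories must be {CATEGORIES}")
    exposure = ExposureDistribution(
        expo_map["none"], expo_map["low"], expo_map["high"], meta["mean_minutes"]
    )

    disease_meta = meta.get("diseases", {})
    diseases = [
        DiseaseSpec(
            name,
            (float(c0), float(c1), float(c2)),
            annual_cost=disease_meta.get(name, {}).get("annual_cost", 0.0),
            excess_mortality=disease_meta.get(name, {}).get("excess_mortality", 0.0),
        )
        for name, c0, c1, c2 in zip(
            prev_df["disease"], prev_df["c0"], prev_df["c1"], prev_df["c2"]
        )
    ]
    return CommunityProfile(
        name=meta["name"],
        population=to_grid(pop_df, "count", "population.csv"),
        mortality_rate=to_grid(mort_df, "rate", "mortality.csv"),
        birth_rate=meta["birth_rate"],
        diseases=diseases,
        baseline_exposure=exposure,
        construction_cost=meta["construction_cost"],
    )
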