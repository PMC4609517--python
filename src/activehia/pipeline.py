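"""End-to-end pipeline driver and summary reporting.

:func:`run_pipeline` executes the full chain for one community — generate or
load the input bundle, estimate the exposure shift, run the dynamic model
under the five relative-risk bound configurations, optionally run the static
model and the static/dynamic comparison, value the benefits — and writes all
artifacts (CSVs, a Table-style summary, and a manifest with the seed and a
config hash) into an output directory.  :func:`render_summary` produces the
summary table on its own.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import (
    CommunityProfile,
    ValidationError,
    generate_community,
    read_community,
    write_community,
)
from .doseresponse import RelativeRiskSet
from .dynamic import HealthImpact, health_impact, run_scenario
from .economics import EconomicConfig, FiveRunResult, five_run_ci, value_impacts
from .exposure import (
    ExposureShift,
    SidewalkDensities,
    PEFAssessment,
    brrc_walkability_fixture,
    pef_shift,
    sidewalk_shift,
    walkability_score,
    walkability_to_shift,
)
from .static import StaticResult, compare_static_dynamic, run_static

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_summary", "estimate_shift"]

_MARK_YEARS = (10, 20, 40)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    seed: int = 0
    community_dir: str | None = None  # read an existing bundle, else generate
    profile_kind: str = "urban"
    community_size: int = 20_000
    method: str = "walkability"  # walkability | sidewalk | pef
    method_params: dict = field(default_factory=dict)
    engine: str = "both"  # dynamic | static | both
    horizon: int = 40
    discount_rate: float = 0.05
    vsl: float = 9.1e6
    output_dir: str = "activehia_out"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in RunConfig.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def estimate_shift(profile: CommunityProfile, method: str, params: dict) -> ExposureShift:
    """Dispatch to one of the three built-environment estimators."""
    baseline = profile.baseline_exposure
    if method == "walkability":
        if params:
            before = params["score_before"]
            after = params["score_after"]
            from .exposure import WalkabilityMapping

            mapping = WalkabilityMapping(
                params["low_to_high_per_unit"], params["minutes_per_unit"]
            )
        else:  # shipped urban-corridor fixture
            fx = brrc_walkability_fixture()
            before = walkability_score(fx["before"])
            after = walkability_score(fx["after"])
            mapping = fx["mapping"]
        return walkability_to_shift(before, after, baseline, mapping)
    if method == "sidewalk":
        d = SidewalkDensities(
            params.get("d_before", 0.8), params.get("d_after", 3.8)
        )
        return sidewalk_shift(d, baseline)
    if method == "pef":
        before = PEFAssessment(*params.get("before", (1, 1, 1, 1)))
        after = PEFAssessment(*params.get("after", (3, 3, 1, 1)))
        return pef_shift(
            before,
            after,
            baseline,
            buffer_fraction=params.get("buffer_fraction", 0.25),
        )
    raise ValidationError(f"unknown exposure method {method!r}")


@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run."""

    profile: CommunityProfile
    shift: ExposureShift
    five_run: FiveRunResult
    static: StaticResult | None
    comparison: pd.DataFrame | None
    summary: pd.DataFrame
    output_dir: Path


def _ci(x: float, lo: float, hi: float, nd: int = 1) -> str:
    return f"{x:.{nd}f} ({lo:.{nd}f}–{hi:.{nd}f})"


def render_summary(
    shift: ExposureShift,
    five_run: FiveRunResult,
    horizon: int,
) -> pd.DataFrame:
    """Summary table: walking outcomes, health outcomes with CI, economics.

    Rows mirror the standard reporting layout: the three walking-category
    shares and the mean before/after, cumulative avoided outcomes at 10/20/40
    years formatted ``x (lo–hi)``, NPV/BCR with CI, and the breakeven year.
    """
    rows: list[dict] = []
    b, a = shift.before, shift.after
    for label, pb, pa in (
        ("No walking (percent)", b.p_none, a.p_none),
        ("1-149 min/week (percent)", b.p_low, a.p_low),
        ("150+ min/week (percent)", b.p_high, a.p_high),
    ):
        rows.append(
            {
                "section": "walking",
                "row": label,
                "before": f"{100 * pb:.1f}%",
                "after": f"{100 * pa:.1f}%",
                "change": f"{100 * (pa - pb):+.1f}%",
            }
        )
    rows.append(
        {
            "section": "walking",
            "row": "Ave. walk time (min/week)",
            "before": f"{b.mean_minutes:.1f}",
            "after": f"{a.mean_minutes:.1f}",
            "change": f"{a.mean_minutes - b.mean_minutes:+.1f}",
        }
    )

    labels = {
        "mortality": "Avoided premature mortality",
        "CHD": "Avoided cases of CHD",
        "type2_diabetes": "Avoided cases of type 2 diabetes",
        "hypertension": "Avoided cases of hypertension",
        "stroke": "Avoided cases of stroke",
    }
    marks = [y for y in _MARK_YEARS if y <= horizon]
    for outcome, per_year in five_run.outcome_ci.items():
        row = {"section": "health", "row": labels.get(outcome, outcome)}
        for y in marks:
            if y in per_year:
                row[f"year_{y}"] = _ci(*per_year[y])
            else:
                row[f"year_{y}"] = "unavailable"
        rows.append(row)

    econ = five_run.econ_central
    if econ is not None:
        npv_ci = five_run.econ_ci.get("npv", (econ.npv, econ.npv))
        bcr_ci = five_run.econ_ci.get("bcr", (econ.bcr, econ.bcr))
        row_npv = {"section": "economic", "row": "Net present value (USD M)"}
        row_bcr = {"section": "economic", "row": "Benefit-cost ratio"}
        for y in marks:
            idx = y - 1
            row_npv[f"year_{y}"] = f"{econ.cumulative_npv[idx] / 1e6:.1f}M"
            row_bcr[f"year_{y}"] = f"{econ.cumulative_bcr[idx]:.1f}"
        row_npv[f"year_{marks[-1]}"] = _ci(
            econ.npv / 1e6, npv_ci[0] / 1e6, npv_ci[1] / 1e6
        )
        row_bcr[f"year_{marks[-1]}"] = _ci(econ.bcr, *bcr_ci)
        rows.extend([row_npv, row_bcr])
        be = econ.breakeven_year
        rows.append(
            {
                "section": "economic",
                "row": "Time for B:C to exceed 1",
                f"year_{marks[-1]}": f"{be} years" if be else "Benefits do not exceed costs",
            }
        )
    else:
        rows.append({"section": "economic", "row": "unavailable"})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full assessment pipeline and write artifacts.

    Any stage failure is re-raised wrapped with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sub_seed = int(rng.integers(0, 2**31 - 1))

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.community_dir:
        profile = stage("load_community", read_community, config.community_dir)
    else:
        profile = stage(
            "generate_community",
            generate_community,
            sub_seed,
            config.community_size,
            config.profile_kind,
        )
    stage("write_community", write_community, profile, out / "community")

    shift = stage("exposure_shift", estimate_shift, profile, config.method, config.method_params)
    pd.DataFrame(
        {
            "scenario": ["before"] * 3 + ["after"] * 3,
            "category": ["none", "low", "high"] * 2,
            "proportion": np.concatenate([shift.before.shares, shift.after.shares]),
            "mean_minutes": [shift.before.mean_minutes] * 3 + [shift.after.mean_minutes] * 3,
        }
    ).to_csv(out / "exposure_shift.csv", index=False)

    rr = RelativeRiskSet.default()
    costs = {dz.name: dz.annual_cost for dz in profile.diseases}
    econ_cfg = EconomicConfig(
        vsl=config.vsl,
        discount_rate=config.discount_rate,
        construction_cost=profile.construction_cost,
        horizon=config.horizon,
    )

    def run_impact(bound: str) -> HealthImpact:
        base = run_scenario(profile, shift.before, rr, config.horizon, bound)
        interv = run_scenario(profile, shift.after, rr, config.horizon, bound)
        return health_impact(base, interv)

    five = stage(
        "dynamic_model",
        five_run_ci,
        run_impact,
        tuple(y for y in _MARK_YEARS if y <= config.horizon) or (config.horizon,),
        lambda imp: value_impacts(imp, costs, econ_cfg),
    )

    impact_rows = []
    central = five.impacts["central"]
    for t in range(central.horizon):
        impact_rows.append({"year": t + 1, "outcome": "mortality", "avoided": central.avoided_deaths[t]})
        for d in central.avoided_incident:
            impact_rows.append({"year": t + 1, "outcome": d, "avoided": central.avoided_incident[d][t]})
    pd.DataFrame(impact_rows).to_csv(out / "impact.csv", index=False)

    econ = five.econ_central
    pd.DataFrame(
        {
            "year": np.arange(1, econ.horizon + 1),
            "discounted_benefit": econ.discounted_benefits,
            "cumulative_NPV": econ.cumulative_npv,
            "cumulative_BCR": econ.cumulative_bcr,
        }
    ).to_csv(out / "valuation.csv", index=False)

    static_res = None
    comparison = None
    if config.engine in ("static", "both"):
        static_res = stage("static_model", run_static, profile, shift, rr, config.horizon)
    if config.engine == "both":
        comparison = stage("comparison", compare_static_dynamic, static_res, central)
        comparison.to_csv(out / "ratio.csv", index=False)

    summary = stage("render_summary", render_summary, shift, five, config.horizon)
    summary.to_csv(out / "summary.csv", index=False)

    manifest = {
        "config": config.__dict__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "community": profile.name,
        "engine": config.engine,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        profile=profile,
        shift=shift,
        five_run=five,
        static=static_res,
        comparison=comparison,
        summary=summary,
        output_dir=out,
    )
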