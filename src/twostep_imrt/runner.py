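"""End-to-end experiment runner and plan serialization.

``run_experiment`` reproduces the study design on a synthetic case: build
each plan recipe, fine-tune it with the shared engine and objective set,
then report a summary table (MU_eff, field #, segment #, normalized COV,
S_D/n, delivery time on the old and new machine presets) side by side.
All results are for synthetic phantoms with this package's in-house
optimizer and dose model — the summary is watermarked accordingly.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .bev import Beam, MLCModel, mlc_preset
from .dose import BeamContextCache, calibrate, compute_influence, plan_dose
from .metrics import build_quality_report
from .optimize import OptimizerConfig, optimize_plan
from .phantoms import make_objective_template, make_phantom
from .segmentation import (
    Aperture,
    Plan,
    Segment,
    SegmentationParams,
    SegmentOrder,
    build_fast_plan,
    build_multisegment_plan,
)
from .timing import PlanDeliveryStats, machine_preset, time_report

__all__ = [
    "PlanRecipe",
    "RunConfig",
    "ExperimentResult",
    "run_experiment",
    "load_config",
    "save_plan",
    "load_plan",
]

PLAN_SCHEMA = "twostep-imrt-plan/1"


@dataclass
class PlanRecipe:
    """One plan to build and optimize.

    ``kind`` is ``fast`` (one segment per retained beam, cyclic order
    ``pattern``) or ``multi`` (every valid order of ``orders`` per beam,
    optionally on both leaf banks).
    """

    name: str
    kind: str
    n: int
    arc_deg: float = 360.0
    start_deg: float = 0.0
    pattern: tuple = ("S1", "S2")
    orders: tuple = ("S0", "S1", "S2")
    both_sides: bool = False
    reference: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("fast", "multi"):
            raise ValueError("recipe kind must be 'fast' or 'multi'")


@dataclass
class RunConfig:
    """Complete configuration of a planning experiment."""

    case_preset: str = "quasimodo"
    case_params: dict = field(default_factory=dict)
    grid_shape: tuple = (256, 256, 16)
    voxel_size: float | tuple = 2.0
    objective_preset: str = "quasimodo"
    recipes: list[PlanRecipe] = field(default_factory=list)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    mlc: str = "s4"
    machines: tuple = ("old", "new")
    seed: int = 0
    bev_resolution: float = 1.0

    def __post_init__(self) -> None:
        if not self.recipes:
            raise ValueError("config needs at least one plan recipe")
        refs = [r.name for r in self.recipes if r.reference]
        if len(refs) != 1:
            raise ValueError("exactly one recipe must be marked as reference")
        self.reference_name = refs[0]


def load_config(path) -> RunConfig:
    """Read a :class:`RunConfig` from YAML."""
    raw = yaml.safe_load(pathlib.Path(path).read_text())
    raw["recipes"] = [PlanRecipe(**r) for r in raw.get("recipes", [])]
    if "segmentation" in raw:
        raw["segmentation"] = SegmentationParams(**raw["segmentation"])
    if "optimizer" in raw:
        raw["optimizer"] = OptimizerConfig(**raw["optimizer"])
    return RunConfig(**raw)


@dataclass
class ExperimentResult:
    """Everything the runner produced."""

    summary: pd.DataFrame
    plans: dict
    reports: dict
    times: pd.DataFrame
    errors: dict


def _build_plan(config: RunConfig, recipe: PlanRecipe, case, mlc: MLCModel) -> Plan:
    common = dict(
        arc_deg=recipe.arc_deg, params=config.segmentation, mlc=mlc,
        start_deg=recipe.start_deg, bev_resolution=config.bev_resolution,
        name=recipe.name,
    )
    if recipe.kind == "fast":
        return build_fast_plan(case, recipe.n, pattern=recipe.pattern, **common)
    return build_multisegment_plan(
        case, recipe.n, orders_per_beam=recipe.orders, both_sides=recipe.both_sides, **common
    )


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Build, optimize and score every recipe of a planning experiment.

    Returns a summary table mirroring the usual study layout (one row per
    plan: MU_eff, field #, segment #, normalized COV, S_D/n, delivery
    times).  The run is deterministic for a fixed seed; a failure in one
    recipe is logged and aborts only that recipe.
    """
    rng = np.random.default_rng(config.seed)  # reserved for stochastic variants
    case = make_phantom(
        config.case_preset, config.case_params or None,
        grid_shape=config.grid_shape, voxel_size=config.voxel_size,
    )
    objectives = make_objective_template(case, config.objective_preset)
    mlc = mlc_preset(config.mlc)
    calib = calibrate()
    cache = BeamContextCache(case, calib)

    plans, reports, errors = {}, {}, {}
    covs, stats = {}, {}
    order = []
    for recipe in config.recipes:
        try:
            plan = _build_plan(config, recipe, case, mlc)
            res = optimize_plan(plan, case, objectives, config.optimizer, calib, cache, mlc)
            dose = plan_dose(res.plan, res.influence)
            report = build_quality_report(dose, objectives, case)
            plans[recipe.name] = res.plan
            reports[recipe.name] = report
            covs[recipe.name] = report.cov
            stats[recipe.name] = PlanDeliveryStats.from_plan(res.plan)
            order.append(recipe.name)
        except Exception as exc:  # noqa: BLE001 - per-recipe isolation
            errors[recipe.name] = f"{type(exc).__name__}: {exc}"
    if config.reference_name not in covs:
        raise RuntimeError(
            f"reference recipe {config.reference_name!r} failed: "
            f"{errors.get(config.reference_name)}"
        )
    ref_cov = covs[config.reference_name]
    times = time_report(stats, machines=config.machines, reference=config.reference_name)

    rows = []
    for name in order:
        plan, rep = plans[name], reports[name]
        row = {
            "plan": name,
            "MU_eff": round(plan.total_mu, 1),
            "field_count": plan.n_beams,
            "segment_count": plan.n_segments,
            "norm_COV": round(covs[name] / ref_cov, 2),
            "S_D_per_n": round(rep.s_d_per_n, 2),
        }
        for m in config.machines:
            key = machine_preset(m).name if isinstance(m, str) else m.name
            row[f"T_{key}_min"] = times.loc[name, f"T_{key}_min"]
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("plan")
    summary.attrs["note"] = (
        "synthetic phantom results from the in-house engine; not patient data"
    )
    return ExperimentResult(summary=summary, plans=plans, reports=reports, times=times, errors=errors)


# ---------------------------------------------------------------------------
# plan serialization


def save_plan(plan: Plan, path) -> None:
    """Write a plan as round-trip-safe JSON."""
    doc = {
        "schema": PLAN_SCHEMA,
        "name": plan.name,
        "discard_log": list(plan.discard_log),
        "segments": [
            {
                "gantry_angle_deg": s.beam.gantry_angle_deg,
                "sad": s.beam.sad,
                "isocenter": list(s.beam.isocenter),
                "order": s.order.value,
                "weight_mu": s.weight_mu,
                "aperture": {
                    "x_left": s.aperture.x_left.tolist(),
                    "x_right": s.aperture.x_right.tolist(),
                    "open": s.aperture.open_.tolist(),
                    "v": s.aperture.v.tolist(),
                    "leaf_width": s.aperture.leaf_width,
                    "valid": s.aperture.valid,
                    "note": s.aperture.note,
                },
            }
            for s in plan.segments
        ],
    }
    pathlib.Path(path).write_text(json.dumps(doc))


def load_plan(path) -> Plan:
    """Read a plan written by :func:`save_plan`; exact field round-trip."""
    try:
        doc = json.loads(pathlib.Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"not a valid plan file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != PLAN_SCHEMA:
        raise ValueError(
            f"unsupported plan schema {doc.get('schema') if isinstance(doc, dict) else None!r};"
            f" expected {PLAN_SCHEMA!r}"
        )
    segments = []
    for s in doc["segments"]:
        ap = s["aperture"]
        segments.append(
            Segment(
                beam=Beam(
                    gantry_angle_deg=s["gantry_angle_deg"],
                    isocenter=tuple(s["isocenter"]),
                    sad=s["sad"],
                ),
                aperture=Aperture(
                    x_left=np.array(ap["x_left"], dtype=float),
                    x_right=np.array(ap["x_right"], dtype=float),
                    open_=np.array(ap["open"], dtype=bool),
                    v=np.array(ap["v"], dtype=float),
                    leaf_width=ap["leaf_width"],
                    valid=ap["valid"],
                    note=ap["note"],
                ),
                order=SegmentOrder(s["order"]),
                weight_mu=s["weight_mu"],
            )
        )
    return Plan(segments=segments, name=doc["name"], discard_log=list(doc["discard_log"]))
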