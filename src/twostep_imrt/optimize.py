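"""Weighted quadratic DVH objectives (COV) and plan fine-tuning.

The composite objective value (COV) is the weighted sum of quadratic
penalties on DVH points: a lower objective ``D_v > C`` contributes
``w * max(0, C - D_v)^2`` and an upper objective ``D_v < C`` contributes
``w * max(0, D_v - C)^2``, with doses expressed in percent of the
prescription.  Lower COV means a better plan.

Fine-tuning varies only what a step-and-shoot delivery can vary: segment
weights (projected gradient descent, weights kept non-negative) and
aperture leaf positions (greedy coordinate descent, accepting only
COV-decreasing moves).  The iteration budget follows the study protocol:
two consecutive runs of 40 accepted steps each; at every run boundary
segments below 2 MU are discarded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObjectiveTerm",
    "OptimizerConfig",
    "OptimizationResult",
    "dvh_percentile",
    "objective_value",
    "cov",
    "evaluate_objectives",
    "scale_initial_weights",
    "optimize_weights",
    "fine_tune_apertures",
    "optimize_plan",
]


@dataclass
class ObjectiveTerm:
    """One DVH objective.

    ``dvh_point`` is the volume percentage v of the D_v statistic (v = 100
    is the minimum dose, v = 0 the maximum); ``dose_level`` is the objective
    C in percent of the prescription; ``weight`` the penalty weight.  With
    ``per_voxel`` the quadratic penalty is averaged over the structure's
    violating voxels instead of being scored on the DVH statistic — a
    smoother variant offered as a configuration switch.
    """

    structure: str
    kind: str
    dvh_point: float
    dose_level: float
    weight: float
    per_voxel: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("lower", "upper"):
            raise ValueError("kind must be 'lower' or 'upper'")
        if not 0 <= self.dvh_point <= 100:
            raise ValueError("dvh_point must lie in [0, 100]")
        if self.dose_level <= 0:
            raise ValueError("dose_level must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class OptimizerConfig:
    """Iteration budget and discard/tuning settings.

    Defaults encode the study protocol: 2 runs x 40 steps (80 iterations
    total) and a 2 MU discard threshold applied at run boundaries.
    ``aperture_passes`` greedy leaf-position sweeps are interleaved between
    weight runs; each sweep may move every leaf by up to
    ``aperture_move_limit`` steps of ``leaf_step_mm``.
    """

    runs: int = 2
    steps_per_run: int = 40
    mu_discard_threshold: float = 2.0
    aperture_passes: int = 6
    leaf_step_mm: float = 3.0
    aperture_move_limit: int = 1
    initial_step_mu: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1 or self.steps_per_run < 1:
            raise ValueError("runs and steps_per_run must be >= 1")
        if self.mu_discard_threshold < 0:
            raise ValueError("mu_discard_threshold must be >= 0")


# ---------------------------------------------------------------------------
# DVH statistics and objective evaluation


def _as_array(dose) -> np.ndarray:
    return dose.array if hasattr(dose, "array") else np.asarray(dose)


def _dv(values: np.ndarray, v: float) -> float:
    """D_v on a value sample: largest d with >= v% of voxels receiving >= d."""
    m = values.size
    if m == 0:
        raise ValueError("empty structure mask")
    if v <= 0:
        return float(values.max())
    k = min(max(int(np.ceil(v / 100.0 * m)), 1), m)  # k-th largest
    return float(np.partition(values, m - k)[m - k])


def dvh_percentile(dose, mask=None, v: float = 50.0, prescription: float | None = None) -> float:
    """D_v of a dose distribution over a mask.

    ``dose`` may be a :class:`~.dose.DoseGrid` or array; ``mask`` a boolean
    array on the same grid (None means all values).  With ``prescription``
    the result is converted to percent of that dose; otherwise it is
    returned in the input units.  D_100 is the minimum, D_0 the maximum.
    """
    arr = _as_array(dose)
    values = arr[np.asarray(mask, dtype=bool)] if mask is not None else arr.ravel()
    d = _dv(np.asarray(values, dtype=float), v)
    if prescription is not None:
        d = d / prescription * 100.0
    return d


def _term_prescription(term: ObjectiveTerm, case) -> float:
    """Reference dose for a term: the structure's own prescription if it is
    a PTV, else the case's primary prescription."""
    return case.prescription.get(term.structure, case.reference_dose)


def _term_penalty(values_pct: np.ndarray, term: ObjectiveTerm) -> tuple[float, float]:
    """Return (M_j in %, penalty) for a term on percent-dose values."""
    if term.per_voxel:
        if term.kind == "lower":
            viol = np.maximum(term.dose_level - values_pct, 0.0)
        else:
            viol = np.maximum(values_pct - term.dose_level, 0.0)
        m = _dv(values_pct, term.dvh_point)
        return m, float(term.weight * np.mean(viol**2))
    m = _dv(values_pct, term.dvh_point)
    if term.kind == "lower":
        d = max(term.dose_level - m, 0.0)
    else:
        d = max(m - term.dose_level, 0.0)
    return m, term.weight * d * d


def objective_value(dose, term: ObjectiveTerm, case) -> float:
    """Weighted quadratic penalty of one objective on a dose distribution."""
    arr = _as_array(dose)
    mask = case.structures[term.structure]
    presc = _term_prescription(term, case)
    values = arr[mask].astype(float) / presc * 100.0
    return _term_penalty(values, term)[1]


def _term_list(objectives) -> list[ObjectiveTerm]:
    return list(getattr(objectives, "objectives", objectives))


def cov(dose, objectives, case) -> float:
    """Composite objective value: sum of all weighted objective penalties."""
    return float(sum(objective_value(dose, t, case) for t in _term_list(objectives)))


def evaluate_objectives(dose, objectives, case) -> pd.DataFrame:
    """Tabulate every objective: its level C_j, plan value M_j, penalty.

    The table feeds both the COV (sum of ``penalty``) and the S_D quality
    score (sum of |M_j - C_j| over violated rows).
    """
    arr = _as_array(dose)
    rows = []
    for t in _term_list(objectives):
        presc = _term_prescription(t, case)
        values = arr[case.structures[t.structure]].astype(float) / presc * 100.0
        m, pen = _term_penalty(values, t)
        violated = m < t.dose_level if t.kind == "lower" else m > t.dose_level
        rows.append(
            {
                "structure": t.structure,
                "kind": t.kind,
                "dvh_point": t.dvh_point,
                "C": t.dose_level,
                "M": m,
                "weight": t.weight,
                "violated": bool(violated),
                "penalty": pen,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast evaluator on the influence matrix


class _CovEvaluator:
    """COV and its weight-gradient on body-restricted dose vectors."""

    def __init__(self, case, objectives, influence):
        self.case = case
        self.influence = influence
        pos = np.full(int(np.prod(influence.grid_shape)), -1, dtype=np.int64)
        pos[influence.body_flat_idx] = np.arange(influence.body_flat_idx.size)
        self.terms = []
        for t in _term_list(objectives):
            mask = case.structures[t.structure]
            idx = pos[np.flatnonzero(mask.ravel())]
            if np.any(idx < 0):
                raise ValueError(f"structure {t.structure!r} leaves the body")
            presc = _term_prescription(t, case)
            self.terms.append((t, idx, presc))

    def dose(self, w: np.ndarray) -> np.ndarray:
        return self.influence.dose_vector(w)

    def cov(self, dose_vec: np.ndarray) -> float:
        total = 0.0
        for t, idx, presc in self.terms:
            values = dose_vec[idx] * (100.0 / presc)
            total += _term_penalty(values, t)[1]
        return float(total)

    def cov_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        dose_vec = self.dose(w)
        unit = self.influence.unit
        total = 0.0
        grad = np.zeros(w.size)
        for t, idx, presc in self.terms:
            scale = 100.0 / presc
            values = dose_vec[idx] * scale
            if t.per_voxel:
                if t.kind == "lower":
                    viol = np.maximum(t.dose_level - values, 0.0)
                    sign = -1.0
                else:
                    viol = np.maximum(values - t.dose_level, 0.0)
                    sign = 1.0
                total += t.weight * float(np.mean(viol**2))
                if viol.any():
                    coeff = 2.0 * t.weight * sign * scale / idx.size
                    grad += coeff * (unit[:, idx] @ viol)
                continue
            m = values.size
            v = t.dvh_point
            if v <= 0:
                j = int(np.argmax(values))
            else:
                k = min(max(int(np.ceil(v / 100.0 * m)), 1), m)
                j = int(np.argpartition(values, m - k)[m - k])
            dval = values[j]
            if t.kind == "lower":
                deficit = max(t.dose_level - dval, 0.0)
                total += t.weight * deficit * deficit
                if deficit > 0:
                    grad += (-2.0 * t.weight * deficit * scale) * unit[:, idx[j]]
            else:
                excess = max(dval - t.dose_level, 0.0)
                total += t.weight * excess * excess
                if excess > 0:
                    grad += (2.0 * t.weight * excess * scale) * unit[:, idx[j]]
        return float(total), grad

    def descent_direction(self, w: np.ndarray) -> np.ndarray:
        """Smoothed descent direction for the weight search.

        The exact gradient of a DVH-point objective lives on a single voxel
        (the percentile voxel), which makes plain gradient descent crawl.
        The search direction therefore comes from a per-voxel surrogate of
        each violated term — every structure voxel on the violating side of
        the objective level contributes — while step acceptance is always
        evaluated on the true COV, so accepted iterations never increase it.
        """
        dose_vec = self.dose(w)
        unit = self.influence.unit
        grad = np.zeros(w.size)
        for t, idx, presc in self.terms:
            scale = 100.0 / presc
            values = dose_vec[idx] * scale
            m = _dv(values, t.dvh_point)
            if t.kind == "lower":
                if not t.per_voxel and m >= t.dose_level:
                    continue
                viol = np.maximum(t.dose_level - values, 0.0)
                sign = -1.0
            else:
                if not t.per_voxel and m <= t.dose_level:
                    continue
                viol = np.maximum(values - t.dose_level, 0.0)
                sign = 1.0
            if viol.any():
                coeff = 2.0 * t.weight * sign * scale / idx.size
                grad += coeff * (unit[:, idx] @ viol)
        return grad


# ---------------------------------------------------------------------------
# optimization


@dataclass
class OptimizationResult:
    """Outcome of a fine-tuning stage."""

    plan: object
    influence: object
    cov_trace: list[float]
    discarded: list[str] = field(default_factory=list)

    @property
    def final_cov(self) -> float:
        return self.cov_trace[-1]


def scale_initial_weights(plan, influence, case, ptv_name: str = "ptv") -> None:
    """Set uniform segment weights such that the mean PTV dose equals the
    prescription — the neutral starting point before weight optimization."""
    pos = np.full(int(np.prod(influence.grid_shape)), -1, dtype=np.int64)
    pos[influence.body_flat_idx] = np.arange(influence.body_flat_idx.size)
    idx = pos[np.flatnonzero(case.structures[ptv_name].ravel())]
    total_unit = influence.unit.sum(axis=0)
    mean_ptv = float(total_unit[idx].mean())
    if mean_ptv <= 0:
        raise ValueError("plan deposits no dose in the PTV")
    w0 = case.prescription[ptv_name] / mean_ptv
    for s in plan.segments:
        s.weight_mu = w0


def _weight_run(
    evaluator: _CovEvaluator, w: np.ndarray, steps: int, step0: float
) -> tuple[np.ndarray, list[float], float]:
    """One projected-gradient run; accepted iterations never increase COV."""
    trace = []
    step = step0
    for _ in range(steps):
        c0, exact_grad = evaluator.cov_and_grad(w)
        trace.append(c0)
        improved = False
        for grad in (evaluator.descent_direction(w), exact_grad):
            gnorm = float(np.linalg.norm(grad))
            if gnorm == 0.0:
                continue
            direction = grad / gnorm
            alpha = step
            for _ in range(30):
                w_new = np.maximum(w - alpha * direction, 0.0)
                c_new = evaluator.cov(evaluator.dose(w_new))
                if c_new < c0 - 1e-12:
                    w, step, improved = w_new, alpha * 2.0, True
                    break
                alpha *= 0.5
            if improved:
                break
        if not improved:
            break
    trace.append(evaluator.cov(evaluator.dose(w)))
    return w, trace, step


def _discard(plan, influence, w: np.ndarray, threshold: float):
    """Drop segments below the MU threshold (run-boundary discard rule)."""
    keep = w >= threshold
    log = [
        f"segment {i} ({plan.segments[i].order.value} at "
        f"{plan.segments[i].beam.gantry_angle_deg:.1f} deg) discarded: "
        f"{w[i]:.2f} MU below {threshold} MU"
        for i in np.flatnonzero(~keep)
    ]
    if not keep.any():
        from .segmentation import EmptyPlanError

        raise EmptyPlanError("all segments fell below the MU threshold")
    if keep.all():
        return plan, influence, w, log
    plan.segments = [s for s, k in zip(plan.segments, keep) if k]
    return plan, influence.dropped(keep), w[keep], log


def optimize_weights(plan, influence, objectives, case, config: OptimizerConfig = OptimizerConfig()):
    """Projected-gradient minimization of COV over segment weights.

    Runs ``config.runs`` consecutive runs of ``config.steps_per_run`` steps;
    at each run boundary (including after the final run) segments with
    weight below the discard threshold are removed.  Returns an
    :class:`OptimizationResult` with the per-iteration COV trace and the
    discard log; the plan's segment weights are updated in place.
    """
    evaluator = _CovEvaluator(case, objectives, influence)
    w = np.array([s.weight_mu for s in plan.segments], dtype=float)
    trace: list[float] = []
    discarded: list[str] = []
    step = max(config.initial_step_mu, 0.1 * float(np.mean(w)) if w.size else 0.0)
    for _ in range(config.runs):
        w, t, step = _weight_run(evaluator, w, config.steps_per_run, step)
        trace.extend(t)
        plan, influence, w, log = _discard(plan, influence, w, config.mu_discard_threshold)
        discarded.extend(log)
        evaluator = _CovEvaluator(case, objectives, influence)
    for s, wi in zip(plan.segments, w):
        s.weight_mu = float(wi)
    return OptimizationResult(plan=plan, influence=influence, cov_trace=trace, discarded=discarded)


def fine_tune_apertures(
    plan,
    case,
    influence,
    objectives,
    config: OptimizerConfig = OptimizerConfig(),
    calib=None,
    cache=None,
    mlc=None,
):
    """Greedy coordinate descent over leaf positions.

    Sweeps segments in plan order, leaf pairs top to bottom, left bank
    before right, trying moves of up to ``aperture_move_limit`` steps of
    ``leaf_step_mm`` in either direction and accepting only COV-decreasing
    moves.  Deliverability (one interval per row, left edge strictly below
    the right) and MLC travel limits are preserved.  Deterministic for a
    fixed sweep order; a no-op when no move improves the plan.
    """
    from .dose import BeamContextCache, calibrate, segment_unit_dose

    calib = calib or calibrate()
    cache = cache or BeamContextCache(case, calib)
    travel = mlc.max_field_extent if mlc is not None else np.inf
    evaluator = _CovEvaluator(case, objectives, influence)
    w = np.array([s.weight_mu for s in plan.segments], dtype=float)
    dose_vec = evaluator.dose(w)
    cov_cur = evaluator.cov(dose_vec)
    trace = [cov_cur]
    step = config.leaf_step_mm
    deltas = [
        k * step * sign
        for k in range(1, config.aperture_move_limit + 1)
        for sign in (-1.0, 1.0)
    ]
    for _ in range(config.aperture_passes):
        improved_any = False
        for i, seg in enumerate(plan.segments):
            ap = seg.aperture
            # trial-open closed rows adjacent to open ones (inheriting the
            # neighbour's interval): lets the optimizer compensate penumbra
            # beyond the shadow edge along the stacking axis
            open_idx = np.flatnonzero(ap.open_)
            for r in open_idx:
                for rn in (r - 1, r + 1):
                    if rn < 0 or rn >= ap.open_.size or ap.open_[rn]:
                        continue
                    trial = ap.copy()
                    trial.open_[rn] = True
                    trial.x_left[rn] = ap.x_left[r]
                    trial.x_right[rn] = ap.x_right[r]
                    seg_trial = replace_aperture(seg, trial)
                    new_unit = segment_unit_dose(case, seg_trial, calib, cache)
                    cand = dose_vec + w[i] * (
                        new_unit.astype(np.float64) - influence.unit[i].astype(np.float64)
                    )
                    c_new = evaluator.cov(cand)
                    if c_new < cov_cur - 1e-12:
                        seg.aperture = trial
                        ap = trial
                        influence.unit[i] = new_unit
                        dose_vec, cov_cur = cand, c_new
                        trace.append(cov_cur)
                        improved_any = True
            for r in np.flatnonzero(ap.open_):
                for bank in ("left", "right"):
                    for delta in deltas:
                        if bank == "left":
                            new_edge = ap.x_left[r] + delta
                            if new_edge < -travel or new_edge >= ap.x_right[r] - 0.5:
                                continue
                        else:
                            new_edge = ap.x_right[r] + delta
                            if new_edge > travel or new_edge <= ap.x_left[r] + 0.5:
                                continue
                        trial = ap.copy()
                        if bank == "left":
                            trial.x_left[r] = new_edge
                        else:
                            trial.x_right[r] = new_edge
                        seg_trial = replace_aperture(seg, trial)
                        new_unit = segment_unit_dose(case, seg_trial, calib, cache)
                        cand = dose_vec + w[i] * (
                            new_unit.astype(np.float64) - influence.unit[i].astype(np.float64)
                        )
                        c_new = evaluator.cov(cand)
                        if c_new < cov_cur - 1e-12:
                            seg.aperture = trial
                            influence.unit[i] = new_unit
                            dose_vec, cov_cur = cand, c_new
                            trace.append(cov_cur)
                            improved_any = True
                            break
        if not improved_any:
            break
    return OptimizationResult(plan=plan, influence=influence, cov_trace=trace)


def replace_aperture(segment, aperture):
    """Segment with the same beam/order/weight but a different aperture."""
    from .segmentation import Segment

    return Segment(
        beam=segment.beam, aperture=aperture, order=segment.order,
        weight_mu=segment.weight_mu,
    )


def optimize_plan(
    plan,
    case,
    objectives,
    config: OptimizerConfig = OptimizerConfig(),
    calib=None,
    cache=None,
    mlc=None,
):
    """Full fine-tuning pipeline on a freshly built plan.

    Traces the influence matrix, scales initial weights so the mean PTV
    dose matches the prescription, then alternates weight runs with
    aperture sweeps: weights (run 1) -> discard -> aperture passes ->
    weights (run 2) -> discard.  Varies only segment weights and apertures,
    never the beam set.
    """
    from .dose import BeamContextCache, calibrate, compute_influence

    calib = calib or calibrate()
    cache = cache or BeamContextCache(case, calib)
    influence = compute_influence(case, plan, calib, cache)
    scale_initial_weights(plan, influence, case)

    evaluator = _CovEvaluator(case, objectives, influence)
    w = np.array([s.weight_mu for s in plan.segments], dtype=float)
    trace: list[float] = []
    discarded: list[str] = []
    step = max(config.initial_step_mu, 0.1 * float(np.mean(w)) if w.size else 0.0)
    one_pass = dataclasses.replace(config, aperture_passes=1)
    for run in range(config.runs):
        # interleave aperture sweeps with the weight steps of this run:
        # the run's weight budget is split into `aperture_passes + 1`
        # blocks with one greedy leaf sweep after each block but the last
        blocks = max(config.aperture_passes, 0) + 1
        edges = np.linspace(0, config.steps_per_run, blocks + 1).round().astype(int)
        for b in range(blocks):
            n_steps = int(edges[b + 1] - edges[b])
            if n_steps > 0:
                w, t, step = _weight_run(evaluator, w, n_steps, step)
                trace.extend(t)
            if b < blocks - 1:
                for s, wi in zip(plan.segments, w):
                    s.weight_mu = float(wi)
                res = fine_tune_apertures(
                    plan, case, influence, objectives, one_pass, calib, cache, mlc
                )
                influence = res.influence
                trace.extend(res.cov_trace[1:])
                evaluator = _CovEvaluator(case, objectives, influence)
        plan, influence, w, log = _discard(plan, influence, w, config.mu_discard_threshold)
        discarded.extend(log)
        for s, wi in zip(plan.segments, w):
            s.weight_mu = float(wi)
        evaluator = _CovEvaluator(case, objectives, influence)
    return OptimizationResult(plan=plan, influence=influence, cov_trace=trace, discarded=discarded)
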