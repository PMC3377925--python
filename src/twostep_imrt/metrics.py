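"""Plan-quality reporting: normalized COV, the S_D score and DVH curves.

Two complementary scores are used.  The normalized COV is the plan's
composite objective value divided by that of a designated reference plan
(the reference normalizes to 1.00); only differences of +25%/-20% are
considered relevant.  The quality score S_D sums, over *violated*
objectives only, the absolute difference between the plan value M_j and the
objective C_j (in percent of prescription):

    S_D = sum_j |M_j - C_j|   if objective j is violated, else 0.

Satisfied or over-achieved objectives contribute nothing, so S_D = 0 for a
plan that fulfills every objective and S_D is independent of the objective
weights.  S_D/n divides by the number of objectives considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optimize import dvh_percentile, evaluate_objectives

__all__ = [
    "QualityReport",
    "quality_score_sd",
    "normalized_cov",
    "dvh_curve",
    "build_quality_report",
]

#: COV ratio bands outside which a difference counts as relevant.
RELEVANT_WORSE = 1.25
RELEVANT_BETTER = 0.80


def quality_score_sd(objective_table: pd.DataFrame) -> tuple[float, float]:
    """S_D and S_D/n from an objective table.

    The table needs columns ``kind`` (lower/upper), ``C`` (objective) and
    ``M`` (plan value), both in percent of prescription; a ``violated``
    column is recomputed if absent.
    """
    if len(objective_table) == 0:
        raise ValueError("objective table is empty")
    t = objective_table
    lower = t["kind"] == "lower"
    shortfall = np.where(lower, t["C"] - t["M"], t["M"] - t["C"]).astype(float)
    contrib = np.maximum(shortfall, 0.0)
    s_d = float(contrib.sum())
    return s_d, s_d / len(t)


def normalized_cov(plan_cov: float, reference_cov: float) -> float:
    """COV normalized to the reference plan (reference itself gives 1.00)."""
    if reference_cov <= 0:
        raise ValueError("reference COV must be positive")
    return plan_cov / reference_cov


def relevance_flag(ratio: float) -> str:
    """Classify a normalized COV against the +25%/-20% relevance band."""
    if ratio > RELEVANT_WORSE:
        return "relevant worsening"
    if ratio < RELEVANT_BETTER:
        return "relevant improvement"
    return "comparable"


def dvh_curve(dose, mask, bin_width: float = 0.5, prescription: float | None = None) -> pd.DataFrame:
    """Cumulative DVH: percent volume receiving at least each dose level.

    Returns a DataFrame with columns ``dose`` (input units, or percent of
    ``prescription`` when given) and ``volume_pct``, monotone non-increasing
    and starting at 100%.
    """
    arr = dose.array if hasattr(dose, "array") else np.asarray(dose)
    values = arr[np.asarray(mask, dtype=bool)].astype(float)
    if values.size == 0:
        raise ValueError("empty structure mask")
    if prescription is not None:
        values = values / prescription * 100.0
    edges = np.arange(0.0, values.max() + 2 * bin_width, bin_width)
    volume = [(values >= d).mean() * 100.0 for d in edges]
    return pd.DataFrame({"dose": edges, "volume_pct": volume})


@dataclass
class QualityReport:
    """Quality summary of one plan against its objective set."""

    cov: float
    normalized_cov: float | None
    s_d: float
    s_d_per_n: float
    objective_table: pd.DataFrame

    @property
    def relevance(self) -> str | None:
        return None if self.normalized_cov is None else relevance_flag(self.normalized_cov)

    def __str__(self) -> str:  # human-readable table
        head = (
            f"COV {self.cov:.4g}"
            + (f"  norm. COV {self.normalized_cov:.2f} ({self.relevance})" if self.normalized_cov else "")
            + f"  S_D {self.s_d:.2f}  S_D/n {self.s_d_per_n:.2f}\n"
        )
        return head + self.objective_table.to_string(index=False)


def build_quality_report(dose, objectives, case, reference_cov: float | None = None) -> QualityReport:
    """Evaluate all objectives of a plan and assemble a quality report."""
    table = evaluate_objectives(dose, objectives, case)
    plan_cov = float(table["penalty"].sum())
    s_d, s_d_n = quality_score_sd(table)
    ncov = None if reference_cov is None else normalized_cov(plan_cov, reference_cov)
    return QualityReport(
        cov=plan_cov, normalized_cov=ncov, s_d=s_d, s_d_per_n=s_d_n, objective_table=table
    )
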