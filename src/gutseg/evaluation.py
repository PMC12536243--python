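"""Agreement metrics and grouped performance summaries.

Model-derived areas are compared against ground-truth ("manual") areas via
the signed relative deviation RD = (A_model - A_manual) / A_manual x 100%,
folded to |RD| for the four agreement categories (very good < 5%, good
5-10%, fair 10-20%, poor > 20%; half-open intervals, boundaries assigned
upward). Spatial co-location is measured by Intersection over Union on the
rasters at each step's working resolution, interpreted with the usual
bands (> 0.50 acceptable, > 0.75 good, > 0.90 near-perfect, strict
inequalities). Linearity between model and manual areas is the Pearson
product-moment coefficient, labelled >= 0.90 very strong, 0.70-0.90 strong,
0.50-0.70 moderate, 0.30-0.50 weak, below that very weak.

Summaries aggregate one record per (sample, step) into per-age-group rows
plus a pooled "All" row (pooled over records, not averaged over groups),
with per-category counts and a modified Bland-Altman export (per-sample RD
against age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

AGREEMENT_CATEGORIES = ("very_good", "good", "fair", "poor")

#: Table-1-shaped metric columns, per (step, design, age group)
SUMMARY_METRIC_COLUMNS = (
    "rd_mean",
    "rd_sd",
    "pcc",
    "pcc_interpretation",
    "iou_mean",
    "iou_sd",
)


def relative_deviation(a_model: float, a_manual: float) -> float:
    """Signed percent deviation of the model area from the manual area."""
    if a_manual <= 0:
        raise ValueError("relative deviation is undefined for A_manual <= 0")
    return (a_model - a_manual) / a_manual * 100.0


def agreement_category(rd: float) -> str:
    """Four-level agreement from |RD|: [0,5) very_good, [5,10) good,
    [10,20) fair, [20,inf) poor."""
    a = abs(rd)
    if a < 5.0:
        return "very_good"
    if a < 10.0:
        return "good"
    if a < 20.0:
        return "fair"
    return "poor"


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two aligned boolean rasters.

    An empty union is an error (the metric is undefined), not a value.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are not aligned")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU is undefined when both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


def interpret_iou(value: float) -> str:
    """Strict-threshold bands: >0.50 acceptable, >0.75 good, >0.90 near-perfect."""
    if not (0.0 <= value <= 1.0):
        raise ValueError("IoU must lie in [0, 1]")
    if value > 0.90:
        return "near_perfect"
    if value > 0.75:
        return "good"
    if value > 0.50:
        return "acceptable"
    return "below_acceptable"


def interpret_pcc(r: float) -> str:
    a = abs(r)
    if a >= 0.90:
        return "very_strong"
    if a >= 0.70:
        return "strong"
    if a >= 0.50:
        return "moderate"
    if a >= 0.30:
        return "weak"
    return "very_weak"


def pearson(xs, ys) -> tuple[float, str]:
    """Pearson product-moment coefficient with its interpretation label."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.size != ys.size or xs.size < 3:
        raise ValueError("Pearson correlation requires n >= 3 paired values")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("Pearson correlation is undefined for zero variance")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, interpret_pcc(r)


@dataclass
class EvalRecord:
    """One evaluated (sample, step) pair."""

    sample_id: str
    age_group: int
    step: int
    model_design: str
    a_model_um2: float
    a_manual_um2: float
    iou: float
    rd: float = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.rd = relative_deviation(self.a_model_um2, self.a_manual_um2)
        self.category = agreement_category(self.rd)
        if not (0.0 <= self.iou <= 1.0):
            raise ValueError("IoU must lie in [0, 1]")


def records_to_dataframe(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "age_group": r.age_group,
                "step": r.step,
                "model_design": r.model_design,
                "a_model_um2": r.a_model_um2,
                "a_manual_um2": r.a_manual_um2,
                "rd": r.rd,
                "category": r.category,
                "iou": r.iou,
            }
            for r in records
        ]
    )


@dataclass
class SummaryTable:
    """Grouped metrics, category counts, and the Bland-Altman scatter."""

    metrics: pd.DataFrame
    category_counts: pd.DataFrame
    bland_altman: pd.DataFrame


def _group_stats(df: pd.DataFrame, step, design, age_label) -> dict:
    rd = df["rd"].to_numpy()
    io = df["iou"].to_numpy()
    row = {
        "step": step,
        "model_design": design,
        "age_group": age_label,
        "n": len(df),
        "rd_mean": float(np.mean(rd)),
        "rd_sd": float(np.std(rd, ddof=1)) if len(rd) > 1 else float("nan"),
        "iou_mean": float(np.mean(io)),
        "iou_sd": float(np.std(io, ddof=1)) if len(io) > 1 else float("nan"),
    }
    try:
        r, label = pearson(df["a_manual_um2"], df["a_model_um2"])
        row["pcc"] = r
        row["pcc_interpretation"] = label
    except ValueError:
        row["pcc"] = float("nan")
        row["pcc_interpretation"] = "not_computable"
    return row


def summarize(records: list[EvalRecord]) -> SummaryTable:
    """Aggregate records per (step, design, age group) plus pooled "All" rows.

    "All" rows pool the records, so their RD mean is the pooled (not
    group-averaged) mean. Groups with fewer than three samples report the
    Pearson coefficient as not computable but emit all other statistics.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_dataframe(records)
    metric_rows = []
    count_rows = []
    for (step, design), sub in df.groupby(["step", "model_design"], sort=True):
        groups = [("All", sub)] + [
            (age, g) for age, g in sub.groupby("age_group", sort=True)
        ]
        for age_label, g in groups:
            metric_rows.append(_group_stats(g, step, design, age_label))
            counts = {
                "step": step,
                "model_design": design,
                "age_group": age_label,
                "n": len(g),
            }
            vc = g["category"].value_counts()
            for cat in AGREEMENT_CATEGORIES:
                counts[cat] = int(vc.get(cat, 0))
            count_rows.append(counts)
    metrics = pd.DataFrame(metric_rows)[
        ["step", "model_design", "age_group", "n", *SUMMARY_METRIC_COLUMNS]
    ]
    counts = pd.DataFrame(count_rows)
    bland = df[["sample_id", "age_group", "step", "model_design", "rd"]].copy()
    return SummaryTable(metrics=metrics, category_counts=counts, bland_altman=bland)


def plot_bland_altman(summary: SummaryTable, path=None):
    """Modified Bland-Altman: per-sample RD against age, one panel per step."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.bland_altman
    steps = sorted(df["step"].unique())
    fig, axes = plt.subplots(1, len(steps), figsize=(4 * len(steps), 3.2), squeeze=False)
    for ax, step in zip(axes[0], steps):
        sub = df[df["step"] == step]
        for design, g in sub.groupby("model_design"):
            jitter = (hash(design) % 7 - 3) * 0.15
            ax.scatter(g["age_group"] + jitter, g["rd"], s=12, label=design, alpha=0.7)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_title(f"Step {step}")
        ax.set_xlabel("age group (days)")
        ax.set_ylabel("relative deviation (%)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
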