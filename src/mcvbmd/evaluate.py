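"""Segmentation-quality metrics and manual-vs-automatic agreement statistics.

Overlap metrics operate on binary masks: Dice similarity coefficient
DSC = 2|X.Y|/(|X|+|Y|), Jaccard/IOU = |X.Y|/|X u Y|, pixel accuracy
(TP+TN)/N and AUROC (probability that a foreground voxel scores above a
background one).  The two-empty-masks convention is 1.0 for DSC and IOU;
IOU relates to DSC by the exact identity IOU = DSC/(2-DSC).

Method agreement between paired manual and automatic measurements is
summarised with Pearson and Spearman correlations (two-sided p-values),
a two-way random-effects absolute-agreement single-measurement ICC
(ICC(2,1) by default) and Bland-Altman mean difference with +/-1.96 SD
limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .core import BinaryMask
from .errors import DegenerateDataError, ShapeError

__all__ = [
    "SegmentationMetrics", "AgreementReport", "dsc", "iou", "pixel_accuracy",
    "auroc", "segmentation_metrics", "summarize_runs", "agreement_stats",
    "bland_altman_plot",
]


def _binary(x) -> np.ndarray:
    if isinstance(x, BinaryMask):
        return x.values.astype(bool)
    return np.asarray(x) > 0.5


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xb, yb = _binary(x), _binary(y)
    if xb.shape != yb.shape:
        raise ShapeError(f"shape mismatch {xb.shape} vs {yb.shape}")
    return xb, yb


@dataclass
class SegmentationMetrics:
    dsc: float
    iou: float
    pixel_accuracy: float
    auroc: float | None = None
    case_id: str = ""


@dataclass
class AgreementReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    icc: float
    bland_altman_mean_diff: float
    bland_altman_loa_low: float
    bland_altman_loa_high: float
    n_pairs: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def dsc(x, y) -> float:
    """Dice similarity coefficient; both masks empty -> 1.0."""
    xb, yb = _pair(x, y)
    denom = int(xb.sum()) + int(yb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(xb, yb).sum()) / denom


def iou(x, y) -> float:
    """Jaccard index |X n Y| / |X u Y|; both masks empty -> 1.0."""
    xb, yb = _pair(x, y)
    union = int(np.logical_or(xb, yb).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(xb, yb).sum()) / union


def pixel_accuracy(x, y) -> float:
    """(TP + TN) / N."""
    xb, yb = _pair(x, y)
    return float((xb == yb).mean())


def auroc(prob_grid, y) -> float:
    """Area under the ROC curve of voxel scores against the reference mask.

    Equals the Mann-Whitney pair statistic
    P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(prob_grid, dtype=float).ravel()
    yb = _binary(y).ravel()
    if scores.shape != yb.shape:
        raise ShapeError("probability grid and mask shapes differ")
    if yb.all() or not yb.any():
        raise DegenerateDataError("AUROC undefined for a single-class reference")
    return float(roc_auc_score(yb, scores))


def segmentation_metrics(pred, ref, prob_grid=None,
                         case_id: str = "") -> SegmentationMetrics:
    return SegmentationMetrics(
        dsc=dsc(pred, ref), iou=iou(pred, ref),
        pixel_accuracy=pixel_accuracy(pred, ref),
        auroc=auroc(prob_grid, ref) if prob_grid is not None else None,
        case_id=case_id)


def summarize_runs(per_run_metrics: dict[str, list[dict[str, float]]]) -> pd.DataFrame:
    """Mean (SD over repeats) per configuration, one row per configuration.

    ``per_run_metrics`` maps configuration name to a list of per-repeat
    metric dicts (each already averaged over cases).  A single repeat
    reports the mean only (SD left as NaN), matching how one-off runs are
    usually tabulated.
    """
    rows = []
    for name, runs in per_run_metrics.items():
        if not runs:
            continue
        frame = pd.DataFrame(runs)
        row: dict[str, float | str] = {"configuration": name, "n_runs": len(runs)}
        for col in frame.columns:
            row[f"{col}_mean"] = float(frame[col].mean())
            row[f"{col}_sd"] = float(frame[col].std(ddof=1)) if len(runs) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def agreement_stats(manual, automatic, icc_form: str = "ICC2") -> AgreementReport:
    """Paired agreement between manual and automatic measurements.

    Degenerate inputs (no variance in either series) raise rather than
    returning NaN correlations.
    """
    manual = np.asarray(manual, dtype=float)
    automatic = np.asarray(automatic, dtype=float)
    if manual.shape != automatic.shape or manual.ndim != 1:
        raise ShapeError("manual and automatic must be equal-length 1D series")
    n = manual.size
    if n < 3:
        raise DegenerateDataError("need at least 3 pairs")
    diffs = automatic - manual
    if np.allclose(manual, manual[0]) or np.allclose(automatic, automatic[0]):
        if np.ptp(diffs) == 0 and np.allclose(manual, automatic):
            # perfect, constant agreement: correlations undefined, ICC 1
            return AgreementReport(1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, n)
        raise DegenerateDataError("zero-variance measurement series")
    pearson = sps.pearsonr(manual, automatic)
    spearman = sps.spearmanr(manual, automatic)
    icc_value = _icc(manual, automatic, icc_form)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return AgreementReport(
        pearson_r=float(pearson.statistic), pearson_p=float(pearson.pvalue),
        spearman_rho=float(spearman.statistic), spearman_p=float(spearman.pvalue),
        icc=icc_value,
        bland_altman_mean_diff=mean_diff,
        bland_altman_loa_low=mean_diff - 1.96 * sd_diff,
        bland_altman_loa_high=mean_diff + 1.96 * sd_diff,
        n_pairs=n,
    )


# accepted aliases per ICC variant: Shrout-Fleiss and McGraw-Wong labels
_ICC_ALIASES = {
    "ICC1": ("ICC1", "ICC(1,1)"),
    "ICC2": ("ICC2", "ICC(A,1)"),  # two-way random, absolute agreement, single
    "ICC3": ("ICC3", "ICC(C,1)"),  # two-way mixed, consistency, single
}


def _icc(manual: np.ndarray, automatic: np.ndarray, form: str) -> float:
    import pingouin as pg

    n = manual.size
    frame = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": ["manual"] * n + ["automatic"] * n,
        "rating": np.concatenate([manual, automatic]),
    })
    table = pg.intraclass_corr(data=frame, targets="target", raters="rater",
                               ratings="rating").set_index("Type")
    for alias in _ICC_ALIASES.get(form, (form,)):
        if alias in table.index:
            return float(table.loc[alias, "ICC"])
    raise KeyError(f"ICC form {form!r} not reported by pingouin")


def bland_altman_plot(manual, automatic, path) -> None:
    """Save a Bland-Altman plot (difference vs mean with limits of agreement)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manual = np.asarray(manual, dtype=float)
    automatic = np.asarray(automatic, dtype=float)
    means = (manual + automatic) / 2.0
    diffs = automatic - manual
    md, sd = diffs.mean(), diffs.std(ddof=1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12)
    for yv, style in ((md, "-"), (md - 1.96 * sd, "--"), (md + 1.96 * sd, "--")):
        ax.axhline(yv, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("automatic - manual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
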