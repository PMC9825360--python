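"""Per-slide segmentation metrics and multi-slide summaries.

All metrics are computed per slide from patch-level confusion counts
(positive = lesion) and then aggregated across slides — counts are never
pooled, so each slide contributes equally regardless of its patch count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "metrics_from_counts",
    "summarize",
    "moving_average",
]

METRIC_NAMES = ("ppv", "tpr", "tnr", "npv", "f1", "iou")


@dataclass
class MetricsReport:
    """Confusion counts and derived fractions for one mask vs ground truth.

    Undefined ratios (zero denominator) are None.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    ppv: float | None = None
    tpr: float | None = None
    tnr: float | None = None
    npv: float | None = None
    f1: float | None = None
    iou: float | None = None
    slide_id: str = ""
    method: str = ""
    condition: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    """Standard 2x2 counts (tp, fp, fn, tn) with positive = lesion."""
    p = np.asarray(pred).astype(np.int8).ravel()
    t = np.asarray(truth).astype(np.int8).ravel()
    if p.shape != t.shape:
        raise AlignmentError("prediction and truth differ in length")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ConfigError("labels must be binary")
    tp = int(((p == 1) & (t == 1)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    fn = int(((p == 0) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    return tp, fp, fn, tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_counts(
    tp: int, fp: int, fn: int, tn: int,
    slide_id: str = "", method: str = "", condition: str = "",
) -> MetricsReport:
    """Derive PPV/TPR/TNR/NPV/F1/IoU from confusion counts.

    F1 is the harmonic mean of PPV and TPR; IoU = tp/(tp+fp+fn).  Ratios
    with a zero denominator are reported as None.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ConfigError("counts must be non-negative")
    ppv = _ratio(tp, tp + fp)
    tpr = _ratio(tp, tp + fn)
    f1 = None
    if ppv is not None and tpr is not None and (ppv + tpr) > 0:
        f1 = 2 * ppv * tpr / (ppv + tpr)
    elif ppv is not None and tpr is not None:
        f1 = 0.0
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        ppv=ppv, tpr=tpr,
        tnr=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
        f1=f1,
        iou=_ratio(tp, tp + fp + fn),
        slide_id=slide_id, method=method, condition=condition,
    )


def summarize(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +/- sample std of each metric, grouped by (method, condition).

    A single-slide group reports std as missing (sample std is undefined),
    not 0.  Rows are sorted for deterministic output.
    """
    if not reports:
        raise ConfigError("no reports to summarize")
    df = pd.DataFrame([r.to_dict() for r in reports])
    grouped = df.groupby(["method", "condition"], sort=True)[list(METRIC_NAMES)]
    out = grouped.agg(["mean", "std"])  # pandas std: ddof=1 -> NaN for n=1
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def moving_average(values, window: int = 15) -> np.ndarray:
    """Centered-start moving average with window k (partial head windows).

    Used to plot refinement quality against coarse-annotation quality after
    sorting slides by their coarse F1.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()
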