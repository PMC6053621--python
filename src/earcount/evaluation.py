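"""Segmentation quality indicators and the count-regression report.

Six indicators compare a predicted binary ear mask M against a reference
mask N: ``Qseg`` (agreement over both classes: sum over the two class
values of |M_w ∩ N_w| divided by the sum of |M_w ∪ N_w|), ``Sr`` (ear-class
completeness |M_ear ∩ N_ear| / |N_ear|), SSIM, Precision, Recall and the
F-measure.  A single-class Jaccard on the ear class is also exposed for
comparison with the both-class ``Qseg`` reading.  Counting performance is
summarized by the OLS regression of algorithm counts on manual counts
(slope, intercept, R^2, residual SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage.metrics import structural_similarity

__all__ = [
    "EvalReport",
    "CountRegressionReport",
    "confusion",
    "pixel_metrics",
    "jaccard_foreground",
    "ssim",
    "count_regression",
    "evaluate_batch",
]

_INDICATORS = ("Qseg", "Sr", "SSIM", "Precision", "Recall", "F")


@dataclass
class EvalReport:
    per_image: pd.DataFrame  # one row per mask pair, indicator columns
    summary: pd.DataFrame    # rows 'mean' and 'sd' over images


@dataclass
class CountRegressionReport:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int


def _as_bool(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    return m.astype(bool) if m.dtype != bool else m


def confusion(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    """Pixelwise (TP, TN, FP, FN) of a predicted vs reference ear mask."""
    pred = _as_bool(pred, "pred")
    ref = _as_bool(ref, "ref")
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    tp = int(np.sum(pred & ref))
    tn = int(np.sum(~pred & ~ref))
    fp = int(np.sum(pred & ~ref))
    fn = int(np.sum(~pred & ref))
    return tp, tn, fp, fn


def pixel_metrics(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float, float, float, float]:
    """(Qseg, Sr, Precision, Recall, F) for one mask pair.

    The reference must contain at least one ear pixel (Sr denominator);
    Precision is defined as 0 for an empty prediction.
    """
    tp, tn, fp, fn = confusion(pred, ref)
    total = tp + tn + fp + fn
    n_ear = tp + fn
    if n_ear == 0:
        raise ValueError("reference mask has no ear pixels; Sr is undefined")
    agree = tp + tn
    qseg = agree / (2 * total - agree)  # = sum_w |inter| / sum_w |union|
    sr = tp / n_ear
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return qseg, sr, precision, recall, f


def jaccard_foreground(pred: np.ndarray, ref: np.ndarray) -> float:
    """Single-class (ear) Jaccard index, for comparison with Qseg."""
    tp, _, fp, fn = confusion(pred, ref)
    union = tp + fp + fn
    return tp / union if union > 0 else 1.0


def ssim(pred: np.ndarray, ref: np.ndarray, window: int = 11,
         sigma: float = 1.5, data_range: float = 255.0) -> float:
    """Structural similarity of the two masks rendered as {0, 255} images.

    Canonical parameters: Gaussian-weighted 11x11 windows, sigma 1.5,
    C1 = (0.01 L)^2, C2 = (0.03 L)^2, mean over the SSIM map.
    """
    pred = _as_bool(pred, "pred")
    ref = _as_bool(ref, "ref")
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    if min(pred.shape) < window:
        raise ValueError(f"image smaller than the {window}x{window} SSIM window")
    return float(
        structural_similarity(
            pred.astype(np.uint8) * 255,
            ref.astype(np.uint8) * 255,
            win_size=window,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def count_regression(pred_counts, true_counts) -> CountRegressionReport:
    """OLS of algorithm counts on manual counts: pred ~ slope*true + intercept."""
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true count lists must have equal length")
    if pred.size < 3:
        raise ValueError("count regression needs at least 3 plots")
    if np.ptp(true) == 0:
        raise ValueError("true counts are constant; the regression is degenerate")
    res = _stats.linregress(true, pred)
    residuals = pred - (res.slope * true + res.intercept)
    return CountRegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=float(residuals.std(ddof=1)),
        n=int(pred.size),
    )


def evaluate_batch(pairs) -> EvalReport:
    """All indicators per (pred, ref) pair plus mean and SD per indicator."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_batch needs at least one mask pair")
    rows = []
    for idx, (pred, ref) in enumerate(pairs):
        try:
            qseg, sr, precision, recall, f = pixel_metrics(pred, ref)
            s = ssim(pred, ref)
            tp, tn, fp, fn = confusion(pred, ref)
        except Exception as exc:
            raise type(exc)(f"image {idx}: {exc}") from exc
        rows.append({"image": idx, "Qseg": qseg, "Sr": sr, "SSIM": s,
                     "Precision": precision, "Recall": recall, "F": f,
                     "TP": tp, "TN": tn, "FP": fp, "FN": fn})
    per_image = pd.DataFrame(rows).set_index("image")
    cols = list(_INDICATORS)
    summary = pd.DataFrame(
        {"mean": per_image[cols].mean(), "sd": per_image[cols].std(ddof=1)}
    ).T
    if len(per_image) == 1:
        summary.loc["sd"] = 0.0
    return EvalReport(per_image=per_image, summary=summary)
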