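"""Evaluation metrics for both halves of the pipeline.

Segmentation: per-class IoU and accuracy from confusion counts, their
class means (mIoU, mAcc), and frame-rate figures (FPS, aFPS).
Regression: R^2, RMSE, MSE (population-normalized) and MAE in pounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------

@dataclass
class SegMetrics:
    iou_per_class: dict[int, float]
    acc_per_class: dict[int, float]
    miou: float
    macc: float
    fps: float = 0.0
    afps: float = 0.0


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """K x K matrix with rows = truth class, cols = predicted class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size and (pred.max() >= n_classes or truth.max() >= n_classes):
        raise ValueError("label outside [0, n_classes)")
    idx = truth.reshape(-1).astype(np.int64) * n_classes + pred.reshape(-1).astype(np.int64)
    return np.bincount(idx, minlength=n_classes * n_classes).reshape(n_classes, n_classes)


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     n_classes: int) -> dict[int, dict[str, int]]:
    """Per-class one-vs-rest (TP, TN, FP, FN) pixel counts."""
    cm = confusion_matrix(pred, truth, n_classes)
    total = int(cm.sum())
    out = {}
    for c in range(n_classes):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        out[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": total - tp - fp - fn}
    return out


def iou(counts: dict[str, int]) -> float:
    """TP / (TP + FP + FN); an absent class predicted absent scores 1."""
    union = counts["TP"] + counts["FP"] + counts["FN"]
    if union == 0:
        warnings.warn("empty union: class absent and never predicted; IoU := 1.0")
        return 1.0
    return counts["TP"] / union


def accuracy(counts: dict[str, int]) -> float:
    denom = counts["TP"] + counts["TN"] + counts["FP"] + counts["FN"]
    if denom == 0:
        warnings.warn("no pixels; accuracy := 1.0")
        return 1.0
    return (counts["TP"] + counts["TN"]) / denom


def miou(iou_per_class: dict[int, float]) -> float:
    return float(np.mean(list(iou_per_class.values())))


def macc(acc_per_class: dict[int, float]) -> float:
    return float(np.mean(list(acc_per_class.values())))


def seg_metrics_from_counts(counts: dict[int, dict[str, int]],
                            fps_value: float = 0.0, afps_value: float = 0.0) -> SegMetrics:
    ious = {c: iou(cc) for c, cc in counts.items()}
    accs = {c: accuracy(cc) for c, cc in counts.items()}
    return SegMetrics(iou_per_class=ious, acc_per_class=accs,
                      miou=miou(ious), macc=macc(accs),
                      fps=fps_value, afps=afps_value)


def evaluate_masks(preds: list[np.ndarray], truths: list[np.ndarray], n_classes: int,
                   frame_times: list[float] | None = None,
                   per_image: bool = False) -> SegMetrics:
    """Aggregate metrics over an evaluation set.

    Default accumulates confusion counts over the whole set (standard
    convention); ``per_image=True`` averages per-image metrics instead.
    """
    if per_image:
        per = [seg_metrics_from_counts(confusion_counts(p, t, n_classes))
               for p, t in zip(preds, truths)]
        ious = {c: float(np.mean([m.iou_per_class[c] for m in per])) for c in range(n_classes)}
        accs = {c: float(np.mean([m.acc_per_class[c] for m in per])) for c in range(n_classes)}
        m = SegMetrics(ious, accs, miou(ious), macc(accs))
    else:
        cm = np.zeros((n_classes, n_classes), dtype=np.int64)
        for p, t in zip(preds, truths):
            cm += confusion_matrix(p, t, n_classes)
        total = int(cm.sum())
        counts = {}
        for c in range(n_classes):
            tp = int(cm[c, c]); fn = int(cm[c].sum() - tp); fp = int(cm[:, c].sum() - tp)
            counts[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": total - tp - fp - fn}
        m = seg_metrics_from_counts(counts)
    if frame_times:
        m.fps = fps(float(np.median(frame_times)))
        m.afps = afps(len(frame_times), float(np.sum(frame_times)))
    return m


def fps(frame_time: float) -> float:
    """Frames per second from one frame's processing time."""
    if frame_time <= 0:
        raise ValueError("frame time must be positive")
    return 1.0 / frame_time


def afps(n_frames: int, total_time: float) -> float:
    """Average FPS: total frames over total processing time."""
    if total_time <= 0:
        raise ValueError("total time must be positive")
    return n_frames / total_time


# ---------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------

@dataclass
class EvalReport:
    r2: float | None
    rmse: float
    mse: float
    mae: float
    model_tag: str = ""
    split_tag: str = ""
    n: int = 0
    error: str | None = None

    def as_dict(self) -> dict:
        return {"model": self.model_tag, "split": self.split_tag, "n": self.n,
                "R2": self.r2, "RMSE": self.rmse, "MSE": self.mse, "MAE": self.mae}


def regression_metrics(y, yhat, model_tag: str = "", split_tag: str = "") -> EvalReport:
    """R^2, RMSE, MSE, MAE between actual and predicted weights (pounds).

    MSE is population-normalized (divide by n).  R^2 is undefined for a
    constant target and reported as missing.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    resid = y - yhat
    mse = float(np.mean(resid ** 2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant target: R^2 undefined")
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return EvalReport(r2=r2, rmse=rmse, mse=mse, mae=mae,
                      model_tag=model_tag, split_tag=split_tag, n=y.size)


# ---------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------

def seg_table(rows: dict[str, dict[str, SegMetrics]], class_names: dict[int, str]) -> pd.DataFrame:
    """Ablation-style table: one row per variant, IoU/Acc/FPS per view + means.

    ``rows`` maps variant name -> {view -> SegMetrics}; the foreground
    class of each view is reported under that view's name.
    """
    out = []
    for variant, by_view in rows.items():
        rec: dict[str, float | str] = {"variant": variant}
        mious, maccs = [], []
        for view, m in by_view.items():
            fg = max(m.iou_per_class)  # foreground = highest class index
            rec[f"IoU_{view}"] = m.iou_per_class[fg]
            rec[f"Acc_{view}"] = m.acc_per_class[fg]
            rec[f"FPS_{view}"] = m.fps
            mious.append(m.miou)
            maccs.append(m.macc)
        rec["aFPS"] = float(np.mean([by_view[v].afps for v in by_view])) if by_view else 0.0
        rec["mIoU"] = float(np.mean(mious))
        rec["mAcc"] = float(np.mean(maccs))
        out.append(rec)
    return pd.DataFrame(out)


def regression_table(reports: list[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
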