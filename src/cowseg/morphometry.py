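"""From predicted masks to the five-feature regression input.

The weight regressors consume, per animal: top-view silhouette area
(A_t), back-view silhouette area (A_b), top-view shooting height (H_t,
m), back-view shooting distance (H_b, m) and age in months.  Areas come
from counting foreground pixels of the segmentation masks, optionally
converted to m^2 through the pinhole pixel scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

FEATURE_NAMES = ["A_t", "A_b", "H_t", "H_b", "age"]
FEATURE_CSV_COLUMNS = ["id", "A_t", "A_b", "H_t", "H_b", "age", "weight"]


@dataclass
class FeatureVector:
    id: str
    A_t: float
    A_b: float
    H_t: float
    H_b: float
    age: float
    weight: float | None = None

    def __post_init__(self):
        if self.A_t < 0 or self.A_b < 0:
            raise ValueError("areas must be non-negative")
        if self.H_t <= 0 or self.H_b <= 0:
            raise ValueError("shooting height/distance must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.A_t, self.A_b, self.H_t, self.H_b, self.age], dtype=float)


def mask_area(mask: np.ndarray, class_index: int = 1,
              pixel_scale: float | None = None) -> float:
    """Pixel count of a class, optionally converted to m^2 via scale^2."""
    count = float(np.count_nonzero(np.asarray(mask) == class_index))
    if count == 0:
        warnings.warn(f"class {class_index} absent from mask; area 0")
    if pixel_scale is not None:
        return count * pixel_scale ** 2
    return count


def largest_component(mask: np.ndarray, class_index: int = 1) -> np.ndarray:
    """Keep only the largest connected component of a class (speckle filter)."""
    binary = np.asarray(mask) == class_index
    labels, n = ndimage.label(binary)
    if n <= 1:
        return np.where(binary, np.uint8(class_index), np.uint8(0))
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return np.where(labels == keep, np.uint8(class_index), np.uint8(0))


def assemble_features(top, back, clean_predicted: bool = False) -> FeatureVector:
    """Build one animal's 5-feature vector from its two view samples.

    ``top`` / ``back`` are :class:`~cowseg.data_io.ImageSample` objects
    carrying masks and metadata; areas are returned in m^2 when the
    samples carry a ``pixel_scale_m``, else in pixels.
    ``clean_predicted`` applies the largest-connected-component filter
    (recommended for predicted, not ground-truth, masks).
    """
    if top.view != "top":
        raise ValueError(f"expected a top view, got {top.view!r}")
    if back.view != "back":
        raise ValueError(f"expected a back view, got {back.view!r}")
    tid, bid = top.meta.get("id"), back.meta.get("id")
    if tid is not None and bid is not None and tid != bid:
        raise ValueError(f"animal id mismatch: top {tid!r} vs back {bid!r}")
    for name, s in (("top", top), ("back", back)):
        if s.mask is None:
            raise ValueError(f"missing {name} mask")
    areas = {}
    for key, s in (("top", top), ("back", back)):
        mask = s.mask
        if clean_predicted:
            mask = largest_component(mask)
        areas[key] = mask_area(mask, 1, s.meta.get("pixel_scale_m"))
    return FeatureVector(
        id=str(tid if tid is not None else bid if bid is not None else ""),
        A_t=areas["top"],
        A_b=areas["back"],
        H_t=float(top.meta["cam_height_m"]),
        H_b=float(back.meta["cam_distance_m"]),
        age=float(top.meta["age_months"]),
        weight=top.meta.get("weight_lb"),
    )


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    rows = [{"id": f.id, "A_t": f.A_t, "A_b": f.A_b, "H_t": f.H_t,
             "H_b": f.H_b, "age": f.age, "weight": f.weight} for f in features]
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)


# ---------------------------------------------------------------------
# feature scaling
# ---------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature scaling: min-max onto [-1, 1] or z-score."""

    mode: str
    lo: np.ndarray  # min or mean
    hi: np.ndarray  # max or sd
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mode == "minmax_pm1":
            return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0
        return (x - self.lo) / self.hi

    def invert(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.mode == "minmax_pm1":
            return self.lo + (z + 1.0) * (self.hi - self.lo) / 2.0
        return z * self.hi + self.lo


def fit_scaler(x: np.ndarray, mode: str = "minmax_pm1",
               names: list[str] | None = None) -> FeatureScaler:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 samples")
    names = names or [f"x{i}" for i in range(x.shape[1])]
    if mode == "minmax_pm1":
        lo, hi = x.min(axis=0), x.max(axis=0)
        bad = np.where(hi <= lo)[0]
    elif mode == "zscore":
        lo, hi = x.mean(axis=0), x.std(axis=0)
        bad = np.where(hi == 0)[0]
    else:
        raise ValueError(f"unknown scaler mode {mode!r}")
    if bad.size:
        raise ValueError(f"constant feature(s): {[names[i] for i in bad]}")
    return FeatureScaler(mode=mode, lo=lo, hi=hi, names=list(names))
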