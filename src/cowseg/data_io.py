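"""Reading, writing and preprocessing of images, masks and annotations.

Covers the capture-side plumbing of the pipeline: Labelme polygon
annotations to 8-bit indexed label masks, proportional resize of camera
frames to the fixed network input size, dataset manifests and the
stratified train/test split.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: fixed network input size (rows, cols) used for both camera views
TARGET_SIZE = (704, 1216)

_PALETTE = [0, 0, 0, 230, 60, 60] + [i for v in range(2, 256) for i in (v, v, v)]


# ---------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------

@dataclass
class ImageSample:
    """One view of one animal: image, optional label mask and metadata.

    ``meta`` carries the per-animal record (age in months, camera height
    and distance in metres, scale weight in pounds when known).
    """

    image: np.ndarray
    view: str
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.view not in ("top", "back"):
            raise ValueError(f"view must be 'top' or 'back', got {self.view!r}")
        if self.mask is not None and self.mask.shape[:2] != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape[:2]} != image shape {self.image.shape[:2]}"
            )


@dataclass
class ManifestRecord:
    id: str
    view: str
    image_path: str
    mask_path: str | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    split_tag: str = "none"
    root: str = "."

    def __post_init__(self):
        keys = [(r.id, r.view) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (id, view) pairs in manifest")

    def __len__(self):
        return len(self.records)

    def by_view(self, view: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.view == view]

    def save(self, path: str | Path) -> None:
        doc = {
            "split_tag": self.split_tag,
            "root": self.root,
            "records": [
                {"id": r.id, "view": r.view, "image_path": r.image_path,
                 "mask_path": r.mask_path, "meta": r.meta}
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        doc = json.loads(Path(path).read_text())
        recs = [ManifestRecord(**r) for r in doc["records"]]
        return cls(records=recs, split_tag=doc.get("split_tag", "none"),
                   root=doc.get("root", str(Path(path).parent)))

    def validate_files(self) -> None:
        root = Path(self.root)
        for r in self.records:
            if not (root / r.image_path).exists():
                raise FileNotFoundError(r.image_path)
            if r.mask_path is not None and not (root / r.mask_path).exists():
                raise FileNotFoundError(r.mask_path)


# ---------------------------------------------------------------------
# Labelme conversion
# ---------------------------------------------------------------------

def rasterize_polygon(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of a polygon on pixel centers.

    ``points`` are (x, y) vertices (Labelme convention); pixel centers sit
    at integer coordinates, row-major, 0-based.  Returns a boolean mask.
    A pixel is inside when a horizontal ray to -x crosses an odd number
    of edges.
    """
    h, w = shape
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError(f"polygon needs >= 3 (x, y) vertices, got shape {pts.shape}")
    ys = np.arange(h, dtype=np.float64)[:, None]
    xs = np.arange(w, dtype=np.float64)[None, :]
    inside = np.zeros((h, w), dtype=bool)
    n = pts.shape[0]
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if y1 == y2:
            continue
        spans = (y1 > ys) != (y2 > ys)          # (h, 1)
        xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)  # (h, 1)
        inside ^= spans & (xs < xint)
    return inside


def labelme_to_mask(annotation: dict, class_map: dict[str, int],
                    shape: tuple[int, int] | None = None) -> np.ndarray:
    """Convert a Labelme JSON document to an 8-bit label mask.

    Polygons are rasterized in file order; later shapes overwrite earlier
    ones.  Unannotated pixels stay 0 (background).
    """
    if shape is None:
        shape = (annotation["imageHeight"], annotation["imageWidth"])
    mask = np.zeros(shape, dtype=np.uint8)
    for i, sh in enumerate(annotation.get("shapes", [])):
        label = sh["label"]
        if label not in class_map:
            raise KeyError(f"class {label!r} (shape {i}) not in class_map")
        idx = class_map[label]
        if not 0 <= idx <= 255:
            raise ValueError(f"class index {idx} does not fit in 8 bits")
        try:
            poly = rasterize_polygon(np.asarray(sh["points"]), shape)
        except ValueError as e:
            raise ValueError(f"malformed polygon at shape {i}: {e}") from e
        mask[poly] = idx
    return mask


def to_uint8_labels(mask: np.ndarray) -> np.ndarray:
    """Value-preserving cast of a (possibly 16-bit) label mask to 8 bits.

    Labels are indices, not intensities, so no rescaling: any value above
    255 is an error.
    """
    m = np.asarray(mask)
    if m.size and m.max() > 255:
        raise ValueError(f"label value {int(m.max())} exceeds 8-bit range")
    if m.size and m.min() < 0:
        raise ValueError("negative label value")
    return m.astype(np.uint8)


# ---------------------------------------------------------------------
# PNG helpers
# ---------------------------------------------------------------------

def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image.astype(np.uint8)).save(path)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as an 8-bit indexed (palette) PNG — lossless."""
    im = Image.fromarray(to_uint8_labels(mask), mode="P")
    im.putpalette(_PALETTE[:768])
    im.save(path)


def load_mask(path: str | Path) -> np.ndarray:
    im = Image.open(path)
    if im.mode not in ("P", "L"):
        im = im.convert("L")
    return np.asarray(im, dtype=np.uint8)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def preprocess_frame(image: np.ndarray, target: tuple[int, int] = TARGET_SIZE,
                     is_mask: bool = False) -> tuple[np.ndarray, dict]:
    """Proportionally resize a frame and pad it to the fixed input size.

    The frame is scaled so its limiting dimension fits ``target`` (aspect
    ratio preserved), then symmetrically zero-padded to exactly
    ``target``.  Masks go through nearest-neighbour so label values are
    preserved.  Returns the processed array and an info dict with the
    scale factor and padding offsets (needed to convert pixel areas back
    to physical units).
    """
    arr = np.asarray(image)
    if arr.ndim not in (2, 3) or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError(f"degenerate input of shape {arr.shape}")
    h, w = arr.shape[:2]
    th, tw = target
    info = {"scale": 1.0, "pad_top": 0, "pad_left": 0}
    if (h, w) == (th, tw):
        return arr, info
    scale = min(th / h, tw / w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    resample = Image.NEAREST if is_mask else Image.BILINEAR
    if arr.ndim == 2 and is_mask:
        pil = Image.fromarray(arr.astype(np.uint8))
    else:
        pil = Image.fromarray(arr.astype(np.uint8))
    resized = np.asarray(pil.resize((nw, nh), resample))
    pad_t = (th - nh) // 2
    pad_l = (tw - nw) // 2
    if resized.ndim == 2:
        out = np.zeros((th, tw), dtype=resized.dtype)
        out[pad_t:pad_t + nh, pad_l:pad_l + nw] = resized
    else:
        out = np.zeros((th, tw, resized.shape[2]), dtype=resized.dtype)
        out[pad_t:pad_t + nh, pad_l:pad_l + nw] = resized
    info.update(scale=scale, pad_top=pad_t, pad_left=pad_l)
    return out, info


# ---------------------------------------------------------------------
# split
# ---------------------------------------------------------------------

def split_dataset(manifest: DatasetManifest, ratio: tuple[float, float] = (0.8, 0.2),
                  seed: int = 0) -> tuple[DatasetManifest, DatasetManifest]:
    """Random per-view stratified split, reproducible under ``seed``."""
    if min(ratio) <= 0:
        raise ValueError("split ratio entries must be positive")
    if len(manifest.records) < 2:
        raise ValueError("need at least 2 records to split")
    frac_train = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train: list[ManifestRecord] = []
    test: list[ManifestRecord] = []
    for view in sorted({r.view for r in manifest.records}):
        recs = sorted(manifest.by_view(view), key=lambda r: r.id)
        order = rng.permutation(len(recs))
        n_train = round(len(recs) * frac_train)
        for pos, k in enumerate(order):
            (train if pos < n_train else test).append(recs[k])
    return (DatasetManifest(train, split_tag="train", root=manifest.root),
            DatasetManifest(test, split_tag="test", root=manifest.root))


def load_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str})
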