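"""Synthetic barn-scene generator.

Produces paired top-view / back-view silhouette images with pixel-exact
ground-truth masks, physical areas, camera geometry and scale weights,
so the whole segmentation-to-weight pipeline can be exercised without
farm imagery.  The top view draws a superellipse trunk with head and
shoulder protrusions; the back view a rounded-trapezoid torso with legs.
Backgrounds carry an illumination gradient, rectangular clutter and
speckle noise controlled by ``clutter_level``.

The generative weight model is a fixed, documented truth:

    W = 520 * A_top^0.9 * A_back^0.45 * g(age) + eps
    g(age) = 0.45 + 0.55 * (1 - exp(-age / 10))

with ``eps ~ Normal(0, noise_sigma_weight)``.  The saturating ``g``
emulates the deceleration of growth after roughly a year of age, and the
constants place weights in the few-hundred-pound range typical of young
beef cattle.  Pixel scales follow a pinhole model with a fixed nominal
focal ratio, so shooting height/distance are genuinely informative
covariates for recovering physical area from pixel area.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    DatasetManifest,
    ImageSample,
    ManifestRecord,
    file_sha256,
    save_image,
    save_mask,
)

log = logging.getLogger(__name__)

#: generative weight-model constants (pounds, m^2, months)
WEIGHT_COEF = 520.0
TOP_AREA_EXP = 0.9
BACK_AREA_EXP = 0.45
AGE_SATURATION_MONTHS = 10.0

#: nominal focal length expressed as a multiple of image height
FOCAL_RATIO = 1.2

METADATA_COLUMNS = ["id", "view", "age_months", "cam_height_m",
                    "cam_distance_m", "area_true_m2", "weight_lb"]


@dataclass
class SceneParams:
    """Study conditions for the synthetic herd."""

    n_animals: int = 55
    age_range: tuple[float, float] = (4.0, 23.0)
    top_area_range: tuple[float, float] = (0.7, 1.6)
    back_area_range: tuple[float, float] = (0.4, 1.1)
    top_cam_height: float = 2.5
    back_cam_height: float = 1.5
    back_cam_distance: float = 2.3
    image_size: tuple[int, int] = (704, 1216)
    clutter_level: float = 0.5
    noise_sigma_weight: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for name in ("age_range", "top_area_range", "back_area_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        if min(self.image_size) <= 0:
            raise ValueError("image_size must be positive")
        if not 0.0 <= self.clutter_level <= 1.0:
            raise ValueError("clutter_level must lie in [0, 1]")


@dataclass
class MorphTruth:
    """Ground-truth morphometry for one animal."""

    A_top_true: float
    A_back_true: float
    age: float
    weight: float
    pixel_scale_top: float
    pixel_scale_back: float
    cam_height_top: float = 2.5
    cam_distance_back: float = 2.3
    cam_height_back: float = 1.5

    def __post_init__(self):
        for name in ("A_top_true", "A_back_true", "weight",
                     "pixel_scale_top", "pixel_scale_back"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")


def growth_factor(age: float | np.ndarray) -> float | np.ndarray:
    """Saturating age factor g(age) = 0.45 + 0.55*(1 - exp(-age/10))."""
    return 0.45 + 0.55 * (1.0 - np.exp(-np.asarray(age, dtype=float) / AGE_SATURATION_MONTHS))


def true_weight(A_top: float, A_back: float, age: float,
                noise_sigma: float = 0.0,
                rng: np.random.Generator | None = None) -> float:
    """Generative scale weight in pounds for given areas (m^2) and age (months)."""
    if A_top <= 0 or A_back <= 0:
        raise ValueError("areas must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    w = WEIGHT_COEF * A_top ** TOP_AREA_EXP * A_back ** BACK_AREA_EXP * growth_factor(age)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng()
        w += rng.normal(0.0, noise_sigma)
    return float(w)


def pixel_scale(distance_m: float, image_height: int) -> float:
    """Metres per pixel under the pinhole model with the nominal focal ratio."""
    return distance_m / (FOCAL_RATIO * image_height)


def sample_morph(params: SceneParams, rng: np.random.Generator) -> MorphTruth:
    """Draw one animal's morphometry.

    Areas grow with age (linear trend across the configured ranges plus
    scatter) so age, area and weight are correlated as in a real herd;
    camera height/distance get small per-shoot jitter so the geometry
    covariates carry information.
    """
    lo_a, hi_a = params.age_range
    age = float(rng.uniform(lo_a, hi_a))
    u = 0.5 if hi_a == lo_a else (age - lo_a) / (hi_a - lo_a)

    def draw_area(lo, hi):
        mean = lo + u * (hi - lo)
        sd = 0.10 * (hi - lo)
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    a_top = draw_area(*params.top_area_range)
    a_back = draw_area(*params.back_area_range)
    h_top = params.top_cam_height * float(rng.uniform(0.92, 1.08))
    d_back = params.back_cam_distance * float(rng.uniform(0.92, 1.08))
    h_img, _ = params.image_size
    w = true_weight(a_top, a_back, age, params.noise_sigma_weight, rng)
    return MorphTruth(
        A_top_true=a_top,
        A_back_true=a_back,
        age=age,
        weight=w,
        pixel_scale_top=pixel_scale(h_top, h_img),
        pixel_scale_back=pixel_scale(d_back, h_img),
        cam_height_top=h_top,
        cam_distance_back=d_back,
        cam_height_back=params.back_cam_height,
    )


# ---------------------------------------------------------------------
# silhouette rasterization
# ---------------------------------------------------------------------

def _top_silhouette(shape, scale_px, shape_rng_state, grid=None):
    """Boolean mask of a superellipse trunk + head/shoulder protrusions.

    ``scale_px`` is the trunk semi-length in pixels; all other dimensions
    are proportions of it, drawn once from ``shape_rng_state`` so the
    silhouette is stable while the overall scale is adjusted.
    """
    h, w = shape
    (aspect, exp_p, wobble_amp, wobble_ph, head_len, head_wid, theta) = shape_rng_state
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = h / 2.0, w / 2.0
    ct, st = np.cos(theta), np.sin(theta)
    u = (xs - cx) * ct + (ys - cy) * st
    v = -(xs - cx) * st + (ys - cy) * ct
    a = scale_px
    b = scale_px / aspect
    phi = np.arctan2(v, u)
    rmod = 1.0 + wobble_amp * np.sin(3.0 * phi + wobble_ph)
    trunk = (np.abs(u / a) ** exp_p + np.abs(v / b) ** exp_p) <= rmod
    # head: ellipse protruding beyond the trunk front
    hu, hv = a * (1.0 + 0.55 * head_len), 0.0
    head = (((u - hu) / (a * head_len)) ** 2 + ((v - hv) / (b * head_wid)) ** 2) <= 1.0
    # shoulder bumps
    s1 = (((u + 0.45 * a) / (0.22 * a)) ** 2 + ((v - 0.85 * b) / (0.35 * b)) ** 2) <= 1.0
    s2 = (((u + 0.45 * a) / (0.22 * a)) ** 2 + ((v + 0.85 * b) / (0.35 * b)) ** 2) <= 1.0
    return trunk | head | s1 | s2


def _back_silhouette(shape, scale_px, shape_rng_state, grid=None):
    """Rounded-trapezoid torso with two legs, as seen from behind."""
    h, w = shape
    (width_top, width_bot, round_p, leg_w, leg_h, tilt) = shape_rng_state
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = h / 2.0 - 0.5 * leg_h * scale_px, w / 2.0  # lift torso so legs fit
    u = xs - cx + tilt * (ys - cy)
    v = ys - cy
    half_h = scale_px
    t = np.clip((v + half_h) / (2 * half_h), 0.0, 1.0)  # 0 at top, 1 at bottom
    half_w = half_h * (width_top + (width_bot - width_top) * t)
    torso = (np.abs(u / half_w) ** round_p + np.abs(v / half_h) ** round_p) <= 1.0
    legs = np.zeros_like(torso)
    for sgn in (-1.0, 1.0):
        lx = sgn * 0.45 * half_h * width_bot
        leg = (np.abs(u - lx) <= leg_w * half_h) & (v >= 0.6 * half_h) & \
              (v <= (1.0 + leg_h) * half_h)
        legs |= leg
    return torso | legs


def _draw_silhouette(kind: str, shape: tuple[int, int], target_px: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Rasterize a silhouette whose pixel count matches ``target_px``.

    The shape is drawn at an analytic initial scale, measured, and the
    scale adjusted (area scales quadratically) until the pixel count is
    within 1% of target.  A silhouette touching the frame border triggers
    regeneration at a smaller scale (logged), so masks never clip.
    """
    h, w = shape
    if kind == "top":
        state = (
            float(rng.uniform(2.1, 2.7)),    # aspect length/width
            float(rng.uniform(2.2, 3.0)),    # superellipse exponent
            float(rng.uniform(0.02, 0.06)),  # boundary wobble amplitude
            float(rng.uniform(0, 2 * np.pi)),
            float(rng.uniform(0.28, 0.38)),  # head length fraction
            float(rng.uniform(0.45, 0.6)),   # head width fraction
            float(rng.uniform(-0.08, 0.08)),  # orientation jitter (rad)
        )
        raster = _top_silhouette
        scale = np.sqrt(target_px * state[0]) / 2.0  # rough a from area ~ 4ab/aspect
    else:
        state = (
            float(rng.uniform(0.85, 1.0)),   # top half-width / half-height
            float(rng.uniform(1.05, 1.25)),  # bottom half-width / half-height
            float(rng.uniform(2.0, 2.8)),    # corner roundness
            float(rng.uniform(0.08, 0.12)),  # leg half-width fraction
            float(rng.uniform(0.15, 0.25)),  # leg length fraction
            float(rng.uniform(-0.05, 0.05)),  # tilt
        )
        raster = _back_silhouette
        scale = np.sqrt(target_px / 3.6)
    max_scale = np.inf
    for attempt in range(25):
        mask = raster(shape, scale, state)
        area = int(mask.sum())
        if area == 0:
            scale *= 1.5
            continue
        touches = (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())
        if touches:
            log.info("silhouette clipped frame (scale %.1f px); regenerating smaller", scale)
            max_scale = scale * 0.97
            scale = max_scale
            continue
        rel = area / target_px
        if abs(rel - 1.0) <= 0.01:
            return mask
        scale = min(scale / np.sqrt(rel), max_scale)
        if scale == max_scale and rel < 1.0:
            return mask  # frame-limited: best achievable without clipping
    return mask


def _background(shape, clutter, rng):
    h, w = shape
    base = rng.uniform(90, 140)
    grad = np.linspace(-1, 1, h)[:, None] * rng.uniform(-25, 25)
    img = np.full((h, w), base) + grad
    img = np.repeat(img[:, :, None], 3, axis=2)
    img += rng.normal(0, 4, size=(h, w, 1))
    n_rect = int(round(clutter * 8))
    for _ in range(n_rect):
        rh = rng.integers(max(2, h // 12), max(3, h // 3))
        rw = rng.integers(max(2, w // 12), max(3, w // 3))
        r0 = rng.integers(0, max(1, h - rh))
        c0 = rng.integers(0, max(1, w - rw))
        col = rng.uniform(40, 200, size=3)
        img[r0:r0 + rh, c0:c0 + rw] = 0.6 * img[r0:r0 + rh, c0:c0 + rw] + 0.4 * col
    if clutter > 0:
        speck = rng.random((h, w)) < 0.02 * clutter
        img[speck] = rng.uniform(30, 220, size=(int(speck.sum()), 3))
    return img


def render_pair(morph: MorphTruth, params: SceneParams,
                rng: np.random.Generator) -> tuple[ImageSample, ImageSample]:
    """Render aligned (image, mask) pairs for the two views of one animal."""
    h, w = params.image_size
    out = []
    for view in ("top", "back"):
        if view == "top":
            ps, area = morph.pixel_scale_top, morph.A_top_true
            meta_cam = {"cam_height_m": morph.cam_height_top,
                        "cam_distance_m": morph.cam_height_top}
        else:
            ps, area = morph.pixel_scale_back, morph.A_back_true
            meta_cam = {"cam_height_m": morph.cam_height_back,
                        "cam_distance_m": morph.cam_distance_back}
        target_px = area / ps ** 2
        if target_px > 0.6 * h * w:
            raise ValueError(
                f"{view} silhouette ({target_px:.0f} px) too large for frame {h}x{w}"
            )
        mask = _draw_silhouette(view, (h, w), target_px, rng)
        img = _background((h, w), params.clutter_level, rng)
        body = np.array([rng.uniform(95, 150), rng.uniform(60, 95), rng.uniform(45, 75)])
        texture = rng.normal(0, 6, size=(h, w, 1))
        fg = body[None, None, :] + texture + \
            np.linspace(-1, 1, w)[None, :, None] * rng.uniform(-10, 10)
        img[mask] = fg[mask]
        img = np.clip(img, 0, 255).astype(np.uint8)
        meta = {"age_months": morph.age, "weight_lb": morph.weight,
                "area_true_m2": area, "pixel_scale_m": ps, **meta_cam}
        out.append(ImageSample(image=img, view=view,
                               mask=mask.astype(np.uint8), meta=meta))
    return out[0], out[1]


def generate_feature_table(params: SceneParams, n: int,
                           seed: int | None = None) -> pd.DataFrame:
    """Sample n animals' five-feature rows straight from the generative
    model (no rendering): columns A_t, A_b, H_t, H_b, age, weight."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for i in range(n):
        m = sample_morph(params, rng)
        rows.append({"id": f"cow{i:04d}", "A_t": m.A_top_true, "A_b": m.A_back_true,
                     "H_t": m.cam_height_top, "H_b": m.cam_distance_back,
                     "age": m.age, "weight": m.weight})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------

def generate_dataset(params: SceneParams, n_per_view: int = 550,
                     out_dir: str | Path = "synthetic") -> DatasetManifest:
    """Write a full paired dataset (PNG images, indexed-PNG masks, CSV, manifest).

    ``n_per_view`` animals are generated, each contributing one top-view
    and one back-view record.  Regeneration under the same ``params.seed``
    is byte-identical.  On failure, partially written output is removed.
    """
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    records: list[ManifestRecord] = []
    rows = []
    try:
        for i in range(n_per_view):
            animal_id = f"cow{i:04d}"
            morph = sample_morph(params, rng)
            top, back = render_pair(morph, params, rng)
            for s in (top, back):
                img_name = f"{animal_id}_{s.view}.png"
                mask_name = f"{animal_id}_{s.view}_mask.png"
                save_image(s.image, out / img_name)
                save_mask(s.mask, out / mask_name)
                records.append(ManifestRecord(
                    id=animal_id, view=s.view, image_path=img_name,
                    mask_path=mask_name, meta=dict(s.meta)))
                rows.append({
                    "id": animal_id, "view": s.view,
                    "age_months": round(s.meta["age_months"], 4),
                    "cam_height_m": round(s.meta["cam_height_m"], 4),
                    "cam_distance_m": round(s.meta["cam_distance_m"], 4),
                    "area_true_m2": round(s.meta["area_true_m2"], 6),
                    "weight_lb": round(s.meta["weight_lb"], 2),
                })
        meta_df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
        meta_df.to_csv(out / "metadata.csv", index=False)
        manifest = DatasetManifest(records, split_tag="none", root=str(out))
        manifest.save(out / "manifest.json")
        checks = {r.image_path: file_sha256(out / r.image_path) for r in records}
        checks.update({r.mask_path: file_sha256(out / r.mask_path) for r in records})
        (out / "checksums.json").write_text(json.dumps(checks, indent=0, sort_keys=True))
        (out / "scene_params.json").write_text(json.dumps(asdict(params), indent=1))
        return manifest
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
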