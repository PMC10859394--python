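# Methods

This note documents the models, numerical choices and limitations of
the package: what each stage computes, which parameters matter, what
the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## 1. Synthetic barn scenes

The generator stands in for a private farm dataset of paired top-view /
back-view images of young cattle (ages 4–23 months) captured with the
top camera ~2.5 m above the ground and the back camera 1.5 m high at
~2.3 m distance, frames preprocessed to 704×1216 pixels.

**Geometry.** Pixel scale follows a pinhole model with a fixed nominal
focal ratio of 1.2 (focal length = 1.2 × image height in pixels):
`pixel_scale = shooting_distance / (1.2 · H)` metres/pixel. The focal
ratio was chosen once so that the largest configured silhouettes
(1.6 m² top view) occupy a realistic fraction of the frame (~25%) with
margin at every supported resolution; shooting height/distance receive
±8% per-animal jitter so the geometry covariates carry real information
about the pixel-to-area conversion, as they do with a hand-held camera.

**Silhouettes.** The top view draws a superellipse trunk (exponent
2.2–3.0, aspect 2.1–2.7) with a protruding head ellipse, two shoulder
bumps and a low-frequency boundary wobble; the back view a
rounded-trapezoid torso (wider at the bottom) with two legs, lifted so
the legs fit the frame. The rasterized pixel count is adjusted by
iterative rescaling until it matches the target area to 1% (area scales
quadratically with the linear scale, so 2–3 iterations suffice); a
silhouette touching the frame border triggers regeneration at a
slightly smaller scale (logged), so masks never clip. Backgrounds carry
an illumination gradient, up to eight clutter rectangles and speckle
noise controlled by `clutter_level` (default 0.5). Masks are exactly
{0, 1} and regeneration under a fixed seed is byte-identical.

**Weight model.** The generative truth is

    W = 520 · A_top^0.9 · A_back^0.45 · g(age) + ε
    g(age) = 0.45 + 0.55 · (1 − exp(−age / 10 months))
    ε ~ Normal(0, 15 lb)

The exponents make weight roughly proportional to area^1.35 (between an
area and a volume scaling law), the saturating g emulates the observed
deceleration of growth after about a year of age, and the constant 520
places weights in the 150–800 lb range of young beef cattle. The noise
default of 15 lb yields R² in the 0.95–0.99 band for well-specified
regressors at n = 500, so the comparison tables are qualitatively
comparable to field studies. Ages are uniform on the configured range;
areas follow a linear-in-age trend across their ranges with 10% scatter,
so age, area and weight are positively correlated as in a real herd.

**What the generator does not emulate:** photorealistic texture, limb
articulation and posture variation, occlusion, perspective
foreshortening, motion blur, multi-animal scenes, and breed or
body-condition variation. Passing tests therefore demonstrate that the
pipeline machinery is correct and internally consistent — not that the
trained segmenter would transfer to farm imagery.

## 2. Data handling

* **Annotation conversion.** Labelme JSON polygons are rasterized in
  file order (later polygons overwrite earlier ones) with an even–odd
  fill rule evaluated at pixel centers (row-major, 0-based, centers at
  integer coordinates). The rule is pinned so the independent
  point-in-polygon oracle in the tests is well-defined. 16-bit masks are
  converted to 8-bit by value-preserving cast — labels are indices, not
  intensities — with an error on any value above 255.
* **Preprocessing.** Frames are proportionally resized so the limiting
  dimension fits 704×1216, then symmetrically zero-padded to exactly
  that size; whether the original pipeline padded or cropped is
  unstated, and padding was chosen because it preserves the full field
  of view and makes the scale factor (recorded for area back-conversion)
  exact. Masks travel through nearest-neighbour resampling.
* **Split.** Train/test 8:2, stratified per view, seeded.

## 3. Segmentation network

Configuration (`SegConfig`) exposes backbone depth (18 basic-block /
50 / 101 bottleneck), stem style, the average-pool downsampling
shortcut, attention variant (none / SE / ECA / CBAM), SE reduction ratio
(16), ASPP dilation rates (default 12/24/36), output stride (16 or 8),
and class count. Defaults follow DeepLab-family conventions because the
architecture family names the modules, not their hyperparameters.

Numerical and design choices:

* **Loss**: pixel-wise cross-entropy; optional auxiliary head on the
  penultimate stage (weight 0.4, off by default) realizes deep
  supervision.
* **Optimizer**: SGD, momentum 0.9, weight decay (L2) applied to all
  parameters; poly learning-rate schedule with power 0.9.
* **Augmentation**: horizontal flip (p = 0.5) and random scaling
  (0.75–1.25 at full scale, 0.8–1.2 desk) followed by random
  crop/zero-pad back to the fixed input size.
* **Upsampling**: learnable deconvolutions implemented as zero-stuffed
  upsampling followed by a 3×3 convolution (exactly a stride-2
  transposed convolution); the final ×4 stage uses a 7×7 kernel so each
  output pixel sees at least two stuffed samples. A fixed nearest
  upsampling is used only for the auxiliary head.
* **ASPP dilation clamp**: a dilation rate at or beyond the feature-map
  extent is clamped (with a warning) at model-build time; on desk-scale
  6×10 feature maps the defaults would all clamp, so the desk config
  specifies rates 2/4/6.
* **Class scheme**: one binary-foreground model per view (the default),
  because the two views are geometrically dissimilar; a joint 3-class
  model remains available through `n_classes`.
* **Normalization**: inputs map to [−1, 1]; batch normalization with
  running statistics (momentum 0.1) for evaluation mode.
* **Inputs not divisible by 16** are zero-padded on the bottom/right and
  the logits cropped back.

Two configuration scales are provided. The full-scale configuration
(depth-101, 704×1216, batch 8, base lr 0.001, 50 000 iterations, weight
decay 5e-4) mirrors a production training protocol and needs accelerator
hardware; it is not exercised by the tests. The desk configuration
(depth-18, 8 base channels, 96×160 scenes, batch 4, base lr 0.03, ≤500
iterations) trains to validation mIoU ≳ 0.9 in about a minute on one
CPU and is what the test suite and the acceptance script run. The desk
base learning rate was set by observing stable convergence on the
generator's scenes (0.05 oscillated; 0.03 converges smoothly); it is the
package's own choice, as are all desk-scale sizes.

The whole network runs on `cowseg.nn`, a small reverse-mode autodiff
core over float32 numpy arrays (im2col convolutions, pooling, batch
norm, channel/spatial gating, fused softmax cross-entropy). Every
operator's gradient is verified against central finite differences in
the test suite, and convolution against a naive seven-loop reference.

## 4. Metrics

Per class: IoU = TP/(TP+FP+FN) and accuracy = (TP+TN)/total, both from
confusion counts accumulated over the whole evaluation set (per-image
averaging is available as an option); mIoU and mAcc are unweighted class
means. An empty union (class absent and never predicted) scores IoU 1.0
with a warning — the convention only matters for degenerate synthetic
cases. FPS = 1/median frame time and aFPS = frames/total time are
reported but are hardware-dependent, so the pipeline writes them to a
separate timings file and keeps the metric tables deterministic.
Regression metrics follow the standard definitions with MSE normalized
by n (population form); R² is undefined and reported missing for a
constant target.

## 5. Weight regression

Features are min–max scaled to [−1, 1] per feature before the BP
network (targets likewise, inverted at prediction); the hidden
activation is tanh with a linear output — the pairing conventional for
Levenberg–Marquardt-trained regression networks and consistent with the
magnitude range of the published reference weights. The published
network's own scaling scheme and output layer are unknown, so the
reference hidden layer is used only for structural forward-pass checks,
never for weight prediction.

**Levenberg–Marquardt**: residual Jacobian computed analytically per
sample; damped normal equations `(JᵀJ + λI)δ = −Jᵀr` with λ₀ = 1e−3,
×10 on a rejected step, ÷10 on an accepted one; stop on gradient
∞-norm < 1e−7, λ > 1e10, or the epoch limit. Training SSE is
non-increasing over accepted steps by construction. Initialization is
uniform(−0.5, 0.5) under the given seed. Inside the pipeline the BP
scaler maps constant feature columns (e.g. all-zero areas from empty
predicted masks) to the scale midpoint with a warning instead of
failing, so a degraded segmenter degrades the regression rather than
crashing it; the standalone `fit_scaler` keeps the strict
error-on-constant contract.

SVR (RBF, C = 3, ε = 0.05 on standardized features and target — chosen
by 5-fold cross-validation on an independent generator draw), decision
tree, and GPR (constant × RBF + white noise, target-normalized) are
delegated to scikit-learn; MLR is solved by `lstsq` (minimum-norm with a
warning when rank-deficient). The comparison harness fits all five on
the train split and reports R²/RMSE/MSE/MAE per split, recording any
model failure without aborting the rest.

## 6. Determinism and problem sizes

Every stage draws from `numpy.random.default_rng` seeded from the
single pipeline seed, and same-seed reruns produce byte-identical
manifests, feature tables and metric tables (timings excluded). The
test suite and acceptance script use: 24 animals / 300 iterations at
96×160 for segmentation quality, 100 scenes for area recovery, 500+125
animals for the regression comparison, and 12 animals / 60 iterations
for the end-to-end determinism check — sizes chosen so the whole suite
runs in minutes on one CPU while each check still measures what it
claims.

## 7. Known limitations

* The synthetic domain gap (§1): results quantify pipeline correctness,
  not field performance; the published field numbers from real imagery
  are not reproducible here and are not claimed.
* The BP network minimizes empirical risk; LM converges to local optima
  and different seeds give different fits (the recovery check therefore
  aggregates over five seeds).
* Silhouette area is frame-limited for silhouettes that would not fit
  the image; the generator caps the drawn scale rather than clipping,
  so extreme area/resolution combinations bias the rendered area low
  (≤1% at the shipped settings).
* Weights above ~800 lb coincide with the saturating part of the growth
  curve, where all models lose leverage — mirroring the difficulty
  field studies report for heavy animals.
* FPS figures depend entirely on the host; only their formulas are
  contractual.
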