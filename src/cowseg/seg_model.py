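"""Encoder-decoder semantic segmentation network and its training loop.

The encoder is a ResNet-style backbone with two "-D" refinements: a deep
stem of three 3x3 convolutions in place of the single 7x7, and a 2x2
stride-2 average pooling placed before the convolution in each
downsampling shortcut.  Multi-scale context is gathered by an atrous
spatial pyramid pooling (ASPP) block whose fused output passes through a
configurable channel-attention module — squeeze-and-excitation (SE) by
default, with ECA and CBAM variants for ablation.  The decoder upsamples
with learnable deconvolutions, fuses stride-4 low-level features through
a skip connection, and a 1x1 pixel classifier produces per-pixel class
probabilities at input resolution.

Training is pixel-wise cross-entropy under SGD with momentum 0.9, weight
decay, the poly learning-rate schedule and flip/scale augmentation.  Two
configuration scales are provided: the full-resolution configuration
(depth-101 backbone, 704x1216 inputs, 50k iterations) mirroring a
production setup, and a desk-scale configuration (depth-18-style,
96x160, a few hundred iterations) that trains in minutes on one CPU.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .data_io import DatasetManifest, load_image, load_mask
from .metrics import SegMetrics, evaluate_masks
from .nn import Tensor

log = logging.getLogger(__name__)

_BLOCKS_PER_DEPTH = {18: (2, 2, 2, 2), 50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}


@dataclass
class SegConfig:
    backbone_depth: int = 101
    stem: str = "deep_stem_D"            # classic | deep_stem_D
    downsample_avgpool: bool = True
    attention: str = "SE"                # none | SE | ECA | CBAM
    se_ratio: int = 16
    aspp_dilations: tuple[int, ...] = (12, 24, 36)
    output_stride: int = 16
    n_classes: int = 2
    aux_head: bool = False
    aux_weight: float = 0.4
    input_size: tuple[int, int] = (704, 1216)
    base_channels: int = 64
    eca_kernel: int = 3

    def __post_init__(self):
        if self.backbone_depth not in _BLOCKS_PER_DEPTH:
            raise ValueError(f"backbone_depth must be one of {sorted(_BLOCKS_PER_DEPTH)}")
        if self.stem not in ("classic", "deep_stem_D"):
            raise ValueError("stem must be 'classic' or 'deep_stem_D'")
        if self.attention not in ("none", "SE", "ECA", "CBAM"):
            raise ValueError("attention must be none|SE|ECA|CBAM")
        d = list(self.aspp_dilations)
        if any(x <= 0 for x in d) or d != sorted(set(d)):
            raise ValueError("aspp_dilations must be strictly increasing positive")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.se_ratio < 1:
            raise ValueError("se_ratio must be positive")


@dataclass
class TrainSchedule:
    batch_size: int = 8
    base_lr: float = 0.001
    lr_policy: str = "poly"
    poly_power: float = 0.9
    max_iters: int = 50_000
    weight_decay: float = 0.0005
    augment_hflip: bool = True
    augment_scale: bool = True
    scale_range: tuple[float, float] = (0.75, 1.25)
    momentum: float = 0.9
    seed: int = 0
    eval_every: int | None = None

    def __post_init__(self):
        if min(self.batch_size, self.base_lr, self.poly_power) <= 0:
            raise ValueError("batch_size, base_lr, poly_power must be positive")
        if self.max_iters < 0 or self.weight_decay < 0:
            raise ValueError("max_iters and weight_decay must be non-negative")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")


def desk_config(attention: str = "SE", n_classes: int = 2) -> SegConfig:
    """Reduced configuration that trains in minutes on one CPU."""
    return SegConfig(backbone_depth=18, base_channels=8, attention=attention,
                     aspp_dilations=(2, 4, 6), n_classes=n_classes,
                     input_size=(96, 160))


def desk_schedule(max_iters: int = 300, seed: int = 0) -> TrainSchedule:
    return TrainSchedule(batch_size=4, base_lr=0.03, max_iters=max_iters,
                         weight_decay=1e-4, scale_range=(0.8, 1.2), seed=seed)


def poly_lr(iteration: int, max_iters: int, base_lr: float, power: float = 0.9) -> float:
    """lr = base_lr * (1 - iter/max_iters)^power, clamped to 0 past the end."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if iteration > max_iters:
        warnings.warn("iteration beyond max_iters: learning rate clamped to 0")
        return 0.0
    return base_lr * (1.0 - iteration / max_iters) ** power


# ---------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------

class ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out, k, stride=1, padding=0, dilation=1, rng=None,
                 relu=True):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride, padding, dilation,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)
        self.relu = relu

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.relu else x


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity shortcut.

    When downsampling with the ResNet-D refinement, the shortcut applies
    2x2 stride-2 average pooling before its 1x1 convolution.
    """

    def __init__(self, c_in, c_out, stride=1, dilation=1, avg_down=True, rng=None):
        super().__init__()
        self.conv1 = ConvBNReLU(c_in, c_out, 3, stride, dilation, dilation, rng)
        self.conv2 = ConvBNReLU(c_out, c_out, 3, 1, dilation, dilation, rng, relu=False)
        self.stride = stride
        self.avg_down = avg_down
        if stride != 1 or c_in != c_out:
            self.short = ConvBNReLU(c_in, c_out, 1,
                                    1 if (avg_down and stride != 1) else stride,
                                    0, 1, rng, relu=False)
        else:
            self.short = None

    def forward(self, x):
        idt = x
        if self.short is not None:
            if self.avg_down and self.stride != 1:
                idt = nn.avg_pool2x2(idt)
            idt = self.short(idt)
        out = self.conv2(self.conv1(x)) + idt
        return out.relu()


class Bottleneck(nn.Module):
    """1x1 reduce, 3x3, 1x1 expand (x4), ResNet-D shortcut option."""

    expansion = 4

    def __init__(self, c_in, c_mid, stride=1, dilation=1, avg_down=True, rng=None):
        super().__init__()
        c_out = c_mid * self.expansion
        self.conv1 = ConvBNReLU(c_in, c_mid, 1, 1, 0, 1, rng)
        self.conv2 = ConvBNReLU(c_mid, c_mid, 3, stride, dilation, dilation, rng)
        self.conv3 = ConvBNReLU(c_mid, c_out, 1, 1, 0, 1, rng, relu=False)
        self.stride = stride
        self.avg_down = avg_down
        if stride != 1 or c_in != c_out:
            self.short = ConvBNReLU(c_in, c_out, 1,
                                    1 if (avg_down and stride != 1) else stride,
                                    0, 1, rng, relu=False)
        else:
            self.short = None

    def forward(self, x):
        idt = x
        if self.short is not None:
            if self.avg_down and self.stride != 1:
                idt = nn.avg_pool2x2(idt)
            idt = self.short(idt)
        out = self.conv3(self.conv2(self.conv1(x))) + idt
        return out.relu()


class Backbone(nn.Module):
    """ResNet/ResNet-D feature extractor.

    ``forward`` returns (low-level features at stride 4, high-level
    features at the configured output stride).
    """

    def __init__(self, config: SegConfig, rng: np.random.Generator):
        super().__init__()
        c = config.base_channels
        blocks = _BLOCKS_PER_DEPTH[config.backbone_depth]
        bottleneck = config.backbone_depth >= 50
        block_cls = Bottleneck if bottleneck else BasicBlock
        exp = block_cls.expansion if bottleneck else 1
        if config.stem == "deep_stem_D":
            mid = max(c // 2, 4)
            self.stem = nn.Sequential(
                ConvBNReLU(3, mid, 3, 2, 1, 1, rng),
                ConvBNReLU(mid, mid, 3, 1, 1, 1, rng),
                ConvBNReLU(mid, c, 3, 1, 1, 1, rng),
            )
        else:
            self.stem = nn.Sequential(ConvBNReLU(3, c, 7, 2, 3, 1, rng))
        widths = (c, 2 * c, 4 * c, 8 * c)
        if config.output_stride == 16:
            strides, dils = (1, 2, 2, 1), (1, 1, 1, 2)
        else:
            strides, dils = (1, 2, 1, 1), (1, 1, 2, 4)
        self.stages = []
        c_in = c
        for i, (n_blocks, width, s, d) in enumerate(zip(blocks, widths, strides, dils)):
            stage = []
            for b in range(n_blocks):
                stage.append(block_cls(c_in, width, s if b == 0 else 1, d,
                                       config.downsample_avgpool, rng))
                c_in = width * exp
            self.stages.append(nn.Sequential(*stage))
        self.low_channels = widths[0] * exp
        self.penultimate_channels = widths[2] * exp
        self.out_channels = widths[3] * exp

    def forward(self, x):
        x = self.stem(x)
        x = nn.max_pool2x2(x)
        low = self.stages[0](x)
        x = self.stages[1](low)
        pen = self.stages[2](x)
        high = self.stages[3](pen)
        return low, pen, high


# ---------------------------------------------------------------------
# attention modules
# ---------------------------------------------------------------------

class Identity(nn.Module):
    def forward(self, x):
        return x


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gating.

    Global average pool -> bottleneck MLP (reduction ``ratio``) -> sigmoid
    gates in (0, 1), applied per channel.
    """

    def __init__(self, channels: int, ratio: int = 16, rng=None):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.channels = channels

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))                      # (N, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1)


class ECABlock(nn.Module):
    """Efficient channel attention: 1-D convolution across the pooled
    channel descriptor, no dimensionality reduction."""

    def __init__(self, channels: int, kernel_size: int = 3, rng=None):
        super().__init__()
        if kernel_size % 2 == 0:
            kernel_size += 1
        self.conv = nn.Conv2d(1, 1, (1, kernel_size), padding=(0, kernel_size // 2),
                              bias=False, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3)).reshape(n, 1, 1, c)
        return self.conv(pooled).sigmoid().reshape(n, c)

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1)


class CBAMBlock(nn.Module):
    """Convolutional block attention: channel gate (shared MLP over avg-
    and max-pooled descriptors) followed by a 7x7-conv spatial gate."""

    def __init__(self, channels: int, ratio: int = 16, rng=None):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.spatial = nn.Conv2d(2, 1, 7, padding=3, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.reshape(n, c, -1).max(axis=2)
        gate_c = (self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())).sigmoid()
        x = x * gate_c.reshape(n, c, 1, 1)
        sp_avg = x.mean(axis=1, keepdims=True)
        sp_max = x.max(axis=1, keepdims=True)
        gate_s = self.spatial(nn.concat([sp_avg, sp_max], axis=1)).sigmoid()
        return x * gate_s


def make_attention(kind: str, channels: int, config: SegConfig, rng) -> nn.Module:
    if kind == "none":
        return Identity()
    if kind == "SE":
        return SEBlock(channels, config.se_ratio, rng)
    if kind == "ECA":
        return ECABlock(channels, config.eca_kernel, rng)
    if kind == "CBAM":
        return CBAMBlock(channels, config.se_ratio, rng)
    raise ValueError(kind)


# ---------------------------------------------------------------------
# ASPP with attention
# ---------------------------------------------------------------------

class ASPPAttn(nn.Module):
    """Atrous spatial pyramid pooling fused through channel attention.

    Branches: 1x1 conv, one 3x3 atrous conv per dilation rate, and a
    global image-pooling branch; concatenated, projected by 1x1 conv,
    then recalibrated by the configured attention block.  Dilations too
    large for the feature map are clamped (with a warning) at call time
    via construction-time ``max_dilation`` — rates are fixed per model,
    so the clamp happens when the module is built for a known input size.
    """

    def __init__(self, c_in: int, c_out: int, config: SegConfig,
                 feature_size: tuple[int, int], rng=None):
        super().__init__()
        dils = []
        limit = max(min(feature_size) - 1, 1)
        for d in config.aspp_dilations:
            if d > limit:
                warnings.warn(f"ASPP dilation {d} exceeds feature map "
                              f"{feature_size}; clamped to {limit}")
                d = limit
            dils.append(d)
        self.branch0 = ConvBNReLU(c_in, c_out, 1, 1, 0, 1, rng)
        self.branches = [ConvBNReLU(c_in, c_out, 3, 1, d, d, rng) for d in dils]
        self.image_pool_conv = ConvBNReLU(c_in, c_out, 1, 1, 0, 1, rng)
        n_branches = 2 + len(dils)
        self.project = ConvBNReLU(n_branches * c_out, c_out, 1, 1, 0, 1, rng)
        self.attention = make_attention(config.attention, c_out, config, rng)
        self.dilations = tuple(dils)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        outs = [self.branch0(x)]
        outs += [b(x) for b in self.branches]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        outs.append(nn.broadcast_hw(self.image_pool_conv(pooled), h, w))
        fused = self.project(nn.concat(outs, axis=1))
        return self.attention(fused)


class DeconvUp(nn.Module):
    """Learnable x2 deconvolution: zero-stuffed upsampling + 3x3 conv."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        self.conv = ConvBNReLU(c_in, c_out, 3, 1, 1, 1, rng)

    def forward(self, x):
        return self.conv(nn.upsample_zero(x, 2))


# ---------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------

class SegModel(nn.Module):
    def __init__(self, config: SegConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        self.backbone = Backbone(config, rng)
        c_high = self.backbone.out_channels
        aspp_ch = max(c_high // 4, 16)
        dec_ch = aspp_ch
        low_proj_ch = max(self.backbone.low_channels, 16)
        h, w = config.input_size
        os = config.output_stride
        feat = (max(h // os, 1), max(w // os, 1))
        self.aspp = ASPPAttn(c_high, aspp_ch, config, feat, rng)
        n_up = {16: 2, 8: 1}[os]
        ups = []
        c = aspp_ch
        for _ in range(n_up):
            ups.append(DeconvUp(c, dec_ch, rng))
            c = dec_ch
        self.ups = ups
        self.low_proj = ConvBNReLU(self.backbone.low_channels, low_proj_ch, 1, 1, 0, 1, rng)
        self.fuse = ConvBNReLU(dec_ch + low_proj_ch, dec_ch, 3, 1, 1, 1, rng)
        self.head = nn.Conv2d(dec_ch, config.n_classes, 1, rng=rng)
        # final x4 deconvolution: zero-stuffed upsampling + 7x7 conv smooths
        # the stride-4 logits back to input resolution with learnable weights
        self.head_up = nn.Conv2d(config.n_classes, config.n_classes, 7,
                                 padding=3, rng=rng)
        if config.aux_head:
            self.aux = nn.Conv2d(self.backbone.penultimate_channels,
                                 config.n_classes, 1, rng=rng)
        else:
            self.aux = None

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None]:
        """Input (N,3,H,W) normalized; returns logits (N,K,H,W) (+ aux)."""
        h, w = x.shape[2], x.shape[3]
        if h < self.config.output_stride or w < self.config.output_stride:
            raise ValueError(f"input {h}x{w} smaller than output stride")
        pad_h = (-h) % 16
        pad_w = (-w) % 16
        if pad_h or pad_w:
            data = np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
            x = Tensor(data)
        low, pen, high = self.backbone(x)
        y = self.aspp(high)
        for up in self.ups:
            y = up(y)
        y = nn.concat([y, self.low_proj(low)], axis=1)
        y = self.fuse(y)
        logits = self.head_up(nn.upsample_zero(self.head(y), 4))
        logits = logits[:, :, :h, :w]
        aux_logits = None
        if self.aux is not None:
            pen_stride = self.config.output_stride  # penultimate stage sits at the output stride
            aux_logits = nn.upsample_nearest(self.aux(pen), pen_stride)[:, :, :h, :w]
        return logits, aux_logits

    # ------------------------------------------------------------------
    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (H, W, n_classes) for one RGB image."""
        self.eval()
        x = Tensor(normalize_image(image)[None])
        logits, _ = self.forward(x)
        probs = nn.softmax_np(logits.data, axis=1)[0]
        return np.moveaxis(probs, 0, -1)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        return self.predict_probs(image).argmax(axis=-1).astype(np.uint8)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> CHW float32 in [-1, 1]."""
    arr = np.asarray(image, dtype=np.float32) / 127.5 - 1.0
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return np.moveaxis(arr, -1, 0)


def forward_segment(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel probability map for a raw image (rows, cols, n_classes)."""
    return model.predict_probs(image)


def build_backbone(config: SegConfig, rng: np.random.Generator | None = None) -> Backbone:
    return Backbone(config, rng or np.random.default_rng())


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(model: SegModel, path: str | Path) -> None:
    state = model.state_dict()
    cfg = asdict(model.config)
    np.savez_compressed(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> SegModel:
    with np.load(path) as data:
        cfg_raw = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_raw)
        for key in ("aspp_dilations", "input_size"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = SegModel(SegConfig(**cfg_dict), np.random.default_rng(0))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model


# ---------------------------------------------------------------------
# data handling for training
# ---------------------------------------------------------------------

def _load_pairs(manifest: DatasetManifest) -> list[tuple[np.ndarray, np.ndarray]]:
    root = Path(manifest.root)
    out = []
    for r in manifest.records:
        img = load_image(root / r.image_path)
        if r.mask_path is None:
            raise ValueError(f"record {r.id}/{r.view} has no mask")
        mask = load_mask(root / r.mask_path)
        out.append((img, mask))
    return out


def _augment(img, mask, schedule: TrainSchedule, rng, size):
    h, w = size
    if schedule.augment_hflip and rng.random() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if schedule.augment_scale:
        s = rng.uniform(*schedule.scale_range)
        nh, nw = max(16, round(img.shape[0] * s)), max(16, round(img.shape[1] * s))
        img = np.asarray(Image.fromarray(img).resize((nw, nh), Image.BILINEAR))
        mask = np.asarray(Image.fromarray(mask).resize((nw, nh), Image.NEAREST))
        # random crop / zero-pad back to the fixed input size
        if nh > h:
            top = rng.integers(0, nh - h + 1)
            img, mask = img[top:top + h], mask[top:top + h]
        if nw > w:
            left = rng.integers(0, nw - w + 1)
            img, mask = img[:, left:left + w], mask[:, left:left + w]
        if img.shape[0] < h or img.shape[1] < w:
            pi = np.zeros((h, w, 3), dtype=img.dtype)
            pm = np.zeros((h, w), dtype=mask.dtype)
            pi[:img.shape[0], :img.shape[1]] = img
            pm[:mask.shape[0], :mask.shape[1]] = mask
            img, mask = pi, pm
    return img, mask


def train_segmenter(train_manifest: DatasetManifest, val_manifest: DatasetManifest,
                    config: SegConfig, schedule: TrainSchedule,
                    log_every: int = 50) -> tuple[SegModel, dict]:
    """Train a segmentation model; returns (model, history).

    History records the loss at every logged iteration and validation
    mIoU at ``eval_every`` intervals plus at the end.  Runs are
    reproducible under ``schedule.seed``.
    """
    if len(train_manifest) < 1:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(schedule.seed)
    model = SegModel(config, np.random.default_rng(rng.integers(2 ** 31)))
    pairs = _load_pairs(train_manifest)
    for _, m in pairs:
        if m.max() >= config.n_classes:
            raise ValueError(f"mask label {int(m.max())} >= n_classes {config.n_classes}")
    val_pairs = _load_pairs(val_manifest) if len(val_manifest) else []
    opt = nn.SGD(model.parameters(), lr=schedule.base_lr,
                 momentum=schedule.momentum, weight_decay=schedule.weight_decay)
    history = {"iter": [], "loss": [], "lr": [], "val_iter": [], "val_miou": []}
    size = config.input_size
    eval_every = schedule.eval_every or max(1, schedule.max_iters // 4)
    model.train()
    for it in range(schedule.max_iters):
        idx = rng.integers(0, len(pairs), size=schedule.batch_size)
        imgs, masks = [], []
        for k in idx:
            img, mask = _augment(*pairs[k], schedule, rng, size)
            imgs.append(normalize_image(img))
            masks.append(mask.astype(np.int64))
        x = Tensor(np.stack(imgs))
        labels = np.stack(masks)
        logits, aux_logits = model.forward(x)
        loss = nn.softmax_cross_entropy(logits, labels)
        if aux_logits is not None:
            loss = loss + nn.softmax_cross_entropy(aux_logits, labels) * config.aux_weight
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"NaN/inf loss at iteration {it} (lr={opt.lr:.2e}); "
                f"diagnostic: batch indices {idx.tolist()}")
        opt.zero_grad()
        loss.backward()
        opt.lr = poly_lr(it, schedule.max_iters, schedule.base_lr, schedule.poly_power)
        opt.step()
        if it % log_every == 0 or it == schedule.max_iters - 1:
            history["iter"].append(it)
            history["loss"].append(float(loss.data))
            history["lr"].append(opt.lr)
            log.info("iter %d loss %.4f lr %.2e", it, float(loss.data), opt.lr)
        if val_pairs and ((it + 1) % eval_every == 0 or it == schedule.max_iters - 1):
            m = eval_segmenter(model, val_pairs, config.n_classes)
            history["val_iter"].append(it + 1)
            history["val_miou"].append(m.miou)
            log.info("iter %d val mIoU %.4f", it + 1, m.miou)
            model.train()
    return model, history


def eval_segmenter(model: SegModel, data, n_classes: int,
                   per_image: bool = False) -> SegMetrics:
    """Evaluate on (image, mask) pairs or a manifest; includes FPS timing."""
    if isinstance(data, DatasetManifest):
        data = _load_pairs(data)
    model.eval()
    preds, truths, times = [], [], []
    for img, mask in data:
        t0 = time.perf_counter()
        preds.append(model.predict_mask(img))
        times.append(time.perf_counter() - t0)
        truths.append(mask)
    return evaluate_masks(preds, truths, n_classes, frame_times=times,
                          per_image=per_image)


def ablation_harness(train_manifest: DatasetManifest, val_manifest: DatasetManifest,
                     variants: dict[str, SegConfig], schedule: TrainSchedule,
                     view: str = "") -> dict[str, SegMetrics]:
    """Train each configured variant and evaluate it on the validation split."""
    out = {}
    for name, cfg in variants.items():
        log.info("ablation variant %s%s", name, f" ({view})" if view else "")
        model, _ = train_segmenter(train_manifest, val_manifest, cfg, schedule)
        out[name] = eval_segmenter(model, val_manifest, cfg.n_classes)
    return out
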