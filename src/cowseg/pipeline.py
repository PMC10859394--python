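"""End-to-end orchestration: synthetic herd -> split -> segmentation ->
feature extraction -> weight-model comparison -> report.

Every stage writes its outputs under a run directory together with the
exact configuration snapshot (and its hash), and every source of
randomness derives from the single configured seed, so a rerun
reproduces manifests, feature tables and metric tables bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import DatasetManifest, ImageSample, load_image, load_mask, split_dataset
from .metrics import SegMetrics, regression_table, seg_table
from .morphometry import assemble_features, features_to_frame
from .seg_model import (
    SegConfig,
    TrainSchedule,
    ablation_harness,
    eval_segmenter,
    save_checkpoint,
    train_segmenter,
)
from .synthetic_scenes import SceneParams, generate_dataset
from .weight_regression import DEFAULT_MODELS, compare_models

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "runs/desk"
    seed: int = 0
    n_per_view: int = 40
    scene: SceneParams = field(default_factory=lambda: SceneParams(image_size=(96, 160)))
    seg: SegConfig = field(default_factory=lambda: SegConfig(
        backbone_depth=18, base_channels=8, attention="SE",
        aspp_dilations=(2, 4, 6), input_size=(96, 160)))
    schedule: TrainSchedule = field(default_factory=lambda: TrainSchedule(
        batch_size=4, base_lr=0.03, max_iters=300, weight_decay=1e-4,
        scale_range=(0.8, 1.2)))
    split_ratio: tuple[float, float] = (0.8, 0.2)
    ablation_attention: tuple[str, ...] = ()   # extra attention variants for the seg table
    use_truth_masks: bool = False
    skip_seg: bool = False
    scaler_mode: str = "minmax_pm1"
    regressors: tuple[str, ...] = DEFAULT_MODELS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kwargs = dict(doc)
        if "scene" in kwargs:
            sc = dict(kwargs["scene"])
            for k in ("age_range", "top_area_range", "back_area_range", "image_size"):
                if k in sc:
                    sc[k] = tuple(sc[k])
            kwargs["scene"] = SceneParams(**sc)
        if "seg" in kwargs:
            sg = dict(kwargs["seg"])
            for k in ("aspp_dilations", "input_size"):
                if k in sg:
                    sg[k] = tuple(sg[k])
            kwargs["seg"] = SegConfig(**sg)
        if "schedule" in kwargs:
            sch = dict(kwargs["schedule"])
            if "scale_range" in sch:
                sch["scale_range"] = tuple(sch["scale_range"])
            kwargs["schedule"] = TrainSchedule(**sch)
        for k in ("split_ratio", "ablation_attention", "regressors"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def snapshot(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.snapshot().encode()).hexdigest()[:16]


def _sub_manifest(man: DatasetManifest, view: str, tag: str) -> DatasetManifest:
    return DatasetManifest(man.by_view(view), split_tag=tag, root=man.root)


def _sample_from_record(rec, root: Path, mask: np.ndarray | None) -> ImageSample:
    meta = dict(rec.meta)
    meta["id"] = rec.id
    if mask is None:
        mask = load_mask(root / rec.mask_path)
    return ImageSample(image=load_image(root / rec.image_path), view=rec.view,
                       mask=mask, meta=meta)


def run_end_to_end(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config_snapshot.json").write_text(config.snapshot())
    (run_dir / "config_hash.txt").write_text(config.hash())
    stage = "synth"
    try:
        scene = dataclasses.replace(config.scene, seed=config.seed)
        data_dir = run_dir / "data"
        manifest = generate_dataset(scene, config.n_per_view, data_dir)
        log.info("stage synth: %d records in %s", len(manifest), data_dir)

        stage = "split"
        train_man, test_man = split_dataset(manifest, config.split_ratio, config.seed)
        train_man.save(run_dir / "manifest_train.json")
        test_man.save(run_dir / "manifest_test.json")

        models = {}
        seg_rows: dict[str, dict[str, SegMetrics]] = {}
        if not config.skip_seg:
            stage = "train-seg"
            schedule = dataclasses.replace(config.schedule, seed=config.seed)
            variants = [config.seg.attention] + [a for a in config.ablation_attention
                                                 if a != config.seg.attention]
            for view in ("top", "back"):
                tr = _sub_manifest(train_man, view, "train")
                te = _sub_manifest(test_man, view, "test")
                for attn in variants:
                    cfg = dataclasses.replace(config.seg, attention=attn)
                    model, history = train_segmenter(tr, te, cfg, schedule)
                    key = f"attention={attn}"
                    m = eval_segmenter(model, te, cfg.n_classes)
                    seg_rows.setdefault(key, {})[view] = m
                    if attn == config.seg.attention:
                        models[view] = model
                        save_checkpoint(model, run_dir / f"seg_{view}.npz")
                        pd.DataFrame({"iter": history["iter"],
                                      "loss": history["loss"],
                                      "lr": history["lr"]}).to_csv(
                            run_dir / f"history_{view}.csv", index=False)
                        pd.DataFrame({"iter": history["val_iter"],
                                      "val_miou": history["val_miou"]}).to_csv(
                            run_dir / f"val_history_{view}.csv", index=False)
            stage = "eval-seg"
            table = seg_table(seg_rows, {0: "background", 1: "cow"})
            # wall-clock columns go to a separate file: the metric table
            # itself must be bit-identical across same-seed reruns
            timing_cols = [c for c in table.columns if c.startswith("FPS") or c == "aFPS"]
            table[["variant"] + timing_cols].to_csv(
                run_dir / "seg_timings.csv", index=False, float_format="%.3f")
            table.drop(columns=timing_cols).to_csv(
                run_dir / "seg_metrics.csv", index=False, float_format="%.6f")

        stage = "extract-features"
        root = Path(manifest.root)
        by_animal: dict[str, dict[str, object]] = {}
        for rec in manifest.records:
            by_animal.setdefault(rec.id, {})[rec.view] = rec
        feats = []
        for animal_id in sorted(by_animal):
            views = by_animal[animal_id]
            if "top" not in views or "back" not in views:
                continue
            samples = {}
            for view, rec in views.items():
                if config.use_truth_masks or config.skip_seg:
                    mask = None  # ground truth from disk
                else:
                    mask = models[view].predict_mask(load_image(root / rec.image_path))
                samples[view] = _sample_from_record(rec, root, mask)
            feats.append(assemble_features(
                samples["top"], samples["back"],
                clean_predicted=not (config.use_truth_masks or config.skip_seg)))
        feat_df = features_to_frame(feats)
        feat_df.to_csv(run_dir / "features.csv", index=False, float_format="%.8g")

        stage = "compare-models"
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(feat_df))
        n_train = round(len(feat_df) * config.split_ratio[0]
                        / sum(config.split_ratio))
        feat_train = feat_df.iloc[np.sort(order[:n_train])]
        feat_test = feat_df.iloc[np.sort(order[n_train:])]
        feat_train.to_csv(run_dir / "features_train.csv", index=False, float_format="%.8g")
        feat_test.to_csv(run_dir / "features_test.csv", index=False, float_format="%.8g")
        reg_table, scatter = compare_models(feat_train, feat_test,
                                            config.regressors, config.seed)
        reg_table.to_csv(run_dir / "regression_metrics.csv", index=False,
                         float_format="%.6f")
        np.savez(run_dir / "scatter.npz",
                 **{f"{m}_{k}": v for m, d in scatter.items() for k, v in d.items()})

        stage = "report"
        report(run_dir)
        return run_dir
    except Exception:
        log.exception("pipeline halted at stage %r (partial state kept in %s)",
                      stage, run_dir)
        (run_dir / "FAILED_STAGE.txt").write_text(stage)
        raise


def report(run_dir: str | Path) -> Path:
    """Render a Markdown summary of a run: metric tables, training curves
    and predicted-vs-actual scatter plots.  Missing artifacts are listed
    but do not prevent rendering."""
    run_dir = Path(run_dir)
    missing: list[str] = []
    lines = ["# Pipeline run report", ""]
    hash_file = run_dir / "config_hash.txt"
    if hash_file.exists():
        lines += [f"Config snapshot hash: `{hash_file.read_text().strip()}`", ""]
    else:
        missing.append("config_hash.txt")

    seg_csv = run_dir / "seg_metrics.csv"
    lines += ["## Segmentation (per-variant IoU / Accuracy / FPS per view)", ""]
    if seg_csv.exists():
        lines += [pd.read_csv(seg_csv).to_markdown(index=False), ""]
    else:
        missing.append("seg_metrics.csv")
        lines += ["_segmentation block unavailable_", ""]

    reg_csv = run_dir / "regression_metrics.csv"
    lines += ["## Weight regression (R2 / RMSE / MSE / MAE, pounds)", ""]
    if reg_csv.exists():
        df = pd.read_csv(reg_csv)
        if (df["split"] == "test").sum() == 0 or df[df.split == "test"]["n"].max() == 0:
            lines += ["_test split empty: test block unavailable_", ""]
        lines += [df.to_markdown(index=False), ""]
    else:
        missing.append("regression_metrics.csv")
        lines += ["_regression block unavailable_", ""]

    # plots are best-effort
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for view in ("top", "back"):
            hist = run_dir / f"history_{view}.csv"
            if hist.exists():
                df = pd.read_csv(hist)
                fig, ax = plt.subplots(figsize=(5, 3))
                ax.plot(df["iter"], df["loss"])
                ax.set_xlabel("iteration"); ax.set_ylabel("loss")
                ax.set_title(f"training loss ({view})")
                fig.tight_layout()
                fig.savefig(run_dir / f"loss_{view}.png", dpi=100)
                plt.close(fig)
                lines += [f"![training loss {view}](loss_{view}.png)", ""]
        scatter_file = run_dir / "scatter.npz"
        if scatter_file.exists():
            with np.load(scatter_file) as data:
                tags = sorted({k.rsplit("_y_test", 1)[0] for k in data.files
                               if k.endswith("_y_test")})
                if tags:
                    fig, axes = plt.subplots(1, len(tags), figsize=(3 * len(tags), 3))
                    axes = np.atleast_1d(axes)
                    for ax, tag in zip(axes, tags):
                        y = data[f"{tag}_y_test"]; yh = data[f"{tag}_yhat_test"]
                        ax.scatter(y, yh, s=8)
                        lim = [min(y.min(), yh.min()), max(y.max(), yh.max())]
                        ax.plot(lim, lim, "k-", lw=1)
                        ax.set_title(tag); ax.set_xlabel("actual (lb)")
                    axes[0].set_ylabel("predicted (lb)")
                    fig.tight_layout()
                    fig.savefig(run_dir / "scatter_test.png", dpi=100)
                    plt.close(fig)
                    lines += ["![predicted vs actual](scatter_test.png)", ""]
    except Exception as e:  # plotting failure must not kill the report
        lines += [f"_plots unavailable: {e}_", ""]

    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {m}" for m in missing]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
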