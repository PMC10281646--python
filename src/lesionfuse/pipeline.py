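"""End-to-end orchestration of the four experiment arms.

A single config drives: augmentation/balancing, per-backbone
fine-tuning and GAP feature extraction, serial fusion of the two
feature streams, butterfly-optimization feature selection on the fused
matrix, and cross-validated evaluation of four arms — each single
backbone alone, the fused features, and the fused-plus-selected
features.  Every stage artifact, the resolved config and all seeds are
written into the run directory so a rerun with the same config is
bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augment import AugmentationPlan, augment_dataset
from .backbones import (
    FineTuneConfig,
    build_backbone,
    build_finetune_head,
    extract_features,
    fine_tune,
)
from .boa import BOAConfig, run_boa
from .errors import ConfigurationError
from .evaluate import DEFAULT_ROSTER, ClassifierSpec, benchmark
from .fusion import serial_fuse
from .synthetic import LabeledImageSet, load_image_set, make_image_set

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; every stage seed derives from ``seed``."""

    workdir: str
    input_dir: str | None = None
    synthetic: dict | None = None          # {n_classes, per_class, size}
    target_per_class: int = 0              # 0 = keep class sizes (no balancing)
    backbones: tuple[str, str] = ("xception", "shufflenet")
    tinycnn_gap_width: int = 8
    epochs: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 16
    boa: dict = field(default_factory=dict)
    roster: tuple[str, ...] = tuple(s.name for s in DEFAULT_ROSTER)
    k_folds: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of input_dir / synthetic must be given"
            )
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ConfigurationError(f"input_dir {self.input_dir!r} not found")
        if len(self.backbones) != 2:
            raise ConfigurationError("exactly two backbones are fused")


def _load_images(cfg: PipelineConfig) -> LabeledImageSet:
    if cfg.input_dir is not None:
        return load_image_set(cfg.input_dir)
    s = dict(cfg.synthetic)
    return make_image_set(
        int(s.get("n_classes", 2)),
        int(s.get("per_class", 30)),
        int(s.get("size", 32)),
        cfg.seed,
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with the failing stage named; artifacts
    written before the failure are retained for debugging.
    """
    cfg.validate()
    run_dir = Path(cfg.workdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        ds = _load_images(cfg)
        manifest["stages"]["load"] = {
            "n_images": len(ds),
            "n_classes": ds.n_classes,
            "seconds": time.perf_counter() - t0,
        }

        stage = "augment"
        t0 = time.perf_counter()
        if cfg.target_per_class > 0:
            plan = AugmentationPlan(
                target_per_class=cfg.target_per_class, seed=cfg.seed
            )
            ds = augment_dataset(ds, plan)
        manifest["stages"]["augment"] = {
            "n_images": len(ds),
            "class_sizes": ds.class_sizes(),
            "seconds": time.perf_counter() - t0,
        }

        stage = "extract"
        t0 = time.perf_counter()
        feats = []
        for i, name in enumerate(cfg.backbones):
            kw = {"gap_width": cfg.tinycnn_gap_width} if name == "tinycnn" else {}
            model, spec = build_backbone(name, seed=cfg.seed + 100 + i, **kw)
            model = build_finetune_head(model, spec, ds.n_classes, seed=cfg.seed + i)
            ft_cfg = FineTuneConfig(
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                seed=cfg.seed,
            )
            model, split = fine_tune(model, ds, ft_cfg)
            fm = extract_features(model, ds, spec)
            fm.to_csv(run_dir / f"features_{i}_{name}.csv")
            feats.append(fm)
            manifest["stages"].setdefault("extract", {})[f"{i}_{name}"] = {
                "width": fm.width,
                "train_size": int(len(split.train_idx)),
                "test_size": int(len(split.test_idx)),
            }
        manifest["stages"]["extract"]["seconds"] = time.perf_counter() - t0

        stage = "fuse"
        fused = serial_fuse(feats[0], feats[1])
        fused.to_csv(run_dir / "features_fused.csv")
        manifest["stages"]["fuse"] = {"width": fused.width}

        stage = "select"
        t0 = time.perf_counter()
        boa_cfg = BOAConfig(seed=cfg.seed, **cfg.boa)
        sel = run_boa(fused, None, boa_cfg)
        (run_dir / "mask.json").write_text(
            json.dumps(
                {
                    "mask": sel.mask.astype(int).tolist(),
                    "selected_indices": sel.selected_indices,
                    "best_cost": sel.best_cost,
                    "best_cost_per_iter": sel.best_cost_per_iter.tolist(),
                    "config": asdict(sel.config_echo),
                }
            )
        )
        manifest["stages"]["select"] = {
            "selected": int(sel.mask.sum()),
            "total": int(fused.width),
            "best_cost": sel.best_cost,
            "seconds": time.perf_counter() - t0,
        }

        stage = "evaluate"
        t0 = time.perf_counter()
        roster = [ClassifierSpec(n) for n in cfg.roster]
        arms = {
            "fv1": (feats[0].values, feats[0].labels),
            "fv2": (feats[1].values, feats[1].labels),
            "fused": (fused.values, fused.labels),
            "fused_boa": (fused.values[:, sel.mask], fused.labels),
        }
        for arm, (x, y) in arms.items():
            report = benchmark(x, y, roster, k=cfg.k_folds, seed=cfg.seed)
            (run_dir / f"report_{arm}.tsv").write_text(report.to_tsv())
            np.savetxt(
                run_dir / f"confusion_{arm}_{roster[0].name}.csv",
                report.confusions[roster[0].name],
                fmt="%d",
                delimiter=",",
            )
        manifest["stages"]["evaluate"] = {"seconds": time.perf_counter() - t0}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir
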