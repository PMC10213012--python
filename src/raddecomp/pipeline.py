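"""Experiment configuration and the staged end-to-end pipeline.

A single YAML config drives five stages — generate, project, train,
decompose, evaluate — each writing its artifacts plus a stage manifest
holding the hash of the config section and input artifacts it consumed.
Re-running with an unchanged config skips completed stages; a changed
config refuses to overwrite silently; a missing upstream artifact raises
an error naming the prerequisite stage.  One global seed fans out to
per-stage seeds through a fixed counter so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .losses import LossWeights
from .phantom import (
    DatasetManifest,
    NoiseConfig,
    PhantomSpec,
    build_dataset,
    generate_phantom,
)
from .projection import ProjectionGeometry, normalize
from .training import TrainingConfig, TrainState, decompose, train

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "MissingPrerequisiteError", "run_pipeline",
           "STAGES"]

STAGES = ("generate", "project", "train", "decompose", "evaluate")

_STAGE_SEED_OFFSETS = {name: 101 * (i + 1) for i, name in enumerate(STAGES)}


class MissingPrerequisiteError(RuntimeError):
    """An earlier pipeline stage's artifacts are required but absent."""


@dataclass
class ExperimentConfig:
    """Full description of one experiment run (YAML-serializable)."""

    seed: int = 0
    output_root: str = "runs/experiment"
    n_cases: int = 12
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    asymmetry_factors: list[float] = field(
        default_factory=lambda: [0.7, 0.8, 0.9, 1.0]
    )
    geometry: dict | None = None
    noise: dict = field(default_factory=lambda: {"i0": 1e4, "enabled": True})
    pose: dict = field(
        default_factory=lambda: {"rotation_deg": 5.0, "translation_mm": 6.0}
    )
    splits: dict = field(
        default_factory=lambda: {"train": 0.5, "val": 0.25, "test": 0.25}
    )
    training: dict = field(default_factory=lambda: {"variant": "proposed2"})
    evaluation: dict = field(default_factory=lambda: {"sweep_points": 41})
    save_volumes: bool = True

    # ------------------------------------------------------------- plumbing
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_root": self.output_root,
            "n_cases": self.n_cases,
            "phantom": self.phantom,
            "asymmetry_factors": self.asymmetry_factors,
            "geometry": self.geometry,
            "noise": self.noise,
            "pose": self.pose,
            "splits": self.splits,
            "training": self.training,
            "evaluation": self.evaluation,
            "save_volumes": self.save_volumes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    def phantom_specs(self) -> list[PhantomSpec]:
        base = dict(self.phantom)
        specs = []
        for i in range(self.n_cases):
            f = self.asymmetry_factors[i % len(self.asymmetry_factors)]
            specs.append(
                PhantomSpec(
                    **{**base,
                       "asymmetry_factor": f,
                       "seed": self.stage_seed("generate") + i}
                )
            )
        return specs

    def training_config(self, n_channels: int, image_size: int,
                        log_path=None) -> TrainingConfig:
        kwargs = dict(self.training)
        weights = kwargs.pop("weights", None)
        return TrainingConfig(
            n_channels=n_channels,
            image_size=image_size,
            seed=self.stage_seed("train"),
            weights=LossWeights(**weights) if weights else LossWeights(),
            log_path=str(log_path) if log_path else None,
            **kwargs,
        )


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()
    ).hexdigest()[:16]


def _stage_dir(config: ExperimentConfig, stage: str) -> Path:
    return Path(config.output_root) / stage


def _stamp_path(config: ExperimentConfig, stage: str) -> Path:
    return _stage_dir(config, stage) / "stage.json"


def _stage_hash(config: ExperimentConfig, stage: str) -> str:
    d = config.to_dict()
    relevant = {
        "generate": ["seed", "n_cases", "phantom", "asymmetry_factors"],
        "project": ["seed", "n_cases", "phantom", "asymmetry_factors",
                    "geometry", "noise", "pose", "splits"],
        "train": ["seed", "n_cases", "phantom", "asymmetry_factors",
                  "geometry", "noise", "pose", "splits", "training"],
        "decompose": ["seed", "n_cases", "phantom", "asymmetry_factors",
                      "geometry", "noise", "pose", "splits", "training"],
        "evaluate": ["seed", "n_cases", "phantom", "asymmetry_factors",
                     "geometry", "noise", "pose", "splits", "training",
                     "evaluation"],
    }[stage]
    return _hash({k: d[k] for k in relevant})


def _check_stamp(config: ExperimentConfig, stage: str) -> str | None:
    """Returns 'skip' if the stage is already done with matching hashes,
    None if it must run; raises on a hash mismatch."""
    path = _stamp_path(config, stage)
    if not path.exists():
        return None
    stamp = json.loads(path.read_text())
    if stamp["config_hash"] != _stage_hash(config, stage):
        raise RuntimeError(
            f"stage {stage!r}: existing outputs were produced by a different "
            "configuration; refusing to overwrite (delete the stage "
            "directory to rerun)"
        )
    return "skip"

def _write_stamp(config: ExperimentConfig, stage: str, extra: dict) -> None:
    _stamp_path(config, stage).write_text(json.dumps(
        {"config_hash": _stage_hash(config, stage), **extra}, indent=1
    ))


def _require(config: ExperimentConfig, stage: str, needed_by: str) -> None:
    if not _stamp_path(config, stage).exists():
        raise MissingPrerequisiteError(
            f"stage {needed_by!r} requires the {stage!r} stage's artifacts; "
            f"run stage {stage!r} first"
        )


def _run_generate(config: ExperimentConfig) -> None:
    out = _stage_dir(config, "generate")
    out.mkdir(parents=True, exist_ok=True)
    specs = config.phantom_specs()
    if config.save_volumes:
        import nibabel as nib

        for i, spec in enumerate(specs):
            ph = generate_phantom(spec)
            affine = np.diag(list(ph.spacing) + [1.0])
            label_map = np.zeros(ph.hu_volume.shape, dtype=np.int16)
            for li, m in enumerate(ph.masks):
                label_map[m] = li + 1
            nib.save(nib.Nifti1Image(ph.hu_volume.astype(np.float32), affine),
                     out / f"case_{i:03d}_hu.nii.gz")
            nib.save(nib.Nifti1Image(label_map, affine),
                     out / f"case_{i:03d}_labels.nii.gz")
            lut = {li + 1: {"name": l.name, "group": l.group, "side": l.side}
                   for li, l in enumerate(ph.labels)}
            (out / f"case_{i:03d}_labels.json").write_text(
                json.dumps(lut, indent=1))
    _write_stamp(config, "generate", {"n_cases": len(specs)})


def _run_project(config: ExperimentConfig) -> DatasetManifest:
    out = _stage_dir(config, "project")
    out.mkdir(parents=True, exist_ok=True)
    geometry = (ProjectionGeometry.from_dict(config.geometry)
                if config.geometry else None)
    noise = NoiseConfig(**config.noise)
    manifest = build_dataset(
        config.phantom_specs(),
        out,
        geometry=geometry,
        noise=noise,
        splits=config.splits,
        seed=config.stage_seed("project"),
        pose_rotation_deg=config.pose["rotation_deg"],
        pose_translation_mm=config.pose["translation_mm"],
    )
    _write_stamp(config, "project", {"manifest": "manifest.json"})
    return manifest


def _run_train(config: ExperimentConfig) -> TrainState:
    _require(config, "project", "train")
    out = _stage_dir(config, "train")
    out.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest.load(
        _stage_dir(config, "project") / "manifest.json")
    sample = manifest.load_drrs(manifest.split("train")[0])
    tcfg = config.training_config(
        n_channels=sample.shape[0], image_size=sample.shape[1],
        log_path=out / "losses.jsonl",
    )
    state = train(manifest, tcfg)
    state.save(out / "final_state.npz")
    _write_stamp(config, "train", {"state": "final_state.npz",
                                   "epochs": tcfg.epochs})
    return state


def _run_decompose(config: ExperimentConfig) -> None:
    import tifffile

    _require(config, "project", "decompose")
    _require(config, "train", "decompose")
    out = _stage_dir(config, "decompose")
    out.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest.load(
        _stage_dir(config, "project") / "manifest.json")
    state = TrainState.load(_stage_dir(config, "train") / "final_state.npz")
    for case in manifest.split("test"):
        rad = normalize(manifest.load_radiograph(case),
                        manifest.normalization)
        dec = decompose(rad, state)
        tifffile.imwrite(out / f"{case.case_id}.tif",
                         dec.channels.astype(np.float32),
                         photometric="minisblack")
    _write_stamp(config, "decompose", {"split": "test"})


def _run_evaluate(config: ExperimentConfig) -> None:
    import tifffile

    from .evaluation import evaluate, plot_volume_ratios
    from .projection import DecomposedSet

    _require(config, "project", "evaluate")
    _require(config, "decompose", "evaluate")
    out = _stage_dir(config, "evaluate")
    out.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest.load(
        _stage_dir(config, "project") / "manifest.json")
    dec_dir = _stage_dir(config, "decompose")
    decs = {}
    for case in manifest.split("test"):
        path = dec_dir / f"{case.case_id}.tif"
        if not path.exists():
            raise MissingPrerequisiteError(
                f"stage 'evaluate': missing decomposition for {case.case_id}")
        channels = tifffile.imread(path).astype(np.float64)
        decs[case.case_id] = DecomposedSet(
            channels=channels,
            labels=[l.name for l in case.labels],
            raw_or_normalized="normalized",
            normalization=manifest.normalization,
        )
    report = evaluate(manifest, decs,
                      sweep_points=config.evaluation.get("sweep_points", 41))
    report.variant = config.training.get("variant", "")
    report.save(out)
    if not report.volume_ratios.empty:
        plot_volume_ratios(report, out / "volume_ratios.png")
    _write_stamp(config, "evaluate", {"report": "summary.json"})


def run_pipeline(config: ExperimentConfig, stages=STAGES) -> None:
    """Execute the requested stages in canonical order.

    Completed stages (matching stamp) are skipped; artifacts from a
    different configuration raise instead of being overwritten.
    """
    chosen = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    Path(config.output_root).mkdir(parents=True, exist_ok=True)
    config.save(Path(config.output_root) / "config.yaml")
    runners = {
        "generate": _run_generate,
        "project": _run_project,
        "train": _run_train,
        "decompose": _run_decompose,
        "evaluate": _run_evaluate,
    }
    for stage in chosen:
        if _check_stamp(config, stage) == "skip":
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        runners[stage](config)
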