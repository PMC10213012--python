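"""Scaled-down ablation benchmark.

Runs the ablation variants end to end (phantom dataset, unpaired
training, decomposition of held-out radiographs, Dice scoring) at a toy
scale chosen so the whole comparison runs on one CPU in minutes: 32
cases (24 train / 8 test) of 32^3 phantoms with 1 bone + 2 muscles
(K+1 = 4 channels), 32 x 32 images, base width 8, 3 residual blocks, 20
epochs per stage, with the discriminator depth shifted down one stride-2
layer for both variant families (see ``TrainingConfig.disc_s2_delta``).

The comparison is directional: the expected outcome is that the proposed
features do not hurt — mean held-out Dice of the reconstruction-GC +
hierarchical variant at least matching the plain baseline — not the
absolute scores, which at this scale are far below a full-scale run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .evaluation import evaluate
from .phantom import PhantomSpec, build_dataset
from .projection import normalize
from .training import TrainingConfig, decompose, train

logger = logging.getLogger(__name__)

__all__ = ["toy_dataset", "run_toy_ablation", "TOY_VARIANTS"]

TOY_VARIANTS = ("conventional1", "proposed1", "proposed2")


def toy_dataset(out_dir, seed: int, n_cases: int = 32):
    """Build the toy benchmark dataset (24 train / 8 test by default)."""
    factors = [0.7, 0.8, 0.9, 1.0]
    specs = [
        PhantomSpec(
            grid_shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0),
            n_bones=1, n_muscles=2,
            asymmetry_factor=factors[i % len(factors)],
            seed=seed * 1000 + i,
        )
        for i in range(n_cases)
    ]
    return build_dataset(
        specs, out_dir, splits={"train": 0.75, "test": 0.25}, seed=seed,
        pose_rotation_deg=5.0, pose_translation_mm=6.0,
    )


def toy_training_config(variant: str, seed: int, epochs: int = 20) -> TrainingConfig:
    return TrainingConfig(
        variant=variant, n_channels=4, image_size=32, epochs=epochs,
        base_width=8, disc_base_width=8, residual_blocks=3,
        disc_s2_delta=1, seed=seed,
    )


def _held_out_dice(manifest, state) -> float:
    decs = {}
    for case in manifest.split("test"):
        rad = normalize(manifest.load_radiograph(case), manifest.normalization)
        decs[case.case_id] = decompose(rad, state)
    report = evaluate(manifest, decs)
    fg = report.per_structure.dropna(subset=["dice"])
    return float(fg["dice"].mean())


def run_toy_ablation(
    work_dir,
    seeds=(0, 1, 2),
    variants=TOY_VARIANTS,
    epochs: int = 20,
    n_cases: int = 32,
) -> dict[int, dict[str, float]]:
    """Train each variant on each seed; return held-out mean Dice.

    Result maps seed -> {variant: mean foreground Dice on the test split}.
    """
    work = Path(work_dir)
    results: dict[int, dict[str, float]] = {}
    for seed in seeds:
        manifest = toy_dataset(work / f"seed{seed}", seed=seed,
                               n_cases=n_cases)
        results[seed] = {}
        for variant in variants:
            cfg = toy_training_config(variant, seed=seed, epochs=epochs)
            state = train(manifest, cfg)
            score = _held_out_dice(manifest, state)
            results[seed][variant] = score
            logger.info("seed %d %s: held-out mean Dice %.4f",
                        seed, variant, score)
    return results


def ordering_holds(scores: dict[str, float], tol: float = 0.0) -> bool:
    """proposed2 >= proposed1 >= conventional1 (within a tolerance)."""
    return (
        scores["proposed2"] >= scores["proposed1"] - tol
        and scores["proposed1"] >= scores["conventional1"] - tol
    )
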