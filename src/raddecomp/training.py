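"""Unpaired mini-max training of the decomposition framework.

Four ablation variants are supported (two baselines, two proposed):

========================  ==========  =========  ==========  ==========
variant                   local       recon l2   recon GC    generator /
                          enhancer                           disc layers
========================  ==========  =========  ==========  ==========
conventional1             no          no         no          3 / 4
conventional2             no          yes (0.5)  no          3 / 4
proposed1                 yes         no         no          2 / 3
proposed2                 yes         no         yes (1.0)   2 / 3
========================  ==========  =========  ==========  ==========

Training alternates discriminator ascent and generator descent on the
total objective with Adam (betas 0.5/0.999), a constant learning rate for
the first half of the epochs and a linear decay to zero over the second
half, batch size 1 and a 50-image history pool feeding the discriminators.
Hierarchical variants run a global low-resolution stage for the full
schedule, then a local high-resolution stage (fresh discriminators) in
which the global generator is frozen for the first 10% of epochs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, avgpool2x
from .losses import (
    LossWeights,
    VARIANTS,
    adversarial_loss,
    cycle_loss,
    reconstruction_gc_loss,
    reconstruction_l2_loss,
    total_loss,
)
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    HierarchicalGenerator,
    PatchDiscriminator,
    ResnetGenerator,
    build_discriminator,
    build_generator,
    build_hierarchical_generator,
)
from .nn import Adam
from .phantom import DatasetManifest
from .projection import DecomposedSet, Radiograph, normalize

logger = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "TrainState", "lr_at_epoch", "train", "decompose"]

#: Table of per-variant architecture sizes (downsample layers in the
#: generator, stride-2 layers in the discriminator).
VARIANT_LAYERS = {
    "conventional1": {"gen_down": 3, "disc_s2": 4},
    "conventional2": {"gen_down": 3, "disc_s2": 4},
    "proposed1": {"gen_down": 2, "disc_s2": 3},
    "proposed2": {"gen_down": 2, "disc_s2": 3},
}


@dataclass(frozen=True)
class TrainingConfig:
    variant: str
    n_channels: int  # K+1
    image_size: int = 512
    epochs: int = 200
    lr0: float = 2e-4
    batch_size: int = 1
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    image_pool_size: int = 50
    base_width: int = 64
    disc_base_width: int = 64
    residual_blocks: int = 9
    enhancer_blocks: int = 3
    freeze_frac: float = 0.1
    #: subtracted from both variants' discriminator stride-2 layer counts
    #: for scaled-down profiles (keeps the conventional-vs-proposed
    #: one-layer contrast while the score map stays non-empty on small
    #: images); 0 reproduces the full-scale architecture table.
    disc_s2_delta: int = 0
    log_path: str | None = None
    checkpoint_dir: str | None = None
    #: every N epochs, log the mean GC between each validation radiograph
    #: and the channel-sum of its decomposition (0 disables)
    val_interval: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.epochs < 2 or self.epochs % 2:
            raise ValueError("epochs must be an even number >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_channels < 2:
            raise ValueError("n_channels (K+1) must be >= 2")

    @property
    def hierarchical(self) -> bool:
        return VARIANTS[self.variant]["hierarchical"]

    def generator_spec(self, out_channels: int, in_channels: int,
                       hierarchical: bool) -> GeneratorSpec:
        return GeneratorSpec(
            in_channels=in_channels,
            out_channels=out_channels,
            residual_blocks=self.residual_blocks,
            downsample_layers=VARIANT_LAYERS[self.variant]["gen_down"],
            base_width=self.base_width,
            hierarchical=hierarchical,
            scales=(self.image_size // 2, self.image_size),
            enhancer_blocks=self.enhancer_blocks,
        )

    def discriminator_spec(self, in_channels: int) -> DiscriminatorSpec:
        s2 = VARIANT_LAYERS[self.variant]["disc_s2"] - self.disc_s2_delta
        if s2 < 1:
            raise ValueError("disc_s2_delta leaves no stride-2 layers")
        return DiscriminatorSpec(
            in_channels=in_channels,
            stride2_layers=s2,
            base_width=self.disc_base_width,
        )


def lr_at_epoch(epoch: int, config: TrainingConfig) -> float:
    """Constant lr0 for the first half of training, then linear decay to 0.

    ``epoch`` is 1-based and must lie in [1, config.epochs].
    """
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} out of range 1..{config.epochs}")
    half = config.epochs // 2
    if epoch <= half:
        return config.lr0
    return config.lr0 * (config.epochs - epoch) / (config.epochs - half)


class ImagePool:
    """Fake-image history pool: with probability 1/2 swap in a stored fake."""

    def __init__(self, size: int):
        self.size = size
        self.images: list[np.ndarray] = []

    def query(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.size == 0:
            return image
        if len(self.images) < self.size:
            self.images.append(image.copy())
            return image
        if rng.random() < 0.5:
            idx = int(rng.integers(0, self.size))
            out = self.images[idx]
            self.images[idx] = image.copy()
            return out
        return image


@dataclass
class TrainState:
    """Mutable training state; serializes bit-exactly for resuming."""

    config: TrainingConfig
    stage: str  # global | local | flat
    epoch: int
    step: int
    g_drr: ResnetGenerator | HierarchicalGenerator
    g_xp: ResnetGenerator | HierarchicalGenerator
    d_drr: PatchDiscriminator
    d_xp: PatchDiscriminator
    opt_g: Adam
    opt_d: Adam
    pool_fake_drr: ImagePool
    pool_fake_xp: ImagePool
    rng: np.random.Generator
    loss_history: list[dict] = field(default_factory=list)
    n_channels: int = 0

    # ------------------------------------------------------------- serialize
    def save(self, path) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for tag, model in (("g_drr", self.g_drr), ("g_xp", self.g_xp),
                           ("d_drr", self.d_drr), ("d_xp", self.d_xp)):
            for k, v in model.state_dict().items():
                arrays[f"{tag}:{k}"] = v
        for tag, opt in (("opt_g", self.opt_g), ("opt_d", self.opt_d)):
            sd = opt.state_dict()
            for i, (m, v) in enumerate(zip(sd["m"], sd["v"])):
                arrays[f"{tag}:m:{i}"] = m
                arrays[f"{tag}:v:{i}"] = v
            arrays[f"{tag}:t"] = np.array([sd["t"]])
            arrays[f"{tag}:lr"] = np.array([sd["lr"]])
        for tag, pool in (("pool_drr", self.pool_fake_drr),
                          ("pool_xp", self.pool_fake_xp)):
            for i, img in enumerate(pool.images):
                arrays[f"{tag}:{i}"] = img
        meta = {
            "config": asdict(self.config),
            "stage": self.stage,
            "epoch": self.epoch,
            "step": self.step,
            "n_channels": self.n_channels,
            "rng_state": self.rng.bit_generator.state,
            "loss_history": self.loss_history,
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg_d = meta["config"]
            cfg_d["weights"] = LossWeights(**cfg_d["weights"])
            config = TrainingConfig(**cfg_d)
            state = _init_state(config, meta["n_channels"],
                                stage=meta["stage"])
            for tag, model in (("g_drr", state.g_drr), ("g_xp", state.g_xp),
                               ("d_drr", state.d_drr), ("d_xp", state.d_xp)):
                sd = {
                    k[len(tag) + 1:]: data[k]
                    for k in data.files if k.startswith(tag + ":")
                }
                model.load_state_dict(sd)
            for tag, opt in (("opt_g", state.opt_g), ("opt_d", state.opt_d)):
                n = len(opt.m)
                opt.load_state_dict({
                    "t": int(data[f"{tag}:t"][0]),
                    "lr": float(data[f"{tag}:lr"][0]),
                    "m": [data[f"{tag}:m:{i}"] for i in range(n)],
                    "v": [data[f"{tag}:v:{i}"] for i in range(n)],
                })
            for tag, pool in (("pool_drr", state.pool_fake_drr),
                              ("pool_xp", state.pool_fake_xp)):
                i = 0
                while f"{tag}:{i}" in data.files:
                    pool.images.append(data[f"{tag}:{i}"])
                    i += 1
            state.epoch = meta["epoch"]
            state.step = meta["step"]
            state.loss_history = meta["loss_history"]
            state.rng.bit_generator.state = meta["rng_state"]
        return state


def _init_state(config: TrainingConfig, n_channels: int,
                stage: str | None = None) -> TrainState:
    """Build models and optimizers for a given stage, deterministically."""
    rng = np.random.default_rng(config.seed)
    hier = config.hierarchical
    if stage is None:
        stage = "global" if hier else "flat"
    seed_base = config.seed
    if stage == "local":
        gspec_drr = config.generator_spec(n_channels, 1, hierarchical=True)
        gspec_xp = config.generator_spec(1, n_channels, hierarchical=True)
        _, _, g_drr = build_hierarchical_generator(gspec_drr, seed=seed_base + 1)
        _, _, g_xp = build_hierarchical_generator(gspec_xp, seed=seed_base + 2)
        disc_seed = seed_base + 100  # fresh high-scale discriminators
    elif stage == "global" and hier:
        gspec_drr = config.generator_spec(n_channels, 1, hierarchical=True)
        gspec_xp = config.generator_spec(1, n_channels, hierarchical=True)
        _, _, g_drr = build_hierarchical_generator(gspec_drr, seed=seed_base + 1)
        _, _, g_xp = build_hierarchical_generator(gspec_xp, seed=seed_base + 2)
        disc_seed = seed_base + 3
    else:
        gspec_drr = config.generator_spec(n_channels, 1, hierarchical=False)
        gspec_xp = config.generator_spec(1, n_channels, hierarchical=False)
        g_drr = build_generator(gspec_drr, seed=seed_base + 1)
        g_xp = build_generator(gspec_xp, seed=seed_base + 2)
        disc_seed = seed_base + 3
    d_drr = build_discriminator(config.discriminator_spec(n_channels),
                                seed=disc_seed)
    d_xp = build_discriminator(config.discriminator_spec(1),
                               seed=disc_seed + 1)
    if stage == "global" and hier:
        g_params = (list(g_drr.global_net.parameters())
                    + list(g_xp.global_net.parameters()))
    else:
        g_params = list(g_drr.parameters()) + list(g_xp.parameters())
    opt_g = Adam(g_params, lr=config.lr0)
    opt_d = Adam(list(d_drr.parameters()) + list(d_xp.parameters()),
                 lr=config.lr0)
    return TrainState(
        config=config, stage=stage, epoch=0, step=0,
        g_drr=g_drr, g_xp=g_xp, d_drr=d_drr, d_xp=d_xp,
        opt_g=opt_g, opt_d=opt_d,
        pool_fake_drr=ImagePool(config.image_pool_size),
        pool_fake_xp=ImagePool(config.image_pool_size),
        rng=rng, n_channels=n_channels,
    )


def _load_normalized_split(manifest: DatasetManifest, split: str):
    """Load a split as normalized [0, 255] arrays."""
    cases = manifest.split(split)
    norm = manifest.normalization
    out = []
    for c in cases:
        out.append({
            "case_id": c.case_id,
            "radiograph": normalize(manifest.load_radiograph(c), norm),
            "drrs": normalize(manifest.load_drrs(c), norm),
        })
    return out


def _generator_forward(model, x: Tensor, stage: str) -> Tensor:
    if isinstance(model, HierarchicalGenerator) and stage == "global":
        return model.global_net(x)
    return model(x)


def _check_finite(value: float, what: str, state: TrainState) -> None:
    if not np.isfinite(value):
        snap = {"stage": state.stage, "epoch": state.epoch,
                "step": state.step, "term": what}
        raise RuntimeError(f"non-finite loss: {json.dumps(snap)}")


def _validation_gc(state: TrainState, val_data: list[dict],
                   low_res: bool) -> float:
    """Mean GC between validation radiographs and their decomposition sums."""
    from .losses import gradient_correlation

    scores = []
    for item in val_data:
        x = _prep(item["radiograph"], low_res)
        out = _generator_forward(state.g_drr, x, state.stage).data[0]
        scores.append(gradient_correlation(x.data[0, 0], out.sum(axis=0)))
    return float(np.mean(scores)) if scores else np.nan


def _train_stage(state: TrainState, data: list[dict], log_fh,
                 stop_after_epoch: int | None = None,
                 val_data: list[dict] | None = None) -> None:
    """Run the remaining epochs of one stage."""
    config = state.config
    last_epoch = (config.epochs if stop_after_epoch is None
                  else min(stop_after_epoch, config.epochs))
    rng = state.rng
    n = len(data)
    flags = VARIANTS[config.variant]
    freeze_until = (int(np.floor(config.freeze_frac * config.epochs))
                    if state.stage == "local" else 0)
    frozen_params: list = []
    if freeze_until > state.epoch and state.stage == "local":
        frozen_params = (list(state.g_drr.global_net.parameters())
                         + list(state.g_xp.global_net.parameters()))

    low_res = state.stage == "global" and config.hierarchical

    while state.epoch < last_epoch:
        epoch = state.epoch + 1
        lr = lr_at_epoch(epoch, config)
        state.opt_g.lr = lr
        state.opt_d.lr = lr
        if state.stage == "local" and state.epoch == freeze_until and frozen_params:
            frozen_params = []
        x_order = rng.permutation(n)
        for xi in x_order:
            losses = _train_step(state, data, int(xi), low_res,
                                 flags, frozen_params, rng)
            state.step += 1
            rec = {"step": state.step, "epoch": epoch, "stage": state.stage,
                   "variant": config.variant, **losses}
            state.loss_history.append(rec)
            if log_fh is not None:
                log_fh.write(json.dumps(rec) + "\n")
        state.epoch = epoch
        if (config.val_interval and val_data
                and epoch % config.val_interval == 0):
            rec = {"epoch": epoch, "stage": state.stage,
                   "variant": config.variant,
                   "val_gc": _validation_gc(state, val_data, low_res)}
            state.loss_history.append(rec)
            if log_fh is not None:
                log_fh.write(json.dumps(rec) + "\n")
        if config.checkpoint_dir:
            ckpt = Path(config.checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            state.save(ckpt / f"{state.stage}_epoch{epoch:04d}.npz")


def _prep(img: np.ndarray, low_res: bool) -> Tensor:
    t = Tensor(img[None, None] if img.ndim == 2 else img[None])
    if low_res:
        t = avgpool2x(t)
    return t


def _train_step(state, data, xi, low_res, flags, frozen_params, rng):
    config = state.config
    n = len(data)
    accum: dict[str, float] = {}
    g_totals = []
    fake_drr_np = fake_xp_np = None
    for _ in range(config.batch_size):
        yi = int(rng.integers(0, n))
        if n > 1:
            while yi == xi:
                yi = int(rng.integers(0, n))
        x = _prep(data[xi]["radiograph"], low_res)        # (1,1,H,W)
        y = _prep(data[yi]["drrs"], low_res)              # (1,K+1,H,W)

        fake_drr = _generator_forward(state.g_drr, x, state.stage)
        fake_xp = _generator_forward(state.g_xp, y, state.stage)
        cyc_x = _generator_forward(state.g_xp, fake_drr, state.stage)
        cyc_y = _generator_forward(state.g_drr, fake_xp, state.stage)

        gen_drr, _ = adversarial_loss(
            state.d_drr(y).detach(), state.d_drr(fake_drr))
        gen_xp, _ = adversarial_loss(
            state.d_xp(x).detach(), state.d_xp(fake_xp))
        gan_term = -(gen_drr + gen_xp)  # minimize negative log D(fake)
        # pixel losses are computed on the [-1, 1] scale so the default
        # weight balance (lambda_cyc = 10 vs an O(1) adversarial term)
        # carries over from the cited unit-scale training convention
        s = 1.0 / 127.5
        cyc_term = cycle_loss(x * s - 1.0, cyc_x * s - 1.0,
                              y * s - 1.0, cyc_y * s - 1.0)
        terms = {"gan": gan_term, "cyc": cyc_term}
        if flags["recon_l2"]:
            # plain rescale (no offset): the channel-sum identity
            # sum_n c_n = x survives multiplication but not shifts
            terms["recon_l2"] = reconstruction_l2_loss(x * s, fake_drr * s)
        if flags["recon_gc"]:
            terms["recon_gc"] = reconstruction_gc_loss(
                x, fake_drr, y, fake_xp)
        g_total, breakdown = total_loss(terms, config.weights, config.variant)
        _check_finite(breakdown["total"], "generator", state)
        g_totals.append(g_total)
        for k, v in breakdown.items():
            accum[k] = accum.get(k, 0.0) + v / config.batch_size
        fake_drr_np = fake_drr.data.copy()
        fake_xp_np = fake_xp.data.copy()

    state.opt_g.zero_grad()
    g_loss = g_totals[0]
    for t in g_totals[1:]:
        g_loss = g_loss + t
    (g_loss * (1.0 / config.batch_size)).backward()
    if frozen_params:
        for p in frozen_params:
            p.zero_grad()
    state.opt_g.step()

    # discriminator ascent on pooled fakes
    yi = int(rng.integers(0, n))
    x_real = _prep(data[xi]["radiograph"], low_res)
    y_real = _prep(data[yi]["drrs"], low_res)
    pooled_drr = Tensor(state.pool_fake_drr.query(fake_drr_np, rng))
    pooled_xp = Tensor(state.pool_fake_xp.query(fake_xp_np, rng))
    _, disc_drr = adversarial_loss(state.d_drr(y_real), state.d_drr(pooled_drr))
    _, disc_xp = adversarial_loss(state.d_xp(x_real), state.d_xp(pooled_xp))
    d_loss = -(disc_drr + disc_xp) * 0.5
    _check_finite(float(d_loss.data), "discriminator", state)
    state.opt_d.zero_grad()
    d_loss.backward()
    state.opt_d.step()
    accum["disc"] = float(-d_loss.data)
    return accum


def train(
    manifest: DatasetManifest,
    config: TrainingConfig,
    state: TrainState | None = None,
    stop_after_epoch: int | None = None,
) -> TrainState:
    """Train (or resume) one variant on the manifest's training split.

    Hierarchical variants run the global low-resolution stage for the full
    epoch schedule, then the local high-resolution stage; the returned
    state is the final one.  All randomness derives from ``config.seed``.
    ``stop_after_epoch`` interrupts the current stage early (the lr
    schedule still follows ``config.epochs``), for checkpoint/resume use.
    """
    data = _load_normalized_split(manifest, "train")
    if not data:
        raise ValueError("training split is empty")
    val_data = (_load_normalized_split(manifest, "val")
                if config.val_interval else [])
    n_channels = data[0]["drrs"].shape[0]
    log_fh = open(config.log_path, "a") if config.log_path else None
    try:
        if state is None:
            state = _init_state(config, n_channels)
        stages = (["global", "local"] if config.hierarchical else ["flat"])
        start = stages.index(state.stage)
        for si, stage_name in enumerate(stages[start:]):
            if si > 0 or state.stage != stage_name:
                # advance to a fresh stage, carrying generator weights over
                prev = state
                state = _init_state(config, n_channels, stage=stage_name)
                state.rng.bit_generator.state = prev.rng.bit_generator.state
                state.g_drr.load_state_dict(prev.g_drr.state_dict())
                state.g_xp.load_state_dict(prev.g_xp.state_dict())
                state.loss_history = prev.loss_history
            if state.epoch < config.epochs:
                _train_stage(state, data, log_fh, stop_after_epoch, val_data)
                if stop_after_epoch is not None and state.epoch < config.epochs:
                    break
    finally:
        if log_fh is not None:
            log_fh.close()
    return state


def decompose(radiograph: Radiograph | np.ndarray, state: TrainState) -> DecomposedSet:
    """Decompose a normalized radiograph into K+1 structure channels.

    Deterministic inference with the trained generator of the state's
    stage; the output is on the normalized [0, 255] scale and carries the
    input's normalization constants when available.
    """
    if isinstance(radiograph, Radiograph):
        pixels = radiograph.pixels
        norm = radiograph.normalization
        if radiograph.raw_or_normalized != "normalized":
            raise ValueError("decompose expects a normalized radiograph")
    else:
        pixels = np.asarray(radiograph, dtype=np.float64)
        norm = None
    x = Tensor(pixels[None, None])
    out = _generator_forward(state.g_drr, x, state.stage)
    channels = np.clip(out.data[0], 0.0, 255.0)
    labels = [f"channel_{i:02d}" for i in range(channels.shape[0])]
    return DecomposedSet(
        channels=channels, labels=labels,
        raw_or_normalized="normalized", normalization=norm,
    )
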