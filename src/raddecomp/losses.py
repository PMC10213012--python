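"""Loss terms for unpaired radiograph decomposition.

The framework couples a standard cycle-consistent adversarial objective
with a *reconstruction gradient-correlation* (GC) term: the sum of the
predicted per-structure channels must reproduce the gradients of the input
radiograph, which is robust to the absolute-intensity discrepancies between
rendered projections and real radiographs.  The total objective is

    L_total = L_GAN + lambda_cyc * L_cyc + lambda_GC * L_reconGC

with lambda_cyc = 10 and lambda_GC = 1.0 by default.  An l2 reconstruction
term (weight 0.5) is kept for the second baseline of the ablation matrix.

All functions accept either plain numpy arrays (returning floats) or
autodiff tensors (returning tensors through which gradients flow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, conv2d

logger = logging.getLogger(__name__)

__all__ = [
    "LossWeights",
    "VARIANTS",
    "ncc",
    "gradient_correlation",
    "adversarial_loss",
    "cycle_loss",
    "reconstruction_gc_loss",
    "reconstruction_l2_loss",
    "total_loss",
]

#: Ablation matrix: which optional terms each training variant uses and
#: whether the generator is trained hierarchically (local enhancer).
VARIANTS: dict[str, dict[str, bool]] = {
    "conventional1": {"hierarchical": False, "recon_l2": False, "recon_gc": False},
    "conventional2": {"hierarchical": False, "recon_l2": True, "recon_gc": False},
    "proposed1": {"hierarchical": True, "recon_l2": False, "recon_gc": False},
    "proposed2": {"hierarchical": True, "recon_l2": False, "recon_gc": True},
}

_NCC_EPS = 1e-8
_SCORE_EPS = 1e-7

# 3x3 Sobel kernels for the u (column) and v (row) gradient components.
_SOBEL_U = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_V = _SOBEL_U.T


@dataclass(frozen=True)
class LossWeights:
    """Balance parameters of the total objective (all dimensionless >= 0)."""

    lambda_cyc: float = 10.0
    lambda_gc: float = 1.0
    lambda_recon_l2: float = 0.5

    def __post_init__(self):
        for name in ("lambda_cyc", "lambda_gc", "lambda_recon_l2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _maybe_float(result: Tensor, *inputs) -> Tensor | float:
    if any(isinstance(x, Tensor) for x in inputs):
        return result
    return float(result.data)


def ncc(a, b):
    """Zero-mean normalized cross-correlation of two equal-shape images.

    Returns a value in [-1, 1]; a small epsilon in the denominator makes
    constant (zero-variance) inputs yield 0 rather than an error.
    """
    ta, tb = as_tensor(a), as_tensor(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    if ta.size < 2:
        raise ValueError("ncc needs at least 2 pixels")
    da = ta - ta.mean()
    db = tb - tb.mean()
    va = (da**2).sum()
    vb = (db**2).sum()
    if float(va.data) == 0.0 or float(vb.data) == 0.0:
        logger.debug("ncc: zero-variance input, returning 0")
    out = (da * db).sum() / ((va * vb + _NCC_EPS) ** 0.5)
    return _maybe_float(out, a, b)


def _sobel(img: Tensor, kernel: np.ndarray) -> Tensor:
    four = img.reshape(1, 1, *img.shape)
    resp = conv2d(four, Tensor(kernel.reshape(1, 1, 3, 3)), None)
    return resp.reshape(resp.shape[2], resp.shape[3])


def _central_diff(img: Tensor, axis: int) -> Tensor:
    if axis == 1:  # u: columns
        return (img[1:-1, 2:] - img[1:-1, :-2]) * 0.5
    return (img[2:, 1:-1] - img[:-2, 1:-1]) * 0.5


def gradient_correlation(a, b, operator: str = "sobel"):
    """Gradient correlation GC(a, b) in [-1, 1].

    Mean of the NCCs of the two directional gradient images,
    GC = 1/2 [ NCC(grad_u a, grad_u b) + NCC(grad_v a, grad_v b) ],
    computed with 3x3 Sobel operators on the valid interior (central
    differences available via ``operator='central'``).  Invariant to
    positive affine intensity changes of either argument.
    """
    ta, tb = as_tensor(a), as_tensor(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    if ta.ndim != 2 or min(ta.shape) < 3:
        raise ValueError("gradient_correlation needs 2-D inputs of size >= 3x3")
    if operator == "sobel":
        gu_a, gv_a = _sobel(ta, _SOBEL_U), _sobel(ta, _SOBEL_V)
        gu_b, gv_b = _sobel(tb, _SOBEL_U), _sobel(tb, _SOBEL_V)
    elif operator == "central":
        gu_a, gv_a = _central_diff(ta, 1), _central_diff(ta, 0)
        gu_b, gv_b = _central_diff(tb, 1), _central_diff(tb, 0)
    else:
        raise ValueError(f"unknown gradient operator: {operator!r}")
    out = (ncc(gu_a, gu_b) + ncc(gv_a, gv_b)) * 0.5
    return _maybe_float(out, a, b)


def _clamped_log(scores: Tensor) -> Tensor:
    lo, hi = float(scores.data.min()), float(scores.data.max())
    if lo < _SCORE_EPS or hi > 1.0 - _SCORE_EPS:
        logger.debug("adversarial_loss: scores clamped to (%g, 1-%g)",
                     _SCORE_EPS, _SCORE_EPS)
    return scores.clip(_SCORE_EPS, 1.0 - _SCORE_EPS).log()


def adversarial_loss(d_real_scores, d_fake_scores):
    """Log-form adversarial terms from post-sigmoid patch score maps.

    Returns ``(generator_term, discriminator_term)`` where the
    discriminator term mean[log D(real)] + mean[log(1 - D(fake))] is
    *maximized* by D and the non-saturating generator term
    mean[log D(fake)] is *maximized* by G.  Reductions are means over
    patches and batch so magnitudes are resolution independent.
    """
    real = as_tensor(d_real_scores)
    fake = as_tensor(d_fake_scores)
    disc = _clamped_log(real).mean() + _clamped_log(1.0 - fake).mean()
    gen = _clamped_log(fake).mean()
    return (
        _maybe_float(gen, d_fake_scores),
        _maybe_float(disc, d_real_scores, d_fake_scores),
    )


def cycle_loss(x, x_cycled, y, y_cycled):
    """Cycle-consistency: mean |x_cycled - x| + mean |y_cycled - y|."""
    tx, txc = as_tensor(x), as_tensor(x_cycled)
    ty, tyc = as_tensor(y), as_tensor(y_cycled)
    if tx.shape != txc.shape or ty.shape != tyc.shape:
        raise ValueError("cycle_loss: shape mismatch")
    out = (txc - tx).abs().mean() + (tyc - ty).abs().mean()
    return _maybe_float(out, x, x_cycled, y, y_cycled)


def _channel_sum_2d(channels) -> Tensor:
    t = as_tensor(channels)
    if t.ndim == 3:
        return t.sum(axis=0)
    if t.ndim == 4 and t.shape[0] == 1:
        return t.sum(axis=1).reshape(t.shape[2], t.shape[3])
    raise ValueError(f"expected (C,H,W) or (1,C,H,W) channels, got {t.shape}")


def _as_2d(img) -> Tensor:
    t = as_tensor(img)
    if t.ndim == 2:
        return t
    if t.ndim == 4 and t.shape[0] == 1 and t.shape[1] == 1:
        return t.reshape(t.shape[2], t.shape[3])
    raise ValueError(f"expected a single 2-D image, got shape {t.shape}")


def reconstruction_gc_loss(x, g_drr_channels, y_channels, g_xp_output,
                           operator: str = "sobel"):
    """Reconstruction GC penalty in [0, 2].

    1/2 [ (1 - GC(x, sum_n G_DRR,n(x))) + (1 - GC(sum_n y_n, G_Xp(y))) ]:
    the channel-sum of the decomposition must match the radiograph's
    gradients, and symmetrically for the reverse generator.
    """
    term_x = 1.0 - gradient_correlation(
        _as_2d(x), _channel_sum_2d(g_drr_channels), operator=operator
    )
    term_y = 1.0 - gradient_correlation(
        _channel_sum_2d(y_channels), _as_2d(g_xp_output), operator=operator
    )
    out = (as_tensor(term_x) + as_tensor(term_y)) * 0.5
    return _maybe_float(out, x, g_drr_channels, y_channels, g_xp_output)


def reconstruction_l2_loss(x, g_drr_channels):
    """Mean squared difference between the channel-sum and the input."""
    diff = _channel_sum_2d(g_drr_channels) - _as_2d(x)
    out = (diff**2).mean()
    return _maybe_float(out, x, g_drr_channels)


def total_loss(terms: dict, weights: LossWeights, variant: str):
    """Weighted generator objective for one ablation variant.

    ``terms`` maps term names to scalars/tensors: ``"gan"`` (generator
    adversarial term, already negated for minimization), ``"cyc"``, and
    optionally ``"recon_gc"`` / ``"recon_l2"``.  Returns ``(total,
    breakdown)`` where the breakdown holds each weighted contribution.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of "
                         f"{sorted(VARIANTS)}")
    flags = VARIANTS[variant]
    breakdown: dict[str, float] = {}
    total = as_tensor(terms["gan"])
    breakdown["gan"] = float(as_tensor(terms["gan"]).data)
    cyc = as_tensor(terms["cyc"]) * weights.lambda_cyc
    breakdown["cyc"] = float(cyc.data)
    total = total + cyc
    if flags["recon_l2"]:
        l2 = as_tensor(terms["recon_l2"]) * weights.lambda_recon_l2
        breakdown["recon_l2"] = float(l2.data)
        total = total + l2
    if flags["recon_gc"]:
        gc = as_tensor(terms["recon_gc"]) * weights.lambda_gc
        breakdown["recon_gc"] = float(gc.data)
        total = total + gc
    breakdown["total"] = float(total.data)
    out = total if any(isinstance(v, Tensor) for v in terms.values()) else float(total.data)
    return out, breakdown
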