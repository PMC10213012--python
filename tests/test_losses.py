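"""Loss-term oracles: definitional brute-force implementations are the
reference for NCC / gradient correlation, and every term is checked for
the closed-form values its definition implies."""

import math

import numpy as np
import pytest

from raddecomp.autodiff import Tensor
from raddecomp.losses import (
    LossWeights,
    VARIANTS,
    adversarial_loss,
    cycle_loss,
    gradient_correlation,
    ncc,
    reconstruction_gc_loss,
    reconstruction_l2_loss,
    total_loss,
)

SOBEL_U = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_V = SOBEL_U.T


def brute_ncc(a, b):
    a = np.asarray(a, float).ravel() - np.asarray(a, float).mean()
    b = np.asarray(b, float).ravel() - np.asarray(b, float).mean()
    return float((a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum() + 1e-8))


def brute_sobel(img, kernel):
    h, w = img.shape
    out = np.zeros((h - 2, w - 2))
    for i in range(h - 2):
        for j in range(w - 2):
            out[i, j] = (img[i : i + 3, j : j + 3] * kernel).sum()
    return out


def brute_gc(a, b):
    return 0.5 * (
        brute_ncc(brute_sobel(a, SOBEL_U), brute_sobel(b, SOBEL_U))
        + brute_ncc(brute_sobel(a, SOBEL_V), brute_sobel(b, SOBEL_V))
    )


class TestNcc:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(size=(8, 8))
        assert ncc(a, a) == pytest.approx(1.0, abs=1e-7)
        assert ncc(a, -a) == pytest.approx(-1.0, abs=1e-7)

    def test_positive_scaling_gives_one(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = 2.0 * a
        assert ncc(a, b) == pytest.approx(1.0, abs=1e-7)

    def test_zero_variance_returns_zero(self):
        assert ncc(np.ones((4, 4)), np.arange(16.0).reshape(4, 4)) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ncc(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGradientCorrelation:
    def test_identity_and_affine_invariance(self, rng):
        a = rng.normal(size=(9, 9))
        assert gradient_correlation(a, a) == pytest.approx(1.0, abs=1e-6)
        assert gradient_correlation(a, 3.0 * a + 7.0) == pytest.approx(
            gradient_correlation(a, a), abs=1e-6
        )

    def test_perturbed_ramp_matches_brute_force(self):
        a = np.tile(np.arange(5.0), (5, 1))  # horizontal ramp
        b = a.copy()
        b[2, 2] += 1.5
        assert gradient_correlation(a, b) == pytest.approx(
            brute_gc(a, b), abs=1e-12
        )

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.normal(size=(16, 16))
            b = rng.normal(size=(16, 16))
            assert abs(gradient_correlation(a, b) - brute_gc(a, b)) < 1e-10

    def test_bounds(self, rng):
        for _ in range(50):
            a = rng.normal(size=(8, 8))
            b = rng.normal(size=(8, 8))
            assert -1.0 <= gradient_correlation(a, b) <= 1.0


class TestAdversarial:
    def test_half_scores_give_two_log_half(self):
        scores = np.full((1, 1, 4, 4), 0.5)
        _, disc = adversarial_loss(scores, scores)
        assert disc == pytest.approx(2.0 * math.log(0.5), abs=1e-9)

    def test_perfect_discriminator_approaches_supremum_zero(self):
        real = np.full((1, 1, 4, 4), 1.0 - 1e-9)
        fake = np.full((1, 1, 4, 4), 1e-9)
        _, disc = adversarial_loss(real, fake)
        assert disc == pytest.approx(0.0, abs=1e-5)

    def test_patch_order_invariance(self, rng):
        real = rng.uniform(0.1, 0.9, size=(1, 1, 3, 3))
        fake = rng.uniform(0.1, 0.9, size=(1, 1, 3, 3))
        g1, d1 = adversarial_loss(real, fake)
        perm = rng.permutation(9)
        g2, d2 = adversarial_loss(
            real.ravel()[perm].reshape(real.shape),
            fake.ravel()[perm].reshape(fake.shape),
        )
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert g1 == pytest.approx(g2, abs=1e-12)


class TestCycle:
    def test_perfect_cycle_is_zero(self, rng):
        x = rng.normal(size=(5, 5))
        y = rng.normal(size=(3, 5, 5))
        assert cycle_loss(x, x, y, y) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=(5, 5))
        y = rng.normal(size=(3, 5, 5))
        assert cycle_loss(x, x + 2.0, y, y) == pytest.approx(2.0, abs=1e-12)

    def test_channel_permutation_invariance(self, rng):
        x = rng.normal(size=(5, 5))
        y = rng.normal(size=(3, 5, 5))
        yc = y + rng.normal(size=y.shape)
        perm = [2, 0, 1]
        assert cycle_loss(x, x, y, yc) == pytest.approx(
            cycle_loss(x, x, y[perm], yc[perm]), abs=1e-12
        )


class TestReconstruction:
    def test_exact_reconstruction_is_zero(self, rng):
        chans = rng.uniform(1.0, 2.0, size=(3, 8, 8))
        chans += np.linspace(0, 1, 8)[None, None, :]  # non-constant gradients
        x = chans.sum(axis=0)
        y = rng.uniform(0.0, 1.0, size=(3, 8, 8))
        y += np.linspace(0, 1, 8)[None, :, None]
        assert reconstruction_gc_loss(x, chans, y, y.sum(axis=0)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_offset_invariance_of_x_term(self, rng):
        chans = rng.normal(size=(3, 8, 8))
        x = chans.sum(axis=0) + 5.0  # constant offset: gradients unchanged
        y = rng.normal(size=(3, 8, 8))
        loss = reconstruction_gc_loss(x, chans, y, y.sum(axis=0))
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_negated_reconstruction_gives_one(self, rng):
        chans = rng.normal(size=(3, 8, 8))
        x = -chans.sum(axis=0)
        y = rng.normal(size=(3, 8, 8))
        loss = reconstruction_gc_loss(x, chans, y, y.sum(axis=0))
        assert loss == pytest.approx(1.0, abs=1e-6)

    def test_l2_values_and_permutation_invariance(self, rng):
        chans = rng.normal(size=(3, 6, 6))
        x = chans.sum(axis=0)
        assert reconstruction_l2_loss(x, chans) == 0.0
        assert reconstruction_l2_loss(x - 3.0, chans) == pytest.approx(9.0)
        assert reconstruction_l2_loss(x, chans[[2, 0, 1]]) == pytest.approx(0.0, abs=1e-12)


class TestTotalLoss:
    def test_default_weights(self):
        w = LossWeights()
        assert (w.lambda_cyc, w.lambda_gc, w.lambda_recon_l2) == (10.0, 1.0, 0.5)

    def test_zero_weights_leave_adversarial_term(self):
        w = LossWeights(lambda_cyc=0.0, lambda_gc=0.0, lambda_recon_l2=0.0)
        total, bd = total_loss({"gan": 1.5, "cyc": 7.0, "recon_gc": 2.0},
                               w, "proposed2")
        assert total == pytest.approx(1.5)

    def test_doubling_lambda_gc_doubles_contribution(self):
        terms = {"gan": 0.1, "cyc": 0.2, "recon_gc": 0.3}
        _, bd1 = total_loss(terms, LossWeights(lambda_gc=1.0), "proposed2")
        _, bd2 = total_loss(terms, LossWeights(lambda_gc=2.0), "proposed2")
        assert bd2["recon_gc"] == pytest.approx(2.0 * bd1["recon_gc"])

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_variant_term_matrix(self, variant):
        terms = {"gan": 1.0, "cyc": 1.0, "recon_gc": 1.0, "recon_l2": 1.0}
        _, bd = total_loss(terms, LossWeights(), variant)
        assert ("recon_l2" in bd) == VARIANTS[variant]["recon_l2"]
        assert ("recon_gc" in bd) == VARIANTS[variant]["recon_gc"]

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError):
            total_loss({"gan": 0.0, "cyc": 0.0}, LossWeights(), "nope")


class TestGradientFlow:
    """Every loss term is differentiable wrt generator outputs."""

    @staticmethod
    def _fd_check(fn, x0, tol=1e-4):
        x = Tensor(x0, requires_grad=True)
        out = fn(x)
        out.backward()
        eps = 1e-6
        num = np.zeros_like(x0)
        it = np.nditer(x0, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = x.data[idx]
            x.data[idx] = orig + eps
            fp = float(fn(x).data)
            x.data[idx] = orig - eps
            fm = float(fn(x).data)
            x.data[idx] = orig
            num[idx] = (fp - fm) / (2 * eps)
        scale = max(np.abs(num).max(), 1e-10)
        assert np.abs(num - x.grad).max() / scale < tol

    def test_cycle_loss_gradient(self, rng):
        x = rng.normal(size=(5, 5))
        y = rng.normal(size=(2, 5, 5))
        self._fd_check(lambda t: cycle_loss(x, t, y, y + 1.0),
                       rng.normal(size=(5, 5)))

    def test_reconstruction_gc_gradient(self, rng):
        x = rng.normal(size=(6, 6))
        y = rng.normal(size=(2, 6, 6))
        self._fd_check(
            lambda t: reconstruction_gc_loss(x, t, y, y.sum(axis=0)),
            rng.normal(size=(2, 6, 6)),
        )

    def test_reconstruction_l2_gradient(self, rng):
        x = rng.normal(size=(5, 5))
        self._fd_check(lambda t: reconstruction_l2_loss(x, t),
                       rng.normal(size=(2, 5, 5)))

    def test_adversarial_gradient(self, rng):
        real = rng.uniform(0.2, 0.8, size=(1, 1, 3, 3))

        def gen_term(t):
            g, _ = adversarial_loss(real, t.sigmoid())
            return g

        self._fd_check(gen_term, rng.normal(size=(1, 1, 3, 3)))
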