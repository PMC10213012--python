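"""Projection model: HU conversion, integrators, noise, normalization."""

import numpy as np
import pytest

from raddecomp.phantom import PhantomSpec, StructureLabel, VolumePhantom, generate_phantom
from raddecomp.projection import (
    Normalization,
    ProjectionGeometry,
    Radiograph,
    RigidTransform,
    add_poisson_noise,
    default_geometry_for,
    denormalize,
    hu_to_attenuation,
    normalize,
    render,
    resize,
)


class TestHuToAttenuation:
    def test_water_and_air_references(self):
        assert hu_to_attenuation(0.0, mu_water=0.02) == pytest.approx(0.02)
        assert hu_to_attenuation(-1000.0) == 0.0
        assert hu_to_attenuation(-1500.0) == 0.0  # clamped

    def test_ten_hu_drop_is_about_one_percent_for_muscle(self):
        mu_hi = hu_to_attenuation(50.0)
        mu_lo = hu_to_attenuation(40.0)
        rel_drop = (mu_hi - mu_lo) / mu_hi
        assert rel_drop == pytest.approx(10.0 / 1050.0, rel=1e-12)
        assert 0.009 < rel_drop < 0.011  # "around 1%"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            hu_to_attenuation(np.array([np.nan]))


def _cube_phantom(side_vox=10, spacing=1.0, hu=0.0, pad=4):
    n = side_vox + 2 * pad
    vol = np.full((n, n, n), -1000.0)
    sl = slice(pad, pad + side_vox)
    vol[sl, sl, sl] = hu
    mask = np.zeros_like(vol, dtype=bool)
    mask[sl, sl, sl] = True
    return VolumePhantom(
        hu_volume=vol, masks=[mask, ~mask & (vol > -200)],
        spacing=(spacing,) * 3,
        labels=[StructureLabel("cube", "bone", "midline"),
                StructureLabel("background", "background", "midline")],
        true_side_volumes={}, affected_side="left", structure_hu={},
    )


class TestRender:
    def test_homogeneous_cube_parallel_integral(self):
        # 10 mm cube of water (mu = 0.02/mm): interior line integral 0.2
        ph = _cube_phantom(side_vox=10, spacing=1.0, hu=0.0)
        geo = default_geometry_for(ph.hu_volume.shape, ph.spacing)
        _, rad = render(ph, geo, mu_water=0.02)
        nv = rad.pixels.shape[0]
        interior = rad.pixels[nv // 2 - 2 : nv // 2 + 2,
                              nv // 2 - 2 : nv // 2 + 2]
        np.testing.assert_allclose(interior, 0.2, rtol=1e-12)

    def test_conservation_aligned(self, toy_spec):
        ph = generate_phantom(toy_spec)
        geo = default_geometry_for(toy_spec.grid_shape, toy_spec.spacing)
        drrs, rad = render(ph, geo)
        err = np.abs(drrs.channel_sum() - rad.pixels).max()
        assert err < 1e-6 * rad.pixels.max()

    def test_conservation_exact_integrator_rotated(self, toy_spec):
        ph = generate_phantom(toy_spec)
        geo = ProjectionGeometry(
            model="pinhole", detector_shape=(16, 16), pixel_pitch=10.0,
            source_detector_distance=1000.0,
            volume_pose=RigidTransform((4.0, -3.0, 7.0), (5.0, 500.0, -4.0)),
        )
        drrs, rad = render(ph, geo, integrator="exact")
        err = np.abs(drrs.channel_sum() - rad.pixels).max()
        assert err < 1e-6 * rad.pixels.max()

    def test_sampling_matches_exact_oracle_on_two_box_phantom(self):
        shape, sp = (32, 32, 32), (4.0, 4.0, 4.0)
        hu = np.full(shape, -1000.0)
        hu[6:14, 8:24, 6:26] = 0.0
        hu[18:28, 10:20, 10:20] = 500.0
        m1 = np.zeros(shape, bool); m1[6:14, 8:24, 6:26] = True
        m2 = np.zeros(shape, bool); m2[18:28, 10:20, 10:20] = True
        ph = VolumePhantom(
            hu_volume=hu, masks=[m1, m2, ~(m1 | m2) & (hu > -200)],
            spacing=sp,
            labels=[StructureLabel("box1", "bone", "left"),
                    StructureLabel("box2", "bone", "right"),
                    StructureLabel("background", "background", "midline")],
            true_side_volumes={}, affected_side="left", structure_hu={},
        )
        geo = ProjectionGeometry(
            model="pinhole", detector_shape=(32, 32), pixel_pitch=6.0,
            source_detector_distance=1000.0,
            volume_pose=RigidTransform((8.0, -5.0, 12.0), (3.0, 500.0, -6.0)),
        )
        _, exact = render(ph, geo, integrator="exact")
        _, sampled = render(ph, geo, integrator="sampling")
        rel = np.abs(sampled.pixels - exact.pixels).max() / exact.pixels.max()
        assert rel < 1e-2

    def test_mass_identity_alpha_v(self, toy_spec):
        # parallel projection: pixel-sum x pixel area = alpha * V
        ph = generate_phantom(toy_spec)
        geo = default_geometry_for(toy_spec.grid_shape, toy_spec.spacing)
        drrs, _ = render(ph, geo)
        pixel_area = geo.pixel_pitch**2
        for ci, lab in enumerate(ph.labels):
            if lab.group == "background":
                continue
            alpha = hu_to_attenuation(ph.structure_hu[lab.name])
            vols = ph.true_side_volumes[lab.name]
            v = vols["left"] + vols["right"]
            # pixel pitch equals voxel spacing here: sum * pitch^2 = alpha*V
            assert drrs.channels[ci].sum() * pixel_area == pytest.approx(
                float(alpha) * v, rel=1e-9
            )

    def test_monotonicity_in_hu(self, toy_spec):
        ph = generate_phantom(toy_spec)
        geo = default_geometry_for(toy_spec.grid_shape, toy_spec.spacing)
        _, before = render(ph, geo)
        idx = tuple(np.array(toy_spec.grid_shape) // 2)
        ph.hu_volume[idx] += 300.0
        _, after = render(ph, geo)
        assert np.all(after.pixels >= before.pixels - 1e-12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            ProjectionGeometry(model="pinhole", source_detector_distance=None)
        with pytest.raises(ValueError):
            ProjectionGeometry(pixel_pitch=0.0)


class TestPoissonNoise:
    def test_high_flux_limit(self, rng):
        p = rng.uniform(0.0, 5.0, size=(32, 32))
        noisy = add_poisson_noise(Radiograph(pixels=p), i0=1e9, seed=0)
        assert np.abs(noisy.pixels - p).max() < 1e-2

    def test_mean_within_three_standard_errors(self):
        # delta method: mean ~ p, var ~ exp(p)/i0
        p, i0, n = 1.0, 1e4, 10_000
        img = Radiograph(pixels=np.full((n,), p).reshape(100, 100))
        noisy = add_poisson_noise(img, i0=i0, seed=3)
        se = np.sqrt(np.exp(p) / i0 / n)
        assert abs(noisy.pixels.mean() - p) < 3 * se

    def test_variance_matches_delta_method_within_20_percent(self):
        for p in (0.5, 1.5, 3.0):
            img = Radiograph(pixels=np.full((200, 200), p))
            noisy = add_poisson_noise(img, i0=1e3, seed=7)
            pred = np.exp(p) / 1e3
            assert noisy.pixels.var() == pytest.approx(pred, rel=0.2)

    def test_determinism(self, rng):
        p = rng.uniform(0.0, 3.0, size=(16, 16))
        a = add_poisson_noise(Radiograph(pixels=p), i0=1e4, seed=5)
        b = add_poisson_noise(Radiograph(pixels=p), i0=1e4, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            add_poisson_noise(Radiograph(pixels=np.ones((2, 2))), i0=0.0, seed=0)
        with pytest.raises(ValueError):
            add_poisson_noise(Radiograph(pixels=-np.ones((2, 2))), i0=10.0, seed=0)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        norm = Normalization(raw_min=1.0, raw_max=3.0)
        assert normalize(np.array(1.0), norm) == 0.0
        assert normalize(np.array(3.0), norm) == 255.0
        assert normalize(np.array(2.0), norm) == pytest.approx(127.5)

    def test_round_trip(self, rng):
        norm = Normalization(raw_min=0.0, raw_max=7.3)
        x = rng.uniform(0.0, 7.3, size=(8, 8))
        np.testing.assert_allclose(
            denormalize(normalize(x, norm), norm), x, atol=1e-12
        )

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            Normalization(raw_min=2.0, raw_max=2.0)


class TestResize:
    def test_identity_and_constant(self, rng):
        x = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(resize(x, 16), x)
        c = np.full((16, 16), 3.7)
        np.testing.assert_allclose(resize(c, 8), 3.7, atol=1e-9)

    def test_downsampled_ramp_stays_linear(self):
        ramp = np.tile(np.arange(32.0), (32, 1))
        small = resize(ramp, 16)
        interior = small[4:-4, 4:-4]
        # columns remain an affine function of the column index
        col_means = interior.mean(axis=0)
        diffs = np.diff(col_means)
        # cubic-spline prefiltering is accurate to ~1e-6 of the value
        np.testing.assert_allclose(diffs, diffs[0], rtol=0, atol=1e-5)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            resize(np.zeros((16, 16)), 4)
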