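"""Metric oracles: PSNR/Dice vs loop-based definitions, threshold
selection, volume-ratio recovery, ICC vs the ANOVA mean squares."""

import math

import numpy as np
import pytest

from raddecomp.evaluation import (
    PSNR_CAP_DB,
    dice,
    evaluate,
    icc,
    psnr,
    select_threshold,
    volume_ratio,
)
from raddecomp.phantom import PhantomSpec, generate_phantom
from raddecomp.projection import (
    DecomposedSet,
    ProjectionGeometry,
    RigidTransform,
    default_geometry_for,
    normalize,
    render,
)


def loop_psnr(pred, truth, peak):
    total, count = 0.0, 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        total += (p - t) ** 2
        count += 1
    mse = total / count
    return 10.0 * math.log10(peak**2 / mse)


def loop_dice(a, b):
    inter = a_n = b_n = 0
    for x, y in zip(a.ravel(), b.ravel()):
        inter += bool(x) and bool(y)
        a_n += bool(x)
        b_n += bool(y)
    return 2.0 * inter / (a_n + b_n)


class TestPsnr:
    def test_identical_images_hit_the_cap(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        assert psnr(img, img) == PSNR_CAP_DB

    def test_unit_offset_closed_form(self, rng):
        img = rng.uniform(1, 254, (16, 16))
        assert psnr(img + 1.0, img) == pytest.approx(
            20.0 * math.log10(255.0), abs=1e-9
        )

    def test_halving_mse_adds_3dB(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        noise = rng.normal(0, 4, (16, 16))
        d = psnr(img + noise, img)
        d2 = psnr(img + noise / math.sqrt(2), img)
        assert d2 - d == pytest.approx(10.0 * math.log10(2.0), abs=1e-9)

    def test_matches_loop_implementation(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 255, (16, 16))
            b = rng.uniform(0, 255, (16, 16))
            assert psnr(a, b) == pytest.approx(loop_psnr(a, b, 255.0), abs=1e-10)


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool); a[0, 0] = True
        b = np.zeros((4, 4), bool); b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool); a[0, :2] = True
        b = np.zeros((4, 4), bool); b[0, 1:3] = True
        assert dice(a, b) == 0.5

    def test_both_empty_convention(self):
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_matches_loop_implementation(self, rng):
        for _ in range(10):
            a = rng.random((16, 16)) > 0.4
            b = rng.random((16, 16)) > 0.6
            assert dice(a, b) == pytest.approx(loop_dice(a, b), abs=1e-12)


class TestSelectThreshold:
    def test_tie_break_to_smallest(self):
        truth = np.zeros((4, 4), bool)
        truth[1:3, 1:3] = True
        pred = np.where(truth, 255.0, 0.0)
        sweep = [10.0, 50.0, 200.0]
        thr, d = select_threshold([pred], [truth], sweep)
        assert thr == 10.0 and d == 1.0

    def test_two_level_image_exhaustive(self):
        truth = np.zeros((6, 6), bool)
        truth[2:5, 2:5] = True
        pred = np.where(truth, 100.0, 10.0)
        for t in (20.0, 50.0, 99.0):
            assert select_threshold([pred], [truth], [t])[1] == 1.0
        # below the background level everything is foreground
        thr, d = select_threshold([pred], [truth], [5.0])
        assert d < 1.0

    def test_result_is_maximum_of_recomputed_means(self, rng):
        truths = [rng.random((8, 8)) > 0.5 for _ in range(3)]
        preds = [rng.uniform(0, 255, (8, 8)) for _ in range(3)]
        sweep = list(np.linspace(10, 200, 11))
        thr, best = select_threshold(preds, truths, sweep)
        means = [
            np.mean([dice(p > t, m) for p, m in zip(preds, truths)])
            for t in sweep
        ]
        assert best == pytest.approx(max(means))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([], [], [1.0])


class TestVolumeRatio:
    def test_symmetric_structure_gives_one(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0),
                           n_bones=1, n_muscles=2, asymmetry_factor=1.0,
                           seed=17)
        ph = generate_phantom(spec)
        drrs, _ = render(ph, default_geometry_for(spec.grid_shape, spec.spacing))
        nu = drrs.channels.shape[2]
        left = np.zeros(drrs.channels.shape[1:], bool)
        left[:, np.arange(nu) - (nu - 1) / 2.0 < 0] = True
        for ci, lab in enumerate(ph.labels):
            if lab.name.startswith("muscle"):
                ch = drrs.channels[ci]
                r = volume_ratio(ch, left & (ch > 0), ~left & (ch > 0))
                assert r.r == pytest.approx(1.0, abs=1e-6)

    def test_scaled_semi_axis_recovers_factor(self):
        spec = PhantomSpec(grid_shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5),
                           n_bones=1, n_muscles=2, asymmetry_factor=0.8,
                           seed=23)
        ph = generate_phantom(spec)
        drrs, _ = render(ph, default_geometry_for(spec.grid_shape, spec.spacing))
        nu = drrs.channels.shape[2]
        left = np.zeros(drrs.channels.shape[1:], bool)
        left[:, np.arange(nu) - (nu - 1) / 2.0 < 0] = True
        for ci, lab in enumerate(ph.labels):
            if lab.name.startswith("muscle"):
                ch = drrs.channels[ci]
                r = volume_ratio(ch, left & (ch > 0), ~left & (ch > 0))
                assert r.r == pytest.approx(0.8, abs=1e-2)

    def test_pinhole_magnification_bias_is_small(self):
        # same phantom under a centred pinhole at d = 1000 mm: the
        # perspective bias on the ratio (pinhole vs parallel, both with
        # the exact intersection-length integrator) is far below 0.02,
        # and the estimate stays within 0.02 of the asymmetry factor up
        # to this grid's voxelization
        spec = PhantomSpec(grid_shape=(32, 32, 32), spacing=(3.0, 3.0, 3.0),
                           n_bones=1, n_muscles=1, asymmetry_factor=0.8,
                           seed=29)
        ph = generate_phantom(spec)
        ci = [l.name for l in ph.labels].index("muscle_01")

        def ratio(channels):
            ch = channels[ci]
            nu = ch.shape[1]
            left = np.zeros_like(ch, bool)
            left[:, np.arange(nu) - (nu - 1) / 2.0 < 0] = True
            return volume_ratio(ch, left & (ch > 0), ~left & (ch > 0)).r

        drrs_par, _ = render(ph, default_geometry_for(spec.grid_shape,
                                                      spec.spacing))
        geo = ProjectionGeometry(
            model="pinhole", detector_shape=(48, 48), pixel_pitch=3.0,
            source_detector_distance=1000.0,
            volume_pose=RigidTransform((0, 0, 0), (0.0, 500.0, 0.0)),
        )
        drrs_pin, _ = render(ph, geo, integrator="exact")
        r_par, r_pin = ratio(drrs_par.channels), ratio(drrs_pin.channels)
        assert abs(r_pin - r_par) < 0.02  # magnification bias alone
        v = ph.true_side_volumes["muscle_01"]
        voxelization = abs(v["left"] / v["right"] - 0.8)
        assert abs(r_pin - 0.8) < 0.02 + voxelization

    def test_disjointness_and_zero_denominator(self):
        ch = np.ones((4, 4))
        full = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            volume_ratio(ch, full, full)
        empty = np.zeros((4, 4), bool)
        with pytest.raises(ZeroDivisionError):
            volume_ratio(np.zeros((4, 4)), full, empty)


class TestIcc:
    def test_perfect_agreement(self):
        pairs = [(0.7, 0.7), (0.8, 0.8), (0.9, 0.9), (1.0, 1.0)]
        assert icc(pairs) == pytest.approx(1.0)

    def test_noise_dominated_pairs_have_low_icc(self, rng):
        truth = rng.uniform(0.7, 1.0, 200)  # between-case sd ~ 0.087
        est = truth + rng.normal(0.0, 0.5, 200)  # noise sd >> signal sd
        assert icc(np.stack([est, truth], axis=1)) < 0.3

    def test_four_pair_hand_table(self):
        # direct ANOVA arithmetic for [(9,8),(7,5),(4,3),(6,6)]
        x = np.array([[9.0, 8.0], [7.0, 5.0], [4.0, 3.0], [6.0, 6.0]])
        n, k = 4, 2
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(axis=1, keepdims=True)
                - x.mean(axis=0, keepdims=True) + grand) ** 2).sum() / (
            (n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert icc(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_two_way_absolute_single(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        truth = rng.uniform(0.7, 1.0, 12)
        est = truth + rng.normal(0, 0.02, 12)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": ["est", "truth"] * 12,
            "ratings": np.stack([est, truth], axis=1).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets",
                                       raters="raters", ratings="ratings")
        icc_a1 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(np.stack([est, truth], axis=1)) == pytest.approx(
            icc_a1, abs=1e-10
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc([(1.0, 1.0), (2.0, 2.0)])


class TestEvaluate:
    def test_perfect_decompositions_score_perfectly(self, tiny_manifest):
        decs = {}
        for case in tiny_manifest.split("test"):
            gt = normalize(tiny_manifest.load_drrs(case),
                           tiny_manifest.normalization)
            decs[case.case_id] = DecomposedSet(
                channels=gt, labels=[l.name for l in case.labels],
                raw_or_normalized="normalized",
                normalization=tiny_manifest.normalization,
            )
        report = evaluate(tiny_manifest, decs)
        assert (report.per_structure["psnr_norm"] == PSNR_CAP_DB).all()
        assert (report.per_structure.dropna(subset=["dice"])["dice"] == 1.0).all()
        for _, row in report.volume_ratios.iterrows():
            assert row["r_est"] == pytest.approx(row["r_truth"], abs=1e-2)

    def test_group_mean_recomputable(self, tiny_manifest):
        decs = {}
        for case in tiny_manifest.split("test"):
            gt = normalize(tiny_manifest.load_drrs(case),
                           tiny_manifest.normalization)
            decs[case.case_id] = DecomposedSet(
                channels=gt, labels=[l.name for l in case.labels],
                raw_or_normalized="normalized",
            )
        report = evaluate(tiny_manifest, decs)
        fg = report.per_structure[report.per_structure["group"] != "background"]
        manual = fg.groupby(["case", "group"])["psnr_norm"].mean()
        row = report.group_summary.iloc[0]
        group = row["group"]
        assert row["psnr_norm_mean"] == pytest.approx(
            manual.xs(group, level="group").mean()
        )

    def test_report_round_trips(self, tiny_manifest, tmp_path):
        decs = {}
        for case in tiny_manifest.split("test"):
            gt = normalize(tiny_manifest.load_drrs(case),
                           tiny_manifest.normalization)
            decs[case.case_id] = DecomposedSet(
                channels=gt, labels=[l.name for l in case.labels],
                raw_or_normalized="normalized",
            )
        report = evaluate(tiny_manifest, decs)
        report.save(tmp_path)
        loaded = type(report).load(tmp_path)
        assert loaded.thresholds == report.thresholds
        assert len(loaded.per_structure) == len(report.per_structure)
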