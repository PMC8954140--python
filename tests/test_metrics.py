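"""Metric oracles: brute-force enumerations for every evaluation metric."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lgeseg.io import MVO, SCAR, WALL_CLASSES
from lgeseg.metrics import (UndefinedMetricError, VolumeMeasurements,
                            avd_avdr, bland_altman, boundary_voxels,
                            classification_metrics, dsc, evaluate_cases,
                            hausdorff, mvo_presence_accuracy)


def brute_dsc(p, g, class_set):
    pm = np.isin(p, class_set)
    gm = np.isin(g, class_set)
    if pm.sum() + gm.sum() == 0:
        return 1.0
    return 2 * np.logical_and(pm, gm).sum() / (pm.sum() + gm.sum())


def brute_hausdorff(p, g, class_set, spacing, mode):
    sp = np.asarray(spacing)
    a = np.argwhere(boundary_voxels(np.isin(p, class_set))) * sp
    m = np.argwhere(boundary_voxels(np.isin(g, class_set))) * sp
    d = cdist(a, m)
    fwd = d.min(axis=1).max()
    if mode == "directed":
        return fwd
    return max(fwd, d.min(axis=0).max())


class TestDSC:
    def test_identical_masks(self, random_labelmap):
        lm = random_labelmap(seed=0)
        assert dsc(lm, lm, (SCAR,)) == 1.0

    def test_disjoint_masks(self):
        p = np.zeros((6, 6, 2), np.uint8)
        g = np.zeros((6, 6, 2), np.uint8)
        p[:2, :2, 0] = SCAR
        g[4:, 4:, 1] = SCAR
        assert dsc(p, g, (SCAR,)) == 0.0

    def test_shifted_square_half_overlap(self):
        p = np.zeros((8, 8, 1), np.uint8)
        g = np.zeros((8, 8, 1), np.uint8)
        p[2:4, 2:4, 0] = SCAR
        g[3:5, 2:4, 0] = SCAR
        assert dsc(p, g, (SCAR,)) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4, 2), np.uint8)
        assert dsc(z, z, (MVO,)) == 1.0

    def test_symmetry_and_grid_mismatch(self, random_labelmap):
        a, b = random_labelmap(seed=1), random_labelmap(seed=2)
        assert dsc(a, b, WALL_CLASSES) == dsc(b, a, WALL_CLASSES)
        with pytest.raises(ValueError):
            dsc(a.labels, b.labels[:6], WALL_CLASSES)


class TestHausdorff:
    def test_identical_masks_zero(self, random_labelmap):
        lm = random_labelmap(seed=3)
        if not (lm.labels == SCAR).any():
            pytest.skip("no scar in this draw")
        assert hausdorff(lm, lm, (SCAR,), (1, 1, 1)) == 0.0

    def test_three_four_five_triangle(self):
        p = np.zeros((8, 8, 2), np.uint8)
        g = np.zeros((8, 8, 2), np.uint8)
        p[0, 0, 0] = SCAR
        g[3, 4, 0] = SCAR
        assert hausdorff(p, g, (SCAR,), (1, 1, 1)) == pytest.approx(5.0)

    def test_empty_mask_undefined(self):
        p = np.zeros((4, 4, 2), np.uint8)
        g = np.zeros((4, 4, 2), np.uint8)
        g[1, 1, 1] = SCAR
        with pytest.raises(UndefinedMetricError):
            hausdorff(p, g, (SCAR,), (1, 1, 1))

    def test_symmetric_at_least_directed(self, rng):
        p = (rng.random((10, 10, 4)) < 0.2).astype(np.uint8) * SCAR
        g = (rng.random((10, 10, 4)) < 0.2).astype(np.uint8) * SCAR
        sp = (1.25, 1.25, 5.0)
        d1 = hausdorff(p, g, (SCAR,), sp, mode="directed")
        d2 = hausdorff(g, p, (SCAR,), sp, mode="directed")
        s = hausdorff(p, g, (SCAR,), sp, mode="symmetric")
        assert s >= d1 - 1e-12 and s >= d2 - 1e-12
        assert s == pytest.approx(max(d1, d2), abs=1e-12)


class TestAVD:
    def test_arithmetic_example(self):
        # 120 vs 100 predicted/manual scar voxels, 1000-voxel wall, unit vox
        p = np.zeros((20, 20, 5), np.uint8)
        g = np.zeros((20, 20, 5), np.uint8)
        p.flat[:120] = SCAR
        g.flat[:100] = SCAR
        g.flat[200:1100] = 2  # 900 myocardium + 100 scar = 1000 wall
        avd, avdr = avd_avdr(p, g, SCAR, (1, 1, 1))
        assert avd == pytest.approx(20.0)
        assert avdr == pytest.approx(2.0)

    def test_perfect_prediction(self, random_labelmap):
        lm = random_labelmap(seed=5)
        avd, avdr = avd_avdr(lm, lm, SCAR, (1.5, 1.5, 8.0))
        assert avd == 0.0 and avdr == 0.0

    def test_symmetric_in_arguments(self, random_labelmap):
        a, b = random_labelmap(seed=6), random_labelmap(seed=7)
        assert avd_avdr(a, b, SCAR, (1, 1, 1))[0] == \
            avd_avdr(b, a, SCAR, (1, 1, 1))[0]

    def test_volume_measurements_container(self):
        p = np.zeros((10, 10, 2), np.uint8)
        g = np.zeros((10, 10, 2), np.uint8)
        p.flat[:30] = SCAR
        g.flat[:20] = SCAR
        g.flat[50:130] = 2
        vm = VolumeMeasurements.from_maps(p, g, SCAR, (2, 2, 2))
        assert vm.v_auto == 30 * 8 and vm.v_manual == 20 * 8
        assert vm.v_myo == 100 * 8  # wall = 80 myocardium + 20 scar
        assert vm.avd() == 80.0
        assert vm.avdr() == pytest.approx(10.0)
        with pytest.raises(ValueError):
            VolumeMeasurements(-1.0, 0.0, 0.0)

    def test_avdr_scales_inversely_with_wall(self):
        p = np.zeros((20, 20, 4), np.uint8)
        g = np.zeros((20, 20, 4), np.uint8)
        p.flat[:50] = SCAR
        g.flat[100:300] = 2
        _, avdr1 = avd_avdr(p, g, SCAR, (1, 1, 1))
        g2 = g.copy()
        g2.flat[300:500] = 2  # double the wall
        _, avdr2 = avd_avdr(p, g2, SCAR, (1, 1, 1))
        assert avdr1 == pytest.approx(2 * avdr2)


class TestCohortMetrics:
    def test_mvo_presence_counting(self):
        gts, preds = [], []
        for i in range(10):
            g = np.zeros((6, 6, 3), np.uint8)
            p = np.zeros((6, 6, 3), np.uint8)
            if i < 5:
                g[2, 2, 1] = MVO
            if i < 3 or i >= 8:  # 3 hits among positives, 2 misses as FP
                p[3, 3, 1] = MVO
            preds.append(p)
            gts.append(g)
        # matches: i<3 (both), i in 3..4 (gt only -> miss), 5..7 (neither),
        # 8..9 (pred only -> miss): 3 + 0 + 3 + 0 = 6
        assert mvo_presence_accuracy(preds, gts, "case") == pytest.approx(60.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_slice_level_matches_per_slice_tally(self, seed):
        rng = np.random.default_rng(seed)
        preds = [(rng.random((5, 5, 4)) < 0.1).astype(np.uint8) * MVO
                 for _ in range(6)]
        gts = [(rng.random((5, 5, 4)) < 0.1).astype(np.uint8) * MVO
               for _ in range(6)]
        hits = total = 0
        for p, g in zip(preds, gts):
            for s in range(4):
                hits += int((p[:, :, s] == MVO).any()
                            == (g[:, :, s] == MVO).any())
                total += 1
        assert mvo_presence_accuracy(preds, gts, "slice") == pytest.approx(
            100 * hits / total)

    def test_classification_arithmetic_example(self):
        true = [1] * 4 + [0] * 6
        pred = [1, 1, 1, 0] + [0] * 5 + [1]  # TP=3 FN=1 TN=5 FP=1
        sens, spec, prec, acc = classification_metrics(pred, true)
        assert sens == pytest.approx(75.0)
        assert spec == pytest.approx(83.333333, abs=1e-4)
        assert prec == pytest.approx(75.0)
        assert acc == pytest.approx(80.0)

    def test_all_correct_and_degenerate(self):
        sens, spec, prec, acc = classification_metrics([1, 0, 1], [1, 0, 1])
        assert (sens, spec, prec, acc) == (100.0, 100.0, 100.0, 100.0)
        sens, *_ = classification_metrics([0, 0], [0, 0])
        assert np.isnan(sens)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 2, 30)
        p = rng.integers(0, 2, 30)
        tp = int(((p == 1) & (t == 1)).sum())
        tn = int(((p == 0) & (t == 0)).sum())
        fp = int(((p == 1) & (t == 0)).sum())
        fn = int(((p == 0) & (t == 1)).sum())
        sens, spec, prec, acc = classification_metrics(p, t)
        assert sens == pytest.approx(100 * tp / (tp + fn))
        assert spec == pytest.approx(100 * tn / (tn + fp))
        assert acc == pytest.approx(100 * (tp + tn) / 30)


class TestBlandAltman:
    def test_identical_lists(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0 and ba.lower == 0.0 and ba.upper == 0.0

    def test_differences_123(self):
        ba = bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert ba.bias == pytest.approx(2.0)
        assert ba.lower == pytest.approx(2 - 1.96)
        assert ba.upper == pytest.approx(2 + 1.96)

    def test_translation_invariance_of_differences(self, rng):
        a = rng.random(10) * 100
        m = rng.random(10) * 100
        b1 = bland_altman(a, m)
        b2 = bland_altman(a + 50, m + 50)
        assert b1.bias == pytest.approx(b2.bias)
        assert b1.upper - b1.lower == pytest.approx(b2.upper - b2.lower)


@pytest.mark.parametrize("seed", range(25))
def test_metric_oracles_on_random_masks(seed):
    """DSC exactly and HD to 1e-9 mm against brute-force enumeration."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(6, 14, 3))
    p = rng.integers(0, 5, shape).astype(np.uint8)
    g = rng.integers(0, 5, shape).astype(np.uint8)
    sp = tuple(rng.uniform(0.5, 8.0, 3))
    for class_set in [(SCAR,), (MVO,), WALL_CLASSES]:
        assert dsc(p, g, class_set) == brute_dsc(p, g, class_set)
        if np.isin(p, class_set).any() and np.isin(g, class_set).any():
            for mode in ("directed", "symmetric"):
                assert hausdorff(p, g, class_set, sp, mode) == pytest.approx(
                    brute_hausdorff(p, g, class_set, sp, mode), abs=1e-9)


def test_evaluate_cases_table_layout(random_labelmap):
    lms = [random_labelmap(seed=s) for s in range(4)]
    df = evaluate_cases([l.labels for l in lms], [l.labels for l in lms],
                        (1, 1, 2), case_ids=list("abcd"))
    assert list(df.index) == ["a", "b", "c", "d", "mean"]
    assert df.loc["mean", "myocardium_dsc"] == pytest.approx(1.0)
    assert {"scar_dsc", "mvo_hd", "myocardium_avdr"} <= set(df.columns)
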