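import numpy as np
import pytest

from cardioseg.metrics import (
    aggregate_reports,
    dsc,
    evaluate_case,
    hd95,
    hd_bruteforce,
    precision,
    recall,
    surface_voxels,
)


def random_mask_pair(rng, size):
    g = rng.random((size,) * 3) < 0.3
    p = rng.random((size,) * 3) < 0.3
    return g, p


class TestOverlapMetrics:
    def test_constructed_half_overlap(self):
        # |G| = |P| = 100 with 50 shared voxels
        G = np.zeros((10, 20), dtype=bool)
        P = np.zeros((10, 20), dtype=bool)
        G[:, :10] = True  # 100 voxels
        P[:, 5:15] = True  # 100 voxels, overlap 50
        assert dsc(G, P) == pytest.approx(0.5)
        assert recall(G, P) == pytest.approx(0.5)
        assert precision(G, P) == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:3] = True
        assert dsc(m, m) == 1.0
        other = ~m
        assert dsc(m, other) == 0.0

    def test_subset_relations(self):
        g = np.zeros((6, 6), dtype=bool)
        g[1:5, 1:5] = True
        p = np.zeros_like(g)
        p[2:4, 2:4] = True  # p subset of g
        assert precision(g, p) == 1.0
        assert recall(g, p) < 1.0
        assert recall(p, g) == 1.0  # pred superset of gold

    def test_empty_mask_conventions(self):
        empty = np.zeros((4, 4), dtype=bool)
        full = np.ones((4, 4), dtype=bool)
        assert dsc(empty, empty) == 1.0
        assert dsc(full, empty) == 0.0
        assert np.isnan(recall(empty, full))
        assert np.isnan(precision(full, empty))

    @pytest.mark.parametrize("seed", range(10))
    def test_f1_identity(self, seed):
        rng = np.random.default_rng(seed)
        g, p = random_mask_pair(rng, 8)
        r, pr = recall(g, p), precision(g, p)
        if np.isnan(r) or np.isnan(pr) or (r + pr) == 0:
            return
        assert dsc(g, p) == pytest.approx(2 * pr * r / (pr + r), rel=1e-12)


class TestHD95:
    def test_zero_for_identical(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        assert hd95(m, m, (5, 1, 1)) == 0.0

    def test_inplane_dilation_bound(self):
        from scipy import ndimage

        m = np.zeros((4, 12, 12), dtype=bool)
        m[1:3, 4:8, 4:8] = True
        struct = np.zeros((1, 3, 3), dtype=bool)
        struct[0] = ndimage.generate_binary_structure(2, 2)
        dil = ndimage.binary_dilation(m, structure=struct)
        assert hd95(m, dil, (5.0, 1.0, 1.0), percentile=100) <= np.sqrt(2.0) + 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_distance_transform_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        g, p = random_mask_pair(rng, int(rng.integers(6, 13)))
        if not g.any() or not p.any():
            return
        spacing = (5.0, 1.0, 1.0)
        for percentile in (95.0, 100.0):
            fast = hd95(g, p, spacing, percentile)
            slow = hd_bruteforce(g, p, spacing, percentile)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_symmetry_and_percentile_monotonicity(self):
        rng = np.random.default_rng(3)
        g, p = random_mask_pair(rng, 10)
        spacing = (2.0, 1.0, 1.0)
        assert hd95(g, p, spacing) == pytest.approx(hd95(p, g, spacing))
        values = [hd95(g, p, spacing, q) for q in (100, 95, 75, 50)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_empty_mask_raises(self):
        m = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            hd95(m, np.zeros_like(m), (1, 1, 1))

    def test_axis_permutation_with_spacing(self):
        rng = np.random.default_rng(5)
        g, p = random_mask_pair(rng, 9)
        spacing = (5.0, 1.0, 2.0)
        perm = (2, 0, 1)
        a = hd95(g, p, spacing)
        b = hd95(
            np.transpose(g, perm), np.transpose(p, perm), tuple(spacing[i] for i in perm)
        )
        assert a == pytest.approx(b, rel=1e-12)


class TestEvaluateCase:
    def test_perfect_prediction(self, phantom_case):
        _, lab = phantom_case
        rep = evaluate_case(lab, lab)
        assert len(rep) == 10
        assert (rep["dsc"] == 1.0).all()
        assert (rep["recall"] == 1.0).all()
        assert (rep["precision"] == 1.0).all()
        assert (rep["hd95_mm"] == 0.0).all()

    def test_missing_structure_scores_zero_with_undefined_hd(self, phantom_case):
        _, lab = phantom_case
        pred = lab.data.copy()
        pred[pred == 10] = 0  # drop the SVC entirely
        from cardioseg.imageio import LabelMap

        rep = evaluate_case(lab, LabelMap(pred, lab.spacing)).set_index("structure")
        assert rep.loc["SVC", "dsc"] == 0.0
        assert np.isnan(rep.loc["SVC", "hd95_mm"])
        assert rep.loc["LV", "dsc"] == 1.0

    def test_eroded_prediction_keeps_precision(self, phantom_case):
        from scipy import ndimage
        from cardioseg.imageio import LabelMap

        _, lab = phantom_case
        lv = lab.data == 1
        eroded = ndimage.binary_erosion(lv)
        pred = np.where(eroded, 1, 0).astype(np.int16)
        gold = np.where(lv, 1, 0).astype(np.int16)
        rep = evaluate_case(
            LabelMap(gold, lab.spacing), LabelMap(pred, lab.spacing)
        ).set_index("structure")
        assert rep.loc["LV", "precision"] == 1.0
        assert rep.loc["LV", "recall"] < 1.0
        assert 0 < rep.loc["LV", "dsc"] < 1.0

    def test_aggregate_shapes(self, phantom_case):
        _, lab = phantom_case
        rep = evaluate_case(lab, lab)
        agg = aggregate_reports([rep, rep])
        assert len(agg) == 10
        assert agg["dsc_mean"].eq(1.0).all()
        assert agg["dsc_std"].eq(0.0).all()


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


class TestMetricProperties:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        g=hnp.arrays(bool, (4, 5, 5)),
        p=hnp.arrays(bool, (4, 5, 5)),
    )
    def test_dsc_bounds_symmetry_and_f1_identity(self, g, p):
        d = dsc(g, p)
        assert 0.0 <= d <= 1.0
        assert d == dsc(p, g)
        r, pr = recall(g, p), precision(g, p)
        if not (np.isnan(r) or np.isnan(pr)) and (r + pr) > 0:
            assert d == pytest.approx(2 * pr * r / (pr + r), rel=1e-12)


class TestSurfaceVoxels:
    def test_solid_block_boundary(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        b = surface_voxels(m)
        assert b.sum() == 26  # 27-voxel cube minus its single interior voxel
        assert not b[2, 2, 2]
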