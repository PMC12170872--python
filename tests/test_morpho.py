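"""Segmentation, 3D/2D morphometrics, colocalization, dots and clusters."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_yen

from mitoquant import morpho, synth
from mitoquant.core import ImageStack3D
from mitoquant.morpho import (
    NoCellsError,
    SegmentationResult,
    UndefinedCorrelationError,
    kapur_threshold,
)
from conftest import disk_mask


def _seg_from_labels(labels, dxy=100.0, dz=100.0):
    return SegmentationResult(
        label_map=np.asarray(labels, dtype=int),
        threshold_global=0.0,
        threshold_local_radius_nm=640.0,
        min_object_voxels=1,
        voxel_xy_nm=dxy,
        voxel_z_nm=dz,
    )


# ---------------------------------------------------------------------------
# thresholds vs brute-force oracles


def _otsu_brute(values, nbins=256):
    counts, edges = np.histogram(values, bins=nbins)
    best, best_t = -1.0, edges[0]
    total = counts.sum()
    for t in range(1, nbins):
        w0, w1 = counts[:t].sum(), counts[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        c = 0.5 * (edges[:-1] + edges[1:])
        m0 = (counts[:t] * c[:t]).sum() / w0
        m1 = (counts[t:] * c[t:]).sum() / w1
        var = w0 / total * w1 / total * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, edges[t]
    return best_t


def _yen_brute(values, nbins=256):
    counts, edges = np.histogram(values, bins=nbins)
    p = counts / counts.sum()
    p1 = np.cumsum(p)
    p2 = np.cumsum(p**2)
    best, best_t = -np.inf, edges[0]
    tot2 = p2[-1]
    for t in range(nbins - 1):
        a, b = p2[t], tot2 - p2[t]
        w, wc = p1[t], 1 - p1[t]
        if a <= 0 or b <= 0 or w <= 0 or wc <= 0:
            continue
        crit = -np.log(a * b) + 2 * np.log(w * wc)
        if crit > best:
            best, best_t = crit, edges[t + 1]
    return best_t


def test_global_otsu_matches_between_class_variance_search():
    rng = np.random.default_rng(0)
    img = np.concatenate([rng.normal(40, 5, 4000), rng.normal(180, 20, 2000)])
    t_lib = threshold_otsu(img, nbins=256)
    t_brute = _otsu_brute(img)
    assert abs(t_lib - t_brute) <= (img.max() - img.min()) / 256 + 1e-9


def test_yen_threshold_matches_brute_force_criterion():
    rng = np.random.default_rng(1)
    img = np.concatenate([rng.normal(30, 4, 5000), rng.normal(150, 15, 1500)])
    assert abs(threshold_yen(img, nbins=256) - _yen_brute(img)) <= (
        img.max() - img.min()
    ) / 256 + 1e-9


def test_kapur_threshold_matches_entropy_maximisation():
    rng = np.random.default_rng(2)
    img = np.concatenate([rng.normal(20, 3, 5000), rng.normal(120, 10, 800)])

    # brute-force maximisation of background+foreground entropies
    counts, edges = np.histogram(img, bins=256)
    p = counts / counts.sum()
    best, best_t = -np.inf, edges[0]
    for t in range(255):
        w0, w1 = p[: t + 1].sum(), p[t + 1 :].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        p0 = p[: t + 1] / w0
        p1 = p[t + 1 :] / w1
        h0 = -np.sum(p0[p0 > 0] * np.log(p0[p0 > 0]))
        h1 = -np.sum(p1[p1 > 0] * np.log(p1[p1 > 0]))
        if h0 + h1 > best:
            best, best_t = h0 + h1, edges[t + 1]
    assert kapur_threshold(img) == pytest.approx(best_t, abs=1e-9)


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentation:
    def test_bimodal_stack_recovers_exact_objects(self):
        data = np.full((6, 40, 40), 10.0)
        data[2:4, 5:15, 5:15] = 200.0
        data[2:4, 25:35, 25:35] = 200.0
        stack = ImageStack3D(data=data, voxel_xy_nm=65.0, voxel_z_nm=200.0)
        seg = morpho.segment_mito(stack, subtract_background=False)
        assert seg.n_objects == 2
        assert np.array_equal(seg.label_map > 0, data > 100)
        assert 10.0 < seg.threshold_global < 200.0

    def test_synthetic_stack_objects_recovered(self, cfg):
        stack, truth = synth.make_mito_stack(
            cfg, n_objects=2, shape_spec="ellipsoid", stack_shape=(14, 96, 96)
        )
        seg = morpho.segment_mito(stack, rolling_ball_radius_px=20)
        assert seg.n_objects == 2
        overlap = (seg.label_map > 0) & (truth["label_map"] > 0)
        assert overlap.sum() / (truth["label_map"] > 0).sum() > 0.95

    def test_intensity_rescaling_preserves_mask(self):
        data = np.full((4, 30, 30), 10.0)
        data[1:3, 10:20, 10:20] = 200.0
        s1 = ImageStack3D(data=data, voxel_xy_nm=65.0, voxel_z_nm=200.0)
        s2 = ImageStack3D(data=data * 3.0, voxel_xy_nm=65.0, voxel_z_nm=200.0)
        m1 = morpho.segment_mito(s1, subtract_background=False).label_map > 0
        m2 = morpho.segment_mito(s2, subtract_background=False).label_map > 0
        assert np.array_equal(m1, m2)

    def test_empty_stack_raises(self):
        stack = ImageStack3D(
            data=np.zeros((4, 20, 20)), voxel_xy_nm=65.0, voxel_z_nm=200.0
        )
        with pytest.raises(morpho.NoObjectsError):
            morpho.segment_mito(stack, subtract_background=False)


# ---------------------------------------------------------------------------
# 3D measurements


class TestMeasure3D:
    def test_single_voxel_volume_and_surface(self):
        lab = np.zeros((5, 5, 5), int)
        lab[2, 2, 2] = 1
        obj = morpho.measure_3d(_seg_from_labels(lab, dxy=100.0, dz=200.0))[0]
        assert obj.volume_um3 == pytest.approx(0.1 * 0.1 * 0.2)
        # 2 faces normal to z (0.1*0.1) + 4 faces normal to x/y (0.1*0.2)
        assert obj.surface_um2 == pytest.approx(2 * 0.01 + 4 * 0.02)

    def test_digitized_sphere_volume_within_3pct(self):
        r = 10
        zz, yy, xx = np.mgrid[-12:13, -12:13, -12:13]
        lab = ((zz**2 + yy**2 + xx**2) <= r * r).astype(int)
        obj = morpho.measure_3d(_seg_from_labels(lab))[0]
        assert obj.volume_um3 == pytest.approx(4 / 3 * np.pi, rel=0.03)
        assert obj.branching == pytest.approx(1.0, abs=0.1)
        assert obj.elongation == pytest.approx(1.0, abs=0.05)

    def test_volume_conservation_across_objects(self, cfg):
        stack, truth = synth.make_mito_stack(
            cfg, n_objects=3, shape_spec="tube", stack_shape=(22, 150, 150)
        )
        seg = _seg_from_labels(truth["label_map"], dxy=65.0, dz=200.0)
        objs = morpho.measure_3d(seg)
        voxel_vol = (0.065**2) * 0.2
        total = (truth["label_map"] > 0).sum() * voxel_vol
        assert sum(o.volume_um3 for o in objs) == pytest.approx(total, rel=1e-9)

    def test_branched_shape_less_ellipsoidal_than_tube(self, cfg):
        res = {}
        for shape in ("tube", "branched", "ellipsoid"):
            stack, truth = synth.make_mito_stack(
                cfg, n_objects=1, shape_spec=shape, stack_shape=(22, 100, 100)
            )
            seg = _seg_from_labels(truth["label_map"], dxy=65.0, dz=200.0)
            res[shape] = morpho.measure_3d(seg)[0].branching
        assert res["ellipsoid"] == pytest.approx(1.0, abs=0.1)
        assert res["branched"] < res["tube"]

    def test_rotation_changes_shape_descriptors_little(self):
        zz, yy, xx = np.mgrid[-15:16, -15:16, -15:16]
        ell = ((zz / 6) ** 2 + (yy / 12) ** 2 + (xx / 9) ** 2) <= 1.0
        base = morpho.measure_3d(_seg_from_labels(ell.astype(int)))[0]
        rot = ndi.rotate(
            ell.astype(float), 30.0, axes=(1, 2), order=0, reshape=True
        ) > 0.5
        rotated = morpho.measure_3d(_seg_from_labels(rot.astype(int)))[0]
        assert rotated.elongation == pytest.approx(base.elongation, rel=0.05)
        assert rotated.flatness == pytest.approx(base.flatness, rel=0.05)

    def test_border_touching_object_flagged(self):
        lab = np.zeros((4, 6, 6), int)
        lab[0, :3, :3] = 1
        assert morpho.measure_3d(_seg_from_labels(lab))[0].truncated


# ---------------------------------------------------------------------------
# colocalization and product image


class TestColoc:
    def test_identical_channels_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        ch = rng.random((20, 20))
        assert morpho.pearson_coloc(ch, ch) == pytest.approx(1.0)

    def test_inverted_channel_anticorrelates(self):
        rng = np.random.default_rng(4)
        ch = rng.random((20, 20))
        assert morpho.pearson_coloc(ch, -ch + 5.0) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(100_000), rng.random(100_000)
        assert abs(morpho.pearson_coloc(a, b)) < 0.02

    def test_constant_channel_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            morpho.pearson_coloc(np.ones((5, 5)), np.random.default_rng(0).random((5, 5)))

    def test_product_image_disjoint_supports_zero(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[:5], b[5:] = 2.0, 3.0
        assert not morpho.mercs_product_image(a, b).any()

    def test_product_image_overlap_and_gain(self):
        a = np.full((4, 4), 2.0)
        b = np.full((4, 4), 3.0)
        assert np.allclose(morpho.mercs_product_image(a, b, gain=1.0), 6.0)
        grad1 = np.linspace(0, 1, 16).reshape(4, 4)
        grad2 = np.linspace(1, 0, 16).reshape(4, 4)
        assert np.allclose(
            morpho.mercs_product_image(grad1, grad2, gain=2.0), grad1 * grad2 * 2.0
        )


# ---------------------------------------------------------------------------
# 2D measurements, PLA dots, clusters


class TestMeasure2D:
    def test_circle_has_unit_aspect_ratio(self):
        df = morpho.measure_2d(disk_mask(64, 20), px_um=0.1)
        assert len(df) == 1
        assert df.loc[0, "aspect_ratio"] == pytest.approx(1.0, rel=0.02)
        assert df.loc[0, "area_um2"] == pytest.approx(np.pi * 2.0**2, rel=0.02)

    def test_two_to_one_ellipse_aspect_ratio(self):
        yy, xx = np.mgrid[:80, :80]
        ell = ((yy - 40) / 10.0) ** 2 + ((xx - 40) / 20.0) ** 2 <= 1.0
        df = morpho.measure_2d(ell)
        assert df.loc[0, "aspect_ratio"] == pytest.approx(2.0, rel=0.05)


class TestPlaDots:
    def _image_with_dots(self, n_dots, n_nuclei, size=200):
        img = np.zeros((size, size))
        nuc = np.zeros((size, size))
        rng = np.random.default_rng(6)
        step = size // max(n_dots, 1)
        for i in range(n_dots):
            r, c = 5 + (i * 13) % (size - 10), 5 + (i * 29) % (size - 10)
            img[r : r + 2, c : c + 2] = 100.0
        for i in range(n_nuclei):
            rr, cc = np.mgrid[:size, :size]
            cy, cx = 20 + (i % 5) * 38, 20 + (i // 5) * 38
            nuc[(rr - cy) ** 2 + (cc - cx) ** 2 <= 49] = 200.0
        return img, nuc

    def test_no_supra_threshold_pixels_count_zero(self):
        img, nuc = self._image_with_dots(0, 4)
        res = morpho.count_pla_dots(img, nuc, dot_threshold=50.0)
        assert res["n_dots"] == 0 and res["dots_per_cell"] == 0.0

    def test_thirty_dots_ten_nuclei_gives_three(self):
        img, nuc = self._image_with_dots(30, 10)
        res = morpho.count_pla_dots(img, nuc, dot_threshold=50.0)
        assert res["n_dots"] == 30 and res["n_cells"] == 10
        assert res["dots_per_cell"] == pytest.approx(3.0)

    def test_knockdown_like_condition_normalizes_to_0p3(self):
        ctrl_img, ctrl_nuc = self._image_with_dots(30, 10)
        ctrl = morpho.count_pla_dots(ctrl_img, ctrl_nuc, dot_threshold=50.0)
        kd_img, kd_nuc = self._image_with_dots(9, 10)
        kd = morpho.count_pla_dots(
            kd_img, kd_nuc, dot_threshold=50.0, reference=ctrl["dots_per_cell"]
        )
        assert kd["normalized"] == pytest.approx(0.3)

    def test_zero_nuclei_raises(self):
        img, _ = self._image_with_dots(5, 1)
        with pytest.raises(NoCellsError):
            morpho.count_pla_dots(img, np.zeros_like(img), dot_threshold=50.0)


class TestClusterSizes:
    def test_single_disk_single_cluster_with_analytic_area(self):
        rng = np.random.default_rng(7)
        img = rng.normal(10.0, 2.0, (40, 40))
        disk = disk_mask(40, 5)
        img[disk] = rng.normal(100.0, 10.0, disk.sum())
        df = morpho.cluster_sizes(img, sigma=0.8)
        assert len(df) == 1
        # lower bound: analytic disk area; upper bound: disk grown by the
        # blur halo the entropy threshold includes (sigma-scale ring)
        analytic = np.pi * 25.0
        halo_bound = np.pi * (5.0 + 2.0) ** 2
        assert analytic <= df.loc[0, "area_px2"] <= halo_bound

    def test_two_overlapping_disks_split_into_two(self):
        rng = np.random.default_rng(8)
        img = rng.normal(10.0, 2.0, (40, 60))
        yy, xx = np.mgrid[:40, :60]
        both = ((yy - 20) ** 2 + (xx - 26) ** 2 <= 25) | (
            (yy - 20) ** 2 + (xx - 34) ** 2 <= 25
        )
        img[both] = rng.normal(100.0, 10.0, both.sum())
        df = morpho.cluster_sizes(img, sigma=0.8, min_cluster_px2=20)
        assert len(df) == 2
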