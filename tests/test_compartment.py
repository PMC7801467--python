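"""ROI sizing, heatmap accumulation, radial profiles, cubic fits — vs oracles."""

import math

import numpy as np
import pytest

from costripe import COMap
from costripe.compartment import (
    CubicFit,
    EmptyHeatmapError,
    Heatmap,
    InsufficientGeometryError,
    NoLabelOverlapError,
    QuantConfig,
    RadialProfile,
    ROISpec,
    accumulate_heatmap,
    compute_roi_size,
    fit_cubic,
    mean_blob_diameter,
    population_heatmap,
    radial_profile,
    select_blobs_for_layer,
)
from costripe.segmentation import BlobSet


def _blobset(blob_centers, interblob_centers, upx=10.0, shape=(100, 100),
             sources=None):
    """Hand-built BlobSet carrying only center geometry."""
    bs = BlobSet(labels=np.zeros(shape, dtype=int), um_per_px=upx)
    bs.blob_centers = {
        i + 1: np.asarray(c, dtype=float).reshape(-1, 2)
        for i, c in enumerate(blob_centers)
    }
    bs.interblob_centers = np.asarray(interblob_centers, dtype=float).reshape(-1, 2)
    if sources is not None:
        bs.interblob_center_sources = np.asarray(sources, dtype=int).reshape(-1, 2)
    return bs


def _heatmap(grid, upx=10.0, source="co"):
    grid = np.asarray(grid, dtype=float)
    return Heatmap(grid=grid / grid.max() if grid.max() > 0 else grid,
                   um_per_px=upx, normalized=True, n_blobs_used=1,
                   mean_blob_diameter_um=float("nan"), source=source)


def brute_force_profile(hm, roi, cfg):
    """Independent per-pixel reimplementation of the radial-profile rule."""
    c = hm.side_px // 2
    R = roi.side_um / 2
    best = None
    for a in cfg.angles_deg:
        th = math.radians(a)
        members = []
        for r in range(hm.side_px):
            for col in range(hm.side_px):
                dx = (col - c) * hm.um_per_px
                dy = -(r - c) * hm.um_per_px
                u = dx * math.cos(th) + dy * math.sin(th)
                v = -dx * math.sin(th) + dy * math.cos(th)
                eps = 1e-6
                if -eps <= u <= R + eps and abs(v) <= cfg.window_width_um / 2 + eps:
                    members.append((r, col))
        if not members:
            continue
        mean = np.mean([hm.grid[r, col] for r, col in members])
        if best is None or mean > best[0] + 1e-15:
            best = (mean, a, members)
    mean, angle, members = best
    nb = cfg.n_profile_bins
    sums = np.zeros(nb)
    counts = np.zeros(nb)
    for r, col in members:
        dx = (col - c) * hm.um_per_px
        dy = -(r - c) * hm.um_per_px
        rad = math.hypot(dx, dy)
        if rad > R:
            continue
        k = max(1, min(nb, math.ceil(rad / (R / nb))))
        sums[k - 1] += hm.grid[r, col]
        counts[k - 1] += 1
    vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    vals = vals / np.nanmax(vals)
    return angle, vals


class TestComputeROISize:
    def test_full_ring_of_interblob_centers(self):
        angles = np.deg2rad(np.arange(0, 360, 20))
        center = np.array([500.0, 500.0])
        ring = center + 250.0 * np.column_stack([np.cos(angles), np.sin(angles)])
        bs = _blobset([center], ring)
        roi = compute_roi_size(bs, QuantConfig())
        assert roi.side_um == pytest.approx(500.0)
        assert roi.grand_average_um == pytest.approx(250.0)

    def test_two_centers_single_midpoint(self):
        bs = _blobset([[200.0, 500.0], [700.0, 500.0]], [[450.0, 500.0]])
        roi = compute_roi_size(bs, QuantConfig())
        assert roi.grand_average_um == pytest.approx(250.0)
        assert roi.side_um == pytest.approx(500.0)

    def test_square_lattice_centerline_matches_ray_arithmetic(self):
        # centers on an exact square lattice; analytic centerlines are the
        # grid lines halfway between rows/columns of centers
        s_um, upx = 300.0, 10.0
        shape = (121, 121)
        centers = [
            [x, y]
            for x in (300.0, 600.0, 900.0)
            for y in (300.0, 600.0, 900.0)
        ]
        mask = np.zeros(shape, dtype=bool)
        for line_um in (450.0, 750.0):
            idx = int(round(line_um / upx))
            mask[idx, :] = True
            mask[:, idx] = True
        bs = _blobset([centers[4]], np.empty((0, 2)), upx=upx, shape=shape)
        cfg = QuantConfig()
        roi = compute_roi_size(bs, cfg, centerline_mask=mask, max_radius_um=2000.0)
        # oracle: distance from the central center (600,600) to the nearest
        # analytic line along each ray heading
        dists = []
        for a in cfg.angles_deg:
            th = math.radians(a)
            cands = []
            for line in (450.0, 750.0):
                if abs(math.cos(th)) > 1e-12:
                    t = (line - 600.0) / math.cos(th)
                    if t > 0:
                        cands.append(t)
                if abs(math.sin(th)) > 1e-12:
                    t = (line - 600.0) / math.sin(th)
                    if t > 0:
                        cands.append(t)
            dists.append(min(cands))
        assert roi.grand_average_um == pytest.approx(np.mean(dists), rel=0.05)

    def test_no_geometry_raises(self):
        bs = _blobset([[100.0, 100.0]], np.empty((0, 2)))
        with pytest.raises(InsufficientGeometryError):
            compute_roi_size(bs, QuantConfig())


class TestAccumulateHeatmap:
    def test_uniform_map_gives_all_ones(self):
        img = COMap(np.full((50, 50), 2.5), um_per_px=10.0)
        roi = ROISpec(side_um=110.0, side_px=11)
        hm = accumulate_heatmap(img, [[250.0, 250.0], [150.0, 150.0]], roi)
        assert np.allclose(hm.grid, 1.0)
        assert hm.n_blobs_used == 2

    def test_single_bright_pixel_at_center(self):
        arr = np.zeros((21, 21))
        arr[10, 10] = 5.0
        img = COMap(arr, um_per_px=10.0)
        roi = ROISpec(side_um=90.0, side_px=9)
        hm = accumulate_heatmap(img, [[100.0, 100.0]], roi)
        assert hm.grid[4, 4] == 1.0
        assert hm.grid.sum() == 1.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        img = COMap(rng.uniform(size=(60, 60)), um_per_px=10.0)
        centers = [[200.0, 300.0], [350.0, 250.0]]
        roi = ROISpec(side_um=150.0, side_px=15)
        hm = accumulate_heatmap(img, centers, roi)
        acc = np.zeros((15, 15))
        for x, y in centers:
            r, c = int(round(y / 10.0)), int(round(x / 10.0))
            acc += img.intensity[r - 7 : r + 8, c - 7 : c + 8]
        acc /= acc.max()
        assert np.abs(hm.grid - acc).max() < 1e-12

    def test_out_of_image_centers_excluded(self):
        img = COMap(np.ones((30, 30)), um_per_px=10.0)
        roi = ROISpec(side_um=110.0, side_px=11)
        hm = accumulate_heatmap(img, [[150.0, 150.0], [10.0, 10.0]], roi)
        assert hm.n_blobs_used == 1
        with pytest.raises(EmptyHeatmapError):
            accumulate_heatmap(img, [[10.0, 10.0]], roi)

    def test_mean_blob_diameter_uses_only_included_blobs(self):
        img = COMap(np.ones((30, 30)), um_per_px=10.0)
        roi = ROISpec(side_um=110.0, side_px=11)
        hm = accumulate_heatmap(
            img, [[150.0, 150.0], [10.0, 10.0]], roi,
            blob_diameters_um=[200.0, 900.0],
        )
        assert hm.mean_blob_diameter_um == 200.0


class TestSelectBlobs:
    def _scene(self):
        rng = np.random.default_rng(1)
        labels = np.zeros((80, 80), dtype=int)
        bs = BlobSet(labels=labels, um_per_px=10.0)
        bs.blob_centers = {
            1: np.array([[200.0, 200.0]]),
            2: np.array([[600.0, 600.0]]),
        }
        return bs

    def test_label_everywhere_selects_all(self):
        bs = self._scene()
        rng = np.random.default_rng(0)
        fluor = COMap(1.0 + 0.01 * rng.uniform(size=(80, 80)), um_per_px=10.0)
        roi = ROISpec(side_um=110.0, side_px=11)
        # uniform bright label: median + 2 MAD is barely above the median,
        # every ROI mean with positive offset clears it
        fluor.intensity[15:26, 15:26] += 1.0
        fluor.intensity[55:66, 55:66] += 1.0
        sel = select_blobs_for_layer(bs, fluor, roi)
        assert set(sel) == {0, 1}

    def test_corner_label_selects_corner_blob_only(self):
        bs = self._scene()
        base = np.zeros((80, 80))
        base[10:31, 10:31] = 1.0  # covers the first blob's ROI only
        fluor = COMap(base, um_per_px=10.0)
        roi = ROISpec(side_um=110.0, side_px=11)
        sel = select_blobs_for_layer(bs, fluor, roi)
        assert list(sel) == [0]

    def test_zero_label_raises(self):
        bs = self._scene()
        fluor = COMap(np.zeros((80, 80)), um_per_px=10.0)
        roi = ROISpec(side_um=110.0, side_px=11)
        with pytest.raises(NoLabelOverlapError):
            select_blobs_for_layer(bs, fluor, roi)


class TestRadialProfile:
    def test_uniform_heatmap_all_bins_one_smallest_angle(self):
        hm = _heatmap(np.ones((41, 41)))
        roi = ROISpec(side_um=410.0, side_px=41)
        prof = radial_profile(hm, roi, QuantConfig())
        assert prof.chosen_angle_deg == 0
        assert np.allclose(prof.bin_values, 1.0)

    def test_radially_symmetric_decreasing(self):
        side = 41
        c = side // 2
        ys, xs = np.mgrid[0:side, 0:side]
        r = np.hypot(xs - c, ys - c)
        hm = _heatmap(np.exp(-r / 10))
        roi = ROISpec(side_um=410.0, side_px=side)
        cfg = QuantConfig()
        # all window means agree for a radially symmetric map
        from costripe.compartment import _window_coords

        dx, dy = _window_coords(hm)
        means = []
        R = roi.side_um / 2
        for a in cfg.angles_deg:
            th = math.radians(a)
            u = dx * math.cos(th) + dy * math.sin(th)
            v = -dx * math.sin(th) + dy * math.cos(th)
            inside = (u >= 0) & (u <= R) & (np.abs(v) <= cfg.window_width_um / 2)
            means.append(hm.grid[inside].mean())
        # equal up to pixel rasterization of the rotated rectangles
        assert np.ptp(means) < 0.01
        prof = radial_profile(hm, roi, cfg)
        finite = prof.bin_values[np.isfinite(prof.bin_values)]
        assert np.all(np.diff(finite) < 0)

    def test_wedge_brightened_window_chosen_and_matches_oracle(self):
        # wedge centered on an in-grid heading (60°); brightness falls off
        # smoothly with angular distance so the centered window wins clearly
        side = 41
        c = side // 2
        ys, xs = np.mgrid[0:side, 0:side]
        ang = np.degrees(np.arctan2(-(ys - c), xs - c)) % 360
        delta = np.abs((ang - 60 + 180) % 360 - 180)
        grid = np.ones((side, side)) + 2.0 * np.exp(-((delta / 25.0) ** 2))
        hm = _heatmap(grid)
        roi = ROISpec(side_um=410.0, side_px=side)
        cfg = QuantConfig()
        prof = radial_profile(hm, roi, cfg)
        assert prof.chosen_angle_deg == 60
        oracle_angle, oracle_vals = brute_force_profile(hm, roi, cfg)
        assert oracle_angle == 60
        np.testing.assert_allclose(prof.bin_values, oracle_vals, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_random_heatmaps(self, seed):
        rng = np.random.default_rng(seed)
        side = 33
        hm = _heatmap(rng.uniform(size=(side, side)))
        roi = ROISpec(side_um=side * 10.0, side_px=side)
        cfg = QuantConfig()
        prof = radial_profile(hm, roi, cfg)
        oracle_angle, oracle_vals = brute_force_profile(hm, roi, cfg)
        assert prof.chosen_angle_deg == oracle_angle
        np.testing.assert_allclose(prof.bin_values, oracle_vals, atol=1e-9)

    def test_rotation_equivariance(self):
        # a 90° scene rotation maps the angle grid onto itself only when the
        # step divides 90, so the property is exercised at a 30° step
        rng = np.random.default_rng(5)
        side = 41
        grid = rng.uniform(size=(side, side))
        hm = _heatmap(grid)
        hm_rot = _heatmap(np.rot90(grid, k=1))  # +90° in x-right / y-up
        roi = ROISpec(side_um=side * 10.0, side_px=side)
        cfg = QuantConfig(angle_step_deg=30)
        p0 = radial_profile(hm, roi, cfg)
        p1 = radial_profile(hm_rot, roi, cfg)
        assert (p0.chosen_angle_deg + 90) % 360 == p1.chosen_angle_deg % 360
        np.testing.assert_allclose(p0.bin_values, p1.bin_values, atol=1e-6)

    def test_rotation_equivariance_180_at_default_step(self):
        rng = np.random.default_rng(8)
        side = 33
        grid = rng.uniform(size=(side, side))
        hm = _heatmap(grid)
        hm_rot = _heatmap(np.rot90(grid, k=2))
        roi = ROISpec(side_um=side * 10.0, side_px=side)
        cfg = QuantConfig()
        p0 = radial_profile(hm, roi, cfg)
        p1 = radial_profile(hm_rot, roi, cfg)
        assert (p0.chosen_angle_deg + 180) % 360 == p1.chosen_angle_deg % 360
        np.testing.assert_allclose(p0.bin_values, p1.bin_values, atol=1e-6)

    def test_window_wider_than_heatmap_rejected(self):
        hm = _heatmap(np.ones((11, 11)))
        roi = ROISpec(side_um=110.0, side_px=11)
        with pytest.raises(ValueError):
            radial_profile(hm, roi, QuantConfig(window_width_um=500.0))


class TestCubicFit:
    def _profile(self, values):
        nb = len(values)
        return RadialProfile(
            bin_values=np.asarray(values, dtype=float),
            bin_centers=(np.arange(1, nb + 1) - 0.5) / nb,
            chosen_angle_deg=0,
            window_width_um=200.0,
        )

    def test_exact_recovery_of_planted_cubic(self):
        x = (np.arange(1, 21) - 0.5) / 20
        y = 0.5 * x**3 - x**2 + 0.2 * x + 1.0
        fit = fit_cubic(self._profile(y))
        assert fit.a == pytest.approx(0.5, abs=1e-9)
        assert fit.b == pytest.approx(-1.0, abs=1e-9)
        assert fit.c == pytest.approx(0.2, abs=1e-9)
        assert fit.d == pytest.approx(1.0, abs=1e-9)
        assert fit.residual_sse < 1e-18

    def test_constant_data(self):
        fit = fit_cubic(self._profile(np.full(20, 0.7)))
        for coef, want in zip((fit.a, fit.b, fit.c, fit.d), (0, 0, 0, 0.7)):
            assert coef == pytest.approx(want, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(size=20)
        prof = self._profile(y)
        fit = fit_cubic(prof)
        X = np.vander(prof.bin_centers, 4)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose([fit.a, fit.b, fit.c, fit.d], beta, atol=1e-9)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_cubic(self._profile([1.0, 0.5, 0.2]))


class TestPopulationHeatmap:
    def test_single_heatmap_unchanged(self):
        hm = _heatmap(np.random.default_rng(0).uniform(size=(32, 32)))
        out = population_heatmap([hm])
        np.testing.assert_allclose(out.grid, hm.grid, atol=1e-12)

    def test_two_identical_heatmaps_equal_input(self):
        hm = _heatmap(np.random.default_rng(1).uniform(size=(32, 32)))
        out = population_heatmap([hm, hm])
        np.testing.assert_allclose(out.grid, hm.grid, atol=1e-12)

    def test_mixed_sizes_match_resample_oracle(self):
        rng = np.random.default_rng(2)
        small = _heatmap(rng.uniform(size=(64, 64)))
        large = _heatmap(rng.uniform(size=(128, 128)))
        out = population_heatmap([small, large])
        from skimage.transform import resize

        up = resize(small.grid, (128, 128), order=1, preserve_range=True,
                    anti_aliasing=False)
        acc = up + large.grid
        acc /= acc.max()
        np.testing.assert_allclose(out.grid, acc, atol=1e-12)

    def test_mixed_sources_rejected(self):
        a = _heatmap(np.ones((8, 8)), source="co")
        b = _heatmap(np.ones((8, 8)), source="fluorescence")
        with pytest.raises(ValueError):
            population_heatmap([a, b])


class TestMeanBlobDiameter:
    def test_circle_of_radius_142_gives_284(self):
        assert mean_blob_diameter([math.pi * 142.0**2]) == pytest.approx(284.0)

    def test_square_blob_analytic(self):
        s = 123.0
        assert mean_blob_diameter([s * s]) == pytest.approx(2 * s / math.sqrt(math.pi))

    def test_two_blobs_average(self):
        areas = [math.pi * 100.0**2, math.pi * 150.0**2]
        assert mean_blob_diameter(areas) == pytest.approx(250.0)
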