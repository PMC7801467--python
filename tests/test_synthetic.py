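"""Generator contracts: determinism, planted geometry, ground-truth consistency."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from costripe import COSceneParams, LabelFieldParams, LaminarParams
from costripe.synthetic import (
    generate_co_map,
    generate_label_field,
    generate_laminar_section,
    generate_landmark_pair,
    generate_oi_conditions,
)


def _scene(**kw):
    base = dict(seed=3, shading_amplitude=0.0, noise_sd=0.0)
    base.update(kw)
    return COSceneParams(**base)


class TestCOMap:
    def test_same_seed_bit_identical(self):
        p = _scene(shading_amplitude=0.2, noise_sd=0.05, elongated_blob_prob=0.2)
        a, ta = generate_co_map(p)
        b, tb = generate_co_map(p)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(ta.blob_mask, tb.blob_mask)
        assert np.array_equal(ta.blob_centers, tb.blob_centers)

    def test_spacing_larger_than_image_gives_uniform_bright_map(self):
        p = _scene(image_size_px=(64, 64), blob_spacing_um=10000.0,
                   blob_diameter_um=300.0)
        co, truth = generate_co_map(p)
        assert not truth.blob_mask.any()
        assert truth.blob_centers.shape == (0, 2)
        assert np.all(co.intensity == co.intensity[0, 0])

    def test_mean_equivalent_diameter_hits_target(self):
        # target the printed 284 µm case diameter; fully-rendered planted
        # masks (border blobs are clipped by design) land within 2% of it
        p = _scene(blob_diameter_um=284.0)
        _, truth = generate_co_map(p)
        lbl, n = ndimage.label(truth.blob_mask)
        assert n > 10
        border = set(
            np.unique(
                np.concatenate([lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]])
            )
        )
        areas = ndimage.sum_labels(truth.blob_mask, lbl, np.arange(1, n + 1))
        interior = np.array(
            [a for i, a in enumerate(areas, 1) if i not in border]
        )
        assert len(interior) > 10
        diam = 2 * np.sqrt(interior * p.um_per_px**2 / np.pi)
        assert abs(diam.mean() - 284.0) / 284.0 < 0.02

    def test_ground_truth_consistency(self):
        p = _scene(elongated_blob_prob=0.15, seed=5)
        co, truth = generate_co_map(p)
        upx = p.um_per_px
        rows = np.clip(np.round(truth.blob_centers[:, 1] / upx).astype(int), 0,
                       co.shape[0] - 1)
        cols = np.clip(np.round(truth.blob_centers[:, 0] / upx).astype(int), 0,
                       co.shape[1] - 1)
        assert truth.blob_mask[rows, cols].all(), "every center inside blob mask"
        assert not (truth.interblob_centerline_mask & truth.blob_mask).any()
        assert np.array_equal(truth.compartment_of_pixel == 1, truth.blob_mask)

    def test_darker_is_blob(self, clean_scene):
        _, co, truth = clean_scene
        assert co.intensity[truth.blob_mask].mean() < co.intensity[~truth.blob_mask].mean()

    def test_nearest_neighbor_spacing_within_10pct(self):
        p = _scene(lattice_jitter_frac=0.15, seed=9)
        _, truth = generate_co_map(p)
        tree = cKDTree(truth.blob_centers)
        d, _ = tree.query(truth.blob_centers, k=2)
        assert abs(d[:, 1].mean() - p.blob_spacing_um) / p.blob_spacing_um < 0.10

    def test_diameter_must_be_below_spacing(self):
        with pytest.raises(ValueError):
            COSceneParams(blob_spacing_um=300.0, blob_diameter_um=300.0)

    def test_elongated_blobs_carry_two_planted_minima(self):
        p = _scene(elongated_blob_prob=1.0, seed=2)
        co, truth = generate_co_map(p)
        multi = [g for g in truth.center_groups if len(g) == 2]
        assert multi, "pairing produced elongated blobs"
        upx = p.um_per_px
        for g in multi[:5]:
            for ci in g:
                x, y = truth.blob_centers[ci]
                r, c = int(round(y / upx)), int(round(x / upx))
                sl = np.s_[max(r - 3, 0) : r + 4, max(c - 3, 0) : c + 4]
                window = co.intensity[sl]
                rr, cc = np.unravel_index(np.argmin(window), window.shape)
                # the local intensity minimum sits at the planted peak, up
                # to rasterization of the off-grid center position
                dist_px = np.hypot(rr + sl[0].start - y / upx,
                                   cc + sl[1].start - x / upx)
                assert dist_px <= 2.0


class TestLabelField:
    def test_blob_mass_monotone_in_rho(self, clean_scene):
        _, _, truth = clean_scene
        fractions = []
        for rho in (0.1, 0.5, 0.9):
            lp = LabelFieldParams(preference_rho=rho, seed=21, noise_sd=0.0)
            fluor, _ = generate_label_field(truth, lp)
            above = fluor.intensity - lp.background_level
            fractions.append(above[truth.blob_mask].sum() / above.sum())
        assert fractions[0] < fractions[1] < fractions[2]

    def test_pure_blob_preference_mass_in_dilated_mask(self, clean_scene):
        params, _, truth = clean_scene
        lp = LabelFieldParams(preference_rho=1.0, seed=4, noise_sd=0.0)
        fluor, _ = generate_label_field(truth, lp)
        dil_px = int(round(lp.patch_sigma_um / params.um_per_px))
        dilated = ndimage.binary_dilation(truth.blob_mask, iterations=dil_px)
        above = fluor.intensity - lp.background_level
        assert above[dilated].sum() / above.sum() >= 0.90

    def test_indifferent_mass_matches_area_fraction(self, clean_scene):
        params, _, truth = clean_scene
        lp = LabelFieldParams(preference_rho=0.5, seed=6, noise_sd=0.0,
                              n_patches=400)
        fluor, _ = generate_label_field(truth, lp)
        above = fluor.intensity - lp.background_level
        blob_frac = above[truth.blob_mask].sum() / above.sum()
        # restrict the area fraction to the patch zone the field is confined to
        xs = np.arange(truth.blob_mask.shape[1]) * params.um_per_px
        ys = np.arange(truth.blob_mask.shape[0]) * params.um_per_px
        cx, cy = xs[-1] / 2, ys[-1] / 2
        zone = (
            (np.abs(xs[None, :] - cx) <= lp.field_extent_um / 2)
            & (np.abs(ys[:, None] - cy) <= lp.field_extent_um / 2)
        )
        area_frac = truth.blob_mask[zone].mean()
        assert abs(blob_frac - area_frac) < 0.05

    def test_zero_amplitude_gives_constant_background(self, clean_scene):
        _, _, truth = clean_scene
        lp = LabelFieldParams(patch_amplitude=0.0, seed=1, noise_sd=0.0)
        fluor, _ = generate_label_field(truth, lp)
        assert np.allclose(fluor.intensity, lp.background_level)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LabelFieldParams(preference_rho=1.5)

    def test_same_seed_identical(self, clean_scene):
        _, _, truth = clean_scene
        lp = LabelFieldParams(preference_rho=0.7, seed=12, noise_sd=0.02)
        a, pa = generate_label_field(truth, lp)
        b, pb = generate_label_field(truth, lp)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.array_equal(pa, pb)


class TestLaminarSection:
    def test_zero_amplitudes_give_zero_image(self):
        p = LaminarParams(layer_amplitudes=(0,) * 7, noise_sd=0.0, seed=0)
        section, _ = generate_laminar_section(p)
        assert np.all(section.intensity == 0)

    def test_thin_stripe_template_l4b_band_empty(self):
        # thin-stripe-like case: zero amplitude planted in the L4B band
        amps = [0.2, 0.9, 0.3, 0.0, 0.25, 0.3, 0.35]
        p = LaminarParams(layer_amplitudes=amps, noise_sd=0.0, seed=0)
        section, ann = generate_laminar_section(p)
        n_rows = section.shape[0]
        depth = (np.arange(n_rows) + 0.5) / n_rows
        i = list(ann.layer_names).index("L4B")
        lo = ann.layer_boundaries_frac[i - 1]
        hi = ann.layer_boundaries_frac[i]
        band = (depth >= lo) & (depth < hi)
        # keep away from the discretized boundary rows
        inner = band & (depth > lo + 0.01) & (depth < hi - 0.01)
        assert np.allclose(section.intensity[inner], 0.0, atol=1e-12)
        assert section.intensity[~band].mean() > 0.1

    def test_column_profile_equals_step_function(self):
        p = LaminarParams(noise_sd=0.0, seed=0)
        section, ann = generate_laminar_section(p)
        profile = section.intensity.mean(axis=1)
        depth = (np.arange(section.shape[0]) + 0.5) / section.shape[0]
        expected = np.asarray(p.layer_amplitudes)[ann.layer_of_depth(depth)]
        assert np.allclose(profile, expected)

    def test_non_increasing_boundaries_rejected(self):
        with pytest.raises(ValueError):
            LaminarParams(layer_boundaries_frac=(0.3, 0.2),
                          layer_amplitudes=(1, 1, 1), layer_names=("a", "b", "c"))

    def test_same_seed_identical(self):
        p = LaminarParams(noise_sd=0.1, seed=5)
        a, _ = generate_laminar_section(p)
        b, _ = generate_laminar_section(p)
        assert np.array_equal(a.intensity, b.intensity)


class TestOIConditions:
    def test_zero_noise_zero_response_frames_equal_baseline(self):
        maps = [np.random.default_rng(0).normal(size=(16, 16)) for _ in range(3)]
        stack = generate_oi_conditions(3, maps, baseline_level=2.0, noise_sd=0.0,
                                       seed=1, response_amplitude=0.0)
        for f in stack.frames.values():
            assert np.allclose(f, stack.baseline)

    def test_difference_of_noiseless_frames_is_response_times_domain_diff(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 32, 32))
        stack = generate_oi_conditions(2, [a, b], baseline_level=1.0, noise_sd=0.0,
                                       seed=0, response_amplitude=0.7)
        diff = stack.frames["cond0"] - stack.frames["cond1"]
        assert np.allclose(diff, 0.7 * (a - b))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            generate_oi_conditions(2, [np.zeros((4, 4)), np.zeros((5, 4))], 1.0, 0.0, 0)

    def test_same_seed_identical(self):
        maps = [np.ones((8, 8)), np.zeros((8, 8))]
        s1 = generate_oi_conditions(2, maps, 1.0, 0.3, seed=9)
        s2 = generate_oi_conditions(2, maps, 1.0, 0.3, seed=9)
        for k in s1.frames:
            assert np.array_equal(s1.frames[k], s2.frames[k])
        assert np.array_equal(s1.baseline, s2.baseline)


class TestLandmarkPairs:
    def test_identity_warp_points_coincide(self):
        src, dst, _ = generate_landmark_pair(6, lambda p: p, seed=0)
        assert np.array_equal(src.points, dst.points)

    def test_translation_applied_exactly(self):
        shift = np.array([10.0, -4.0])
        src, dst, _ = generate_landmark_pair(5, lambda p: p + shift, seed=1)
        assert np.allclose(dst.points - src.points, shift)

    def test_planted_nonlinear_warp_verified_pointwise(self):
        warp = lambda p: p + 15.0 * np.sin(p / 200.0)
        src, dst, returned = generate_landmark_pair(12, warp, seed=2)
        assert returned is warp
        assert np.allclose(dst.points, warp(src.points))

    def test_draws_are_never_collinear(self):
        for seed in range(20):
            src, _, _ = generate_landmark_pair(3, lambda p: p, seed=seed)
            centered = src.points - src.points.mean(axis=0)
            assert np.linalg.svd(centered, compute_uv=False)[1] > 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            generate_landmark_pair(2, lambda p: p, seed=0)
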