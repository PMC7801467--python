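"""Seeded synthetic cortical scenes with exported ground truth.

Primary visual cortex (V1) shows a quasi-regular mosaic of cytochrome-oxidase
(CO) rich patches ("blobs") separated by CO-pale tissue ("interblobs").  The
analysis pipeline in this package quantifies where fluorescently labeled
feedback axons terminate relative to that mosaic.  Because the histology it
was designed for is not publicly deposited, every stage is validated against
the generators in this module, which emulate the statistical structure the
analysis assumes and export the planted ground truth:

``generate_co_map``
    a jittered hexagonal blob lattice rendered as a dark-blob CO stain, with
    optional elongated (two-peaked) blobs, multiplicative staining shading
    and additive noise;
``generate_label_field``
    a patchy fluorescent terminal field with a controllable blob-vs-interblob
    preference ``rho``;
``generate_laminar_section``
    a pia-to-white-matter section with planted per-layer label amplitudes;
``generate_oi_conditions``
    single-condition intrinsic-imaging frames with a pre-stimulus baseline;
``generate_landmark_pair``
    landmark point sets related by a planted warp, for registration tests.

All randomness flows from one :class:`numpy.random.Generator` seeded per
call; identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .alignment import PointSet
from .image import COMap
from .laminar import LaminarAnnotation
from .oi import ConditionStack
from .segmentation import voronoi_centerline


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class COSceneParams:
    """Geometry and rendering parameters of a synthetic CO-blob scene.

    ``blob_diameter_um`` is the target mean equivalent-area diameter of the
    planted blob masks (the diameter of the circle with the same area); it
    must be smaller than ``blob_spacing_um``.  ``lattice_jitter_frac`` is the
    full spread of the per-axis uniform jitter of lattice sites as a
    fraction of the spacing (each site moves up to half the spread per
    axis), keeping the mean nearest-neighbor distance within ~10% of the
    spacing for spreads below 0.2.
    ``contrast`` is the peak intensity dip of a blob below the bright
    interblob background (background level is 1).
    """

    image_size_px: tuple[int, int] = (360, 360)  # (rows, cols)
    um_per_px: float = 10.0
    blob_spacing_um: float = 450.0
    blob_diameter_um: float = 300.0
    lattice_jitter_frac: float = 0.10
    elongated_blob_prob: float = 0.0
    contrast: float = 0.5
    shading_amplitude: float = 0.0
    noise_sd: float = 0.0
    #: intensity support of each blob's Gaussian dip, in units of the mask
    #: radius; > 1 grades the interblob tissue (brightest farthest from all
    #: blobs, as in real CO staining) while the planted mask stays at the
    #: equivalent-area radius
    intensity_truncation_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blob_diameter_um >= self.blob_spacing_um:
            raise ValueError("blob_diameter_um must be < blob_spacing_um")
        if not (0 <= self.lattice_jitter_frac < 0.5):
            raise ValueError("lattice_jitter_frac must be in [0, 0.5)")
        if not (0 <= self.elongated_blob_prob <= 1):
            raise ValueError("elongated_blob_prob must be in [0, 1]")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must be in (0, 1]")
        if self.intensity_truncation_factor < 1:
            raise ValueError("intensity_truncation_factor must be >= 1")
        if self.shading_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        for v in (self.um_per_px, self.blob_spacing_um, self.blob_diameter_um):
            if not (v > 0 and np.isfinite(v)):
                raise ValueError("scene scales must be positive and finite")


@dataclass
class LabelFieldParams:
    """Parameters of a patchy fluorescent terminal field.

    ``preference_rho`` weights patch placement toward the blob compartment:
    each candidate pixel carries weight ``rho`` if it is a blob pixel and
    ``1 - rho`` otherwise, so 1 = purely blob-seeking, 0 = purely
    interblob-seeking, and 0.5 = indifferent (placement uniform over the
    tissue, blob mass share = blob area fraction).
    """

    preference_rho: float = 0.5
    n_patches: int = 80
    patch_sigma_um: float = 100.0
    patch_amplitude: float = 1.0
    background_level: float = 0.05
    noise_sd: float = 0.0
    #: side of the centered square zone receiving patches; terminal fields
    #: of a single injection cover a confined region of the section
    field_extent_um: float = 2400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.preference_rho <= 1):
            raise ValueError("preference_rho must be in [0, 1]")
        if self.n_patches < 1:
            raise ValueError("n_patches must be positive")
        if self.patch_sigma_um <= 0 or self.field_extent_um <= 0:
            raise ValueError("patch_sigma_um and field_extent_um must be positive")
        if self.background_level < 0 or self.noise_sd < 0 or self.patch_amplitude < 0:
            raise ValueError("levels must be non-negative")


#: nominal fractional depths of macaque V1 layer boundaries (pia = 0,
#: white matter = 1); values are schematic, not measurements.
DEFAULT_LAYER_BOUNDARIES = (0.07, 0.35, 0.40, 0.50, 0.64, 0.78)
DEFAULT_LAYER_NAMES = ("L1", "L2/3", "L4A", "L4B", "L4C", "L5", "L6")


@dataclass
class LaminarParams:
    """Planted per-layer amplitudes of a pia-to-white-matter section."""

    layer_boundaries_frac: Sequence[float] = DEFAULT_LAYER_BOUNDARIES
    layer_amplitudes: Sequence[float] = (0.1, 0.9, 0.3, 0.7, 0.2, 0.3, 0.4)
    layer_names: Sequence[str] | None = DEFAULT_LAYER_NAMES
    column_width_um: float = 500.0
    noise_sd: float = 0.0
    cortex_depth_um: float = 1800.0
    image_width_um: float = 1500.0
    um_per_px: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.layer_boundaries_frac, dtype=float)
        if b.size and (np.any(np.diff(b) <= 0) or b.min() <= 0 or b.max() >= 1):
            raise ValueError("layer boundaries must be strictly increasing in (0, 1)")
        if len(self.layer_amplitudes) != b.size + 1:
            raise ValueError("need one amplitude per layer (len(boundaries) + 1)")
        if np.any(np.asarray(self.layer_amplitudes) < 0):
            raise ValueError("layer amplitudes must be non-negative")
        if self.layer_names is None:
            self.layer_names = tuple(f"L{i + 1}" for i in range(b.size + 1))
        if len(self.layer_names) != b.size + 1:
            raise ValueError("need one name per layer")


@dataclass
class GroundTruthScene:
    """Planted ground truth exported alongside a synthetic CO map.

    ``blob_centers`` holds every planted intensity minimum in µm (elongated
    blobs contribute two); ``center_groups`` groups center indices by blob.
    ``compartment_of_pixel`` is 1 on blob pixels and 0 elsewhere.
    """

    blob_mask: np.ndarray
    blob_centers: np.ndarray  # (n, 2) float µm, columns (x, y)
    interblob_centerline_mask: np.ndarray
    compartment_of_pixel: np.ndarray
    params_used: COSceneParams
    center_groups: list[list[int]] = field(default_factory=list)

    def blob_area_fraction(self) -> float:
        return float(self.blob_mask.mean())


# --------------------------------------------------------------------------
# CO map generation
# --------------------------------------------------------------------------

def _hex_lattice(params: COSceneParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice sites (µm).

    The lattice overhangs the image border by one blob radius so the mosaic
    covers the field up to the edges, as in a real blob-filled map; border
    blobs render clipped.
    """
    h_um = params.image_size_px[0] * params.um_per_px
    w_um = params.image_size_px[1] * params.um_per_px
    s = params.blob_spacing_um
    row_step = s * math.sqrt(3) / 2
    overhang = params.blob_diameter_um / 2
    pts = []
    j = 0
    y = -overhang + 0.25 * s
    while y <= h_um + overhang:
        x0 = -overhang + (0.25 if j % 2 == 0 else 0.75) * s
        x = x0
        while x <= w_um + overhang:
            pts.append((x, y))
            x += s
        y += row_step
        j += 1
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    if pts.size:
        jitter = rng.uniform(-0.5, 0.5, size=pts.shape) * params.lattice_jitter_frac * s
        pts = pts + jitter
        keep = (
            (pts[:, 0] >= -overhang) & (pts[:, 0] <= w_um + overhang)
            & (pts[:, 1] >= -overhang) & (pts[:, 1] <= h_um + overhang)
        )
        pts = pts[keep]
    return pts


def _pixel_grid_um(shape: tuple[int, int], um_per_px: float):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    return xs * um_per_px, ys * um_per_px


def generate_co_map(params: COSceneParams) -> tuple[COMap, GroundTruthScene]:
    """Render a synthetic CO-stained section and its ground truth.

    Blobs are dark (darker-is-blob convention): each blob subtracts an
    inverted 2D Gaussian from the bright background, truncated at the radius
    of the target equivalent-area diameter, so the planted blob mask is the
    truncation footprint.  With probability ``elongated_blob_prob`` a lattice
    site and one of its nearest neighbors are merged into a single elongated
    blob whose intensity carries two local minima at the original sites,
    mirroring the multi-peaked elongated blobs seen in real CO maps.

    Returns the rendered map plus a :class:`GroundTruthScene` whose
    interblob centerline is the (group-wise) Voronoi boundary of the planted
    blobs, restricted to non-blob pixels.
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_size_px)
    sites = _hex_lattice(params, rng)

    intensity = np.ones(shape, dtype=float)
    blob_mask = np.zeros(shape, dtype=bool)

    if sites.shape[0] == 0:
        truth = GroundTruthScene(
            blob_mask=blob_mask,
            blob_centers=np.empty((0, 2)),
            interblob_centerline_mask=np.zeros(shape, dtype=bool),
            compartment_of_pixel=np.zeros(shape, dtype=np.uint8),
            params_used=params,
        )
        return _finalize_co(intensity, params, rng), truth

    # pair up sites into elongated blobs
    n = sites.shape[0]
    elongate = rng.uniform(size=n) < params.elongated_blob_prob
    tree = cKDTree(sites)
    consumed = np.zeros(n, dtype=bool)
    groups: list[list[int]] = []
    centers: list[np.ndarray] = []
    for i in range(n):
        if consumed[i]:
            continue
        if elongate[i]:
            dists, idx = tree.query(sites[i], k=min(4, n))
            partner = next(
                (int(j) for j in np.atleast_1d(idx)[1:] if not consumed[int(j)]),
                None,
            )
            if partner is not None:
                consumed[i] = consumed[partner] = True
                groups.append([len(centers), len(centers) + 1])
                centers.extend([sites[i], sites[partner]])
                continue
        consumed[i] = True
        groups.append([len(centers)])
        centers.append(sites[i])
    centers_arr = np.asarray(centers, dtype=float)

    r_um = params.blob_diameter_um / 2
    sigma = r_um / 1.5
    xs_um, ys_um = _pixel_grid_um(shape, params.um_per_px)
    group_of_center = np.empty(len(centers), dtype=int)
    for g, members in enumerate(groups):
        group_of_center[members] = g

    trunc_um = params.intensity_truncation_factor * r_um
    pad = int(math.ceil(trunc_um / params.um_per_px)) + 2
    for g, members in enumerate(groups):
        pts = centers_arr[members]
        # local window around the blob (or capsule) for speed
        x_lo = max(int(pts[:, 0].min() / params.um_per_px) - pad, 0)
        x_hi = min(int(pts[:, 0].max() / params.um_per_px) + pad + 1, shape[1])
        y_lo = max(int(pts[:, 1].min() / params.um_per_px) - pad, 0)
        y_hi = min(int(pts[:, 1].max() / params.um_per_px) + pad + 1, shape[0])
        wx = xs_um[y_lo:y_hi, x_lo:x_hi]
        wy = ys_um[y_lo:y_hi, x_lo:x_hi]
        if len(members) == 1:
            d = np.hypot(wx - pts[0, 0], wy - pts[0, 1])
            dip = params.contrast * np.exp(-(d**2) / (2 * sigma**2))
        else:
            d, t = _dist_to_segment(wx, wy, pts[0], pts[1])
            # longitudinal modulation: deepest at the two planted peaks
            dip = (
                params.contrast
                * np.exp(-(d**2) / (2 * sigma**2))
                * (0.80 + 0.20 * np.cos(2 * math.pi * np.clip(t, 0, 1)))
            )
        inside = d <= r_um
        intensity[y_lo:y_hi, x_lo:x_hi] -= np.where(d <= trunc_um, dip, 0.0)
        blob_mask[y_lo:y_hi, x_lo:x_hi] |= inside

    centerline = voronoi_centerline(
        shape,
        params.um_per_px,
        centers_arr,
        group_of_center=group_of_center,
        exclude_mask=blob_mask,
    )

    # ground-truth centers: only peaks whose pixel lies inside the image
    # (border blobs render clipped; their off-image peaks are not listed)
    cols = np.round(centers_arr[:, 0] / params.um_per_px).astype(int)
    rows = np.round(centers_arr[:, 1] / params.um_per_px).astype(int)
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    new_index = np.full(len(centers_arr), -1, dtype=int)
    new_index[inside] = np.arange(int(inside.sum()))
    kept_groups = []
    for members in groups:
        kept = [int(new_index[m]) for m in members if inside[m]]
        if kept:
            kept_groups.append(kept)

    truth = GroundTruthScene(
        blob_mask=blob_mask,
        blob_centers=centers_arr[inside],
        interblob_centerline_mask=centerline,
        compartment_of_pixel=blob_mask.astype(np.uint8),
        params_used=params,
        center_groups=kept_groups,
    )
    return _finalize_co(intensity, params, rng), truth


def _dist_to_segment(x, y, p0, p1):
    """Distance of grid points to segment p0-p1 and normalized position t."""
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vx * vx + vy * vy
    t = ((x - p0[0]) * vx + (y - p0[1]) * vy) / L2
    tc = np.clip(t, 0.0, 1.0)
    px, py = p0[0] + tc * vx, p0[1] + tc * vy
    return np.hypot(x - px, y - py), t


def _finalize_co(intensity, params, rng) -> COMap:
    """Apply multiplicative shading and additive noise; wrap as a COMap."""
    shape = intensity.shape
    if params.shading_amplitude > 0:
        xs, ys = _pixel_grid_um(shape, params.um_per_px)
        theta = rng.uniform(0, 2 * math.pi)
        span = max(xs.max(), ys.max(), 1.0)
        ramp = (xs * math.cos(theta) + ys * math.sin(theta)) / span
        ramp = ramp - ramp.mean()
        ramp /= max(abs(ramp.min()), abs(ramp.max()), 1e-12)
        intensity = intensity * (1.0 + params.shading_amplitude * ramp)
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0, params.noise_sd, size=shape)
    return COMap(intensity=intensity, um_per_px=params.um_per_px, modality="co")


# --------------------------------------------------------------------------
# fluorescent label field
# --------------------------------------------------------------------------

def generate_label_field(
    truth: GroundTruthScene, params: LabelFieldParams
) -> tuple[COMap, np.ndarray]:
    """Render a patchy fluorescent terminal field over a CO scene.

    Each of ``n_patches`` Gaussian patches lands on the blob compartment
    with probability ``rho A_b / (rho A_b + (1 - rho) A_i)`` (``A_b``,
    ``A_i`` = blob / interblob pixel counts; equivalent to drawing a pixel
    with per-pixel weight ``rho`` on blobs and ``1 - rho`` elsewhere), then
    uniformly over that compartment's pixels; placement is restricted to a
    centered square of side ``field_extent_um``.  The compartment coin, the
    blob draw and the interblob draw use fixed positions in the random
    stream, so on a fixed seed the rendered blob-mass fraction is
    non-decreasing in ``rho``.

    Returns the fluorescence map and the patch centers in µm, shape (n, 2).
    """
    scene = truth.params_used
    shape = truth.blob_mask.shape
    if params.field_extent_um != float("inf"):
        if params.field_extent_um > max(shape) * scene.um_per_px:
            raise ValueError("field_extent_um larger than the scene")
    rng = np.random.default_rng(params.seed)

    xs_um, ys_um = _pixel_grid_um(shape, scene.um_per_px)
    cx = (shape[1] - 1) * scene.um_per_px / 2
    cy = (shape[0] - 1) * scene.um_per_px / 2
    half = params.field_extent_um / 2
    region = (np.abs(xs_um - cx) <= half) & (np.abs(ys_um - cy) <= half)

    blob_idx = np.flatnonzero(truth.blob_mask & region)
    inter_idx = np.flatnonzero(~truth.blob_mask & region)
    if blob_idx.size == 0 and params.preference_rho > 0:
        blob_idx = inter_idx  # blob-free degenerate scene: fall back
    if inter_idx.size == 0:
        inter_idx = blob_idx
    if blob_idx.size == 0:
        raise ValueError("no pixels available for patch placement")

    rho = params.preference_rho
    w_blob = rho * blob_idx.size
    w_inter = (1.0 - rho) * inter_idx.size
    p_blob = w_blob / (w_blob + w_inter) if (w_blob + w_inter) > 0 else 0.0
    # fixed stream layout: coins, then blob draws, then interblob draws
    coins = rng.uniform(size=params.n_patches)
    blob_draws = rng.integers(0, blob_idx.size, size=params.n_patches)
    inter_draws = rng.integers(0, inter_idx.size, size=params.n_patches)
    flat = np.where(coins < p_blob, blob_idx[blob_draws], inter_idx[inter_draws])
    rows, cols = np.unravel_index(flat, shape)
    patch_centers = np.column_stack([cols, rows]).astype(float) * scene.um_per_px

    field_img = np.full(shape, params.background_level, dtype=float)
    sig_px = params.patch_sigma_um / scene.um_per_px
    reach = int(math.ceil(4 * sig_px)) + 1
    for r0, c0 in zip(rows, cols):
        y_lo, y_hi = max(r0 - reach, 0), min(r0 + reach + 1, shape[0])
        x_lo, x_hi = max(c0 - reach, 0), min(c0 + reach + 1, shape[1])
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        field_img[y_lo:y_hi, x_lo:x_hi] += params.patch_amplitude * np.exp(
            -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sig_px**2)
        )
    if params.noise_sd > 0:
        field_img = field_img + rng.normal(0, params.noise_sd, size=shape)

    fluor = COMap(
        intensity=field_img, um_per_px=scene.um_per_px, modality="fluorescence"
    )
    return fluor, patch_centers


# --------------------------------------------------------------------------
# laminar sections
# --------------------------------------------------------------------------

def generate_laminar_section(
    params: LaminarParams,
) -> tuple[COMap, LaminarAnnotation]:
    """Render a flat pia-to-white-matter section with a step laminar profile.

    Rows run from pia (top) to the white-matter border (bottom); every pixel
    of a layer carries that layer's amplitude plus optional Gaussian noise.
    The returned annotation has straight pia/white-matter polylines and the
    fractional layer boundaries, exactly as a manual tracing would provide.
    """
    rng = np.random.default_rng(params.seed)
    n_rows = max(int(round(params.cortex_depth_um / params.um_per_px)), 1)
    n_cols = max(int(round(params.image_width_um / params.um_per_px)), 1)
    depth = (np.arange(n_rows) + 0.5) / n_rows
    bounds = np.asarray(params.layer_boundaries_frac, dtype=float)
    layer_of_row = np.searchsorted(bounds, depth, side="right")
    amp = np.asarray(params.layer_amplitudes, dtype=float)[layer_of_row]
    intensity = np.tile(amp[:, None], (1, n_cols))
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0, params.noise_sd, intensity.shape)

    annotation = LaminarAnnotation(
        pia_curve=np.array([[0.0, 0.0], [n_cols - 1.0, 0.0]]),
        wm_curve=np.array([[0.0, n_rows - 1.0], [n_cols - 1.0, n_rows - 1.0]]),
        layer_boundaries_frac=tuple(float(b) for b in bounds),
        layer_names=tuple(params.layer_names),
    )
    section = COMap(
        intensity=intensity, um_per_px=params.um_per_px, modality="fluorescence"
    )
    return section, annotation


# --------------------------------------------------------------------------
# intrinsic-imaging condition stacks
# --------------------------------------------------------------------------

def generate_oi_conditions(
    n_conditions: int,
    domain_maps: Sequence[np.ndarray],
    baseline_level: float,
    noise_sd: float,
    seed: int,
    response_amplitude: float = 1.0,
    condition_labels: Sequence[str] | None = None,
) -> ConditionStack:
    """Simulate trial-averaged single-condition intrinsic-imaging frames.

    Each condition frame is ``baseline_level + response_amplitude *
    domain_map + noise``; the pre-stimulus baseline frame carries
    ``baseline_level + noise``.  One domain map per condition, all sharing
    one shape.
    """
    if len(domain_maps) != n_conditions:
        raise ValueError("need one domain map per condition")
    maps = [np.asarray(m, dtype=float) for m in domain_maps]
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("domain maps must share one shape")
    if condition_labels is None:
        condition_labels = [f"cond{i}" for i in range(n_conditions)]
    rng = np.random.default_rng(seed)
    frames = {}
    for label, m in zip(condition_labels, maps):
        noise = rng.normal(0, noise_sd, shape) if noise_sd > 0 else 0.0
        frames[label] = baseline_level + response_amplitude * m + noise
    b_noise = rng.normal(0, noise_sd, shape) if noise_sd > 0 else 0.0
    baseline = baseline_level + b_noise + np.zeros(shape)
    return ConditionStack(frames=frames, baseline=baseline)


# --------------------------------------------------------------------------
# landmark pairs
# --------------------------------------------------------------------------

def generate_landmark_pair(
    n_points: int,
    planted_warp: Callable[[np.ndarray], np.ndarray],
    seed: int,
    extent_um: float = 1000.0,
) -> tuple[PointSet, PointSet, Callable[[np.ndarray], np.ndarray]]:
    """Draw non-collinear source landmarks and their exact warped images.

    ``planted_warp`` maps an (n, 2) µm array to an (n, 2) µm array.  Draws
    that are (near-)collinear are resampled from the same seeded stream and
    never returned.
    """
    if n_points < 3:
        raise ValueError("need at least 3 landmark points")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        src = rng.uniform(0, extent_um, size=(n_points, 2))
        centered = src - src.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] > 1e-6 * max(sv[0], 1.0):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a non-collinear configuration")
    dst = np.asarray(planted_warp(src), dtype=float)
    return (
        PointSet(points=src, frame_id="source"),
        PointSet(points=dst, frame_id="destination"),
        planted_warp,
    )
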