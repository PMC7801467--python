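"""Blob-centered ROI quantification of CO and fluorescence intensity.

Given the segmented blob mosaic and a co-registered fluorescence image, this
module implements the compartment analysis:

1. ``compute_roi_size`` — for every blob center, the distance to the
   interblob structure is measured along rays cast at fixed angular
   increments (default 20°); the grand average blob-center-to-interblob-
   center (B_ctr-I_ctr) distance, doubled, gives the square ROI side.
2. ``accumulate_heatmap`` — the ROI is centered on each blob, intensities
   are summed pixelwise across blob ROIs and normalized to the maximum, so
   the heatmap shows the average intensity landscape around a blob center.
3. ``radial_profile`` — a window of fixed width (default 200 µm) is rotated
   about the heatmap center in the same angular increments; the window with
   the highest mean signal is split into 20 radial bins from the blob
   center (0) to the interblob center (1) and the bin means are normalized
   to their maximum.
4. ``fit_cubic`` — the profile is summarized by a least-squares cubic
   y = ax³ + bx² + cx + d.
5. ``population_heatmap`` — per-case heatmaps are rescaled to the largest,
   summed and re-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .image import COMap
from .segmentation import BlobSet


class InsufficientGeometryError(ValueError):
    """No ray from any blob center reaches the interblob structure."""


class EmptyHeatmapError(ValueError):
    """No usable blob-centered ROI (all excluded or zero label)."""


class NoLabelOverlapError(ValueError):
    """No blob ROI overlies above-background fluorescent label."""


@dataclass
class QuantConfig:
    """Knobs of the compartment analysis (defaults follow the workflow)."""

    angle_step_deg: int = 20
    n_profile_bins: int = 20
    window_width_um: float = 200.0
    dark_fraction: float = 0.33
    high_bin_threshold: float = 0.70
    roi_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.angle_step_deg <= 0 or 360 % self.angle_step_deg != 0:
            raise ValueError("angle_step_deg must be a positive divisor of 360")
        for name in ("n_profile_bins", "window_width_um", "dark_fraction",
                     "high_bin_threshold", "roi_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(0, 360, self.angle_step_deg)


@dataclass
class ROISpec:
    """Square ROI geometry: side = roi_multiplier x grand-avg B_ctr-I_ctr."""

    side_um: float
    side_px: int  # odd, so the blob center sits on the central pixel
    grand_average_um: float = float("nan")


@dataclass
class Heatmap:
    """Accumulated blob-centered intensity grid."""

    grid: np.ndarray
    um_per_px: float
    normalized: bool
    n_blobs_used: int
    mean_blob_diameter_um: float
    source: str  # {"co", "fluorescence"}
    layer_id: str | None = None
    empty: bool = False

    @property
    def side_px(self) -> int:
        return self.grid.shape[0]

    @property
    def side_um(self) -> float:
        return self.grid.shape[0] * self.um_per_px


@dataclass
class RadialProfile:
    """Normalized bin intensities on the B_ctr(0) -> I_ctr(1) axis."""

    bin_values: np.ndarray
    bin_centers: np.ndarray
    chosen_angle_deg: int
    window_width_um: float
    source: str = ""
    layer_id: str | None = None

    def argmax_distance(self) -> float:
        """Normalized distance of the highest-intensity bin."""
        return float(self.bin_centers[int(np.nanargmax(self.bin_values))])


@dataclass
class CubicFit:
    """Least-squares cubic y = ax^3 + bx^2 + cx + d."""

    a: float
    b: float
    c: float
    d: float
    residual_sse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval([self.a, self.b, self.c, self.d], np.asarray(x))


# --------------------------------------------------------------------------
# ROI sizing
# --------------------------------------------------------------------------

def compute_roi_size(
    blobs: BlobSet,
    cfg: QuantConfig | None = None,
    centerline_mask: np.ndarray | None = None,
    max_radius_um: float | None = None,
) -> ROISpec:
    """Grand-average B_ctr-I_ctr distance, doubled, as the ROI side.

    For each blob center, rays are cast at ``angle_step_deg`` increments.
    When ``centerline_mask`` is given, a ray's distance is to its first
    crossing of the centerline; otherwise each interblob center point is
    assigned to the nearest ray heading (within half the angular step) and
    the ray records the nearest assigned point.  Rays that hit nothing are
    dropped from that blob's mean; blobs with no hitting ray are dropped
    from the grand average.
    """
    cfg = cfg or QuantConfig()
    centers = blobs.all_blob_centers()
    if len(centers) == 0:
        raise InsufficientGeometryError("no blob centers")
    angles = np.deg2rad(cfg.angles_deg)
    per_blob_means = []
    if centerline_mask is None:
        ipts = np.asarray(blobs.interblob_centers, dtype=float).reshape(-1, 2)
        if len(ipts) == 0:
            raise InsufficientGeometryError("no interblob centers")
        sources = np.asarray(blobs.interblob_center_sources, dtype=int).reshape(-1, 2)
        half_step = cfg.angle_step_deg / 2
        for ci, c in enumerate(centers):
            if sources.shape[0] == ipts.shape[0] and sources.size:
                # only the interblob centers adjacent to this blob center
                pts_i = ipts[(sources == ci).any(axis=1)]
            else:
                pts_i = ipts
            if len(pts_i) == 0:
                continue
            vec = pts_i - c
            radii = np.hypot(vec[:, 0], vec[:, 1])
            ok = radii > 0
            ang = np.degrees(np.arctan2(vec[ok, 1], vec[ok, 0])) % 360
            radii = radii[ok]
            ray_dists = []
            for a in cfg.angles_deg:
                delta = np.abs((ang - a + 180) % 360 - 180)
                hit = delta <= half_step
                if hit.any():
                    ray_dists.append(radii[hit].min())
            if ray_dists:
                per_blob_means.append(float(np.mean(ray_dists)))
    else:
        mask = np.asarray(centerline_mask, dtype=bool)
        upx = blobs.um_per_px
        if max_radius_um is None:
            max_radius_um = float(np.hypot(*mask.shape)) * upx
        step = upx / 2
        radii_steps = np.arange(step, max_radius_um + step, step)
        for c in centers:
            ray_dists = []
            for th in angles:
                xs = (c[0] + radii_steps * math.cos(th)) / upx
                ys = (c[1] + radii_steps * math.sin(th)) / upx
                cols = np.round(xs).astype(int)
                rows = np.round(ys).astype(int)
                ok = (
                    (rows >= 0) & (rows < mask.shape[0])
                    & (cols >= 0) & (cols < mask.shape[1])
                )
                on_line = np.where(
                    ok,
                    mask[np.clip(rows, 0, mask.shape[0] - 1),
                         np.clip(cols, 0, mask.shape[1] - 1)],
                    False,
                )
                hits = np.flatnonzero(on_line)
                if hits.size:
                    ray_dists.append(radii_steps[hits[0]])
            if ray_dists:
                per_blob_means.append(float(np.mean(ray_dists)))
    if not per_blob_means:
        raise InsufficientGeometryError("no ray reached the interblob structure")
    grand = float(np.mean(per_blob_means))
    side_um = cfg.roi_multiplier * grand
    side_px = int(round(side_um / blobs.um_per_px))
    if side_px % 2 == 0:
        side_px += 1
    return ROISpec(side_um=side_um, side_px=side_px, grand_average_um=grand)


# --------------------------------------------------------------------------
# heatmap accumulation
# --------------------------------------------------------------------------

def _usable_center_windows(comap: COMap, centers_um: np.ndarray, side_px: int):
    """Yield (index, row slice, col slice) for fully in-image, valid ROIs."""
    half = side_px // 2
    for i, (x, y) in enumerate(np.asarray(centers_um).reshape(-1, 2)):
        r = int(round(y / comap.um_per_px))
        c = int(round(x / comap.um_per_px))
        if (
            r - half < 0
            or c - half < 0
            or r + half >= comap.shape[0]
            or c + half >= comap.shape[1]
        ):
            continue
        rs = slice(r - half, r + half + 1)
        cs = slice(c - half, c + half + 1)
        if not comap.valid_mask[rs, cs].all():
            continue
        yield i, rs, cs


def accumulate_heatmap(
    comap: COMap,
    centers_um: np.ndarray,
    roi: ROISpec,
    blob_diameters_um: Sequence[float] | None = None,
    layer_id: str | None = None,
) -> Heatmap:
    """Sum blob-centered square ROIs pixelwise and normalize to the maximum.

    Centers whose ROI leaves the image or touches invalid pixels are
    excluded (and not counted in ``n_blobs_used``), keeping the
    normalization unbiased.  ``blob_diameters_um``, aligned with
    ``centers_um`` rows, feeds the mean-blob-diameter overlay.
    """
    centers_um = np.asarray(centers_um, dtype=float).reshape(-1, 2)
    acc = np.zeros((roi.side_px, roi.side_px), dtype=float)
    used_idx = []
    for i, rs, cs in _usable_center_windows(comap, centers_um, roi.side_px):
        acc += comap.intensity[rs, cs]
        used_idx.append(i)
    if not used_idx:
        raise EmptyHeatmapError("no usable blob-centered ROI")
    peak = acc.max()
    empty = peak <= 0
    if not empty:
        acc = acc / peak
    mean_diam = float("nan")
    if blob_diameters_um is not None:
        diams = np.asarray(blob_diameters_um, dtype=float)[used_idx]
        if diams.size:
            mean_diam = float(diams.mean())
    return Heatmap(
        grid=acc,
        um_per_px=comap.um_per_px,
        normalized=not empty,
        n_blobs_used=len(used_idx),
        mean_blob_diameter_um=mean_diam,
        source=comap.modality,
        layer_id=layer_id,
        empty=empty,
    )


def select_blobs_for_layer(
    blobs: BlobSet, fluor: COMap, roi: ROISpec
) -> np.ndarray:
    """Indices (into all blob centers) of blobs overlying the labeled field.

    A blob center is selected when the mean fluorescence within its ROI
    exceeds the field background, estimated robustly as median + 2 x MAD of
    all valid fluorescence pixels.
    """
    centers = blobs.all_blob_centers()
    if len(centers) == 0:
        raise NoLabelOverlapError("no blob centers")
    vals = fluor.valid_values()
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    background = med + 2.0 * mad
    selected = [
        i
        for i, rs, cs in _usable_center_windows(fluor, centers, roi.side_px)
        if fluor.intensity[rs, cs].mean() > background
    ]
    if not selected:
        raise NoLabelOverlapError("no blob ROI overlies above-background label")
    return np.asarray(selected, dtype=int)


# --------------------------------------------------------------------------
# radial profiles
# --------------------------------------------------------------------------

def _window_coords(hm: Heatmap):
    """Per-pixel (dx, dy) in µm relative to the heatmap center, y up."""
    c = hm.side_px // 2
    ys, xs = np.mgrid[0 : hm.side_px, 0 : hm.side_px]
    dx = (xs - c).astype(float) * hm.um_per_px
    dy = -(ys - c).astype(float) * hm.um_per_px  # counter-clockwise angles
    return dx, dy


def radial_profile(
    hm: Heatmap, roi: ROISpec, cfg: QuantConfig | None = None
) -> RadialProfile:
    """Bin the densest rotated window into a B_ctr -> I_ctr profile.

    A rectangle of width ``window_width_um`` extends from the heatmap center
    to radius ``side_um / 2`` at each heading in ``angles_deg``; a pixel
    belongs to the window when its center lies inside the rectangle.  The
    heading with the highest mean window intensity wins (ties to the
    smallest angle).  The window's pixels are then split into
    ``n_profile_bins`` equal bins of their *distance from the blob center*
    (pixels beyond the interblob-center radius ``side_um / 2`` — possible in
    the window's far corners — are excluded), and bin means are normalized
    to a maximum of 1.
    """
    cfg = cfg or QuantConfig()
    if cfg.window_width_um > hm.side_um:
        raise ValueError("window width exceeds heatmap side")
    if not hm.normalized and not hm.empty:
        raise ValueError("heatmap must be normalized")
    R = roi.side_um / 2
    half_w = cfg.window_width_um / 2
    dx, dy = _window_coords(hm)
    radius = np.hypot(dx, dy)
    eps = 1e-6  # µm; keeps boundary pixels stable at cardinal headings
    best = None
    for a in cfg.angles_deg:
        th = math.radians(a)
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        inside = (u >= -eps) & (u <= R + eps) & (np.abs(v) <= half_w + eps)
        if not inside.any():
            continue
        mean = hm.grid[inside].mean()
        if best is None or mean > best[0] + 1e-15:
            best = (mean, int(a), inside)
    if best is None:
        raise ValueError("no pixel falls inside any window")
    _, angle, inside = best

    nb = cfg.n_profile_bins
    width = R / nb
    keep = inside & (radius <= R)
    uu = radius[keep]
    vals = hm.grid[keep]
    # bin k (1-based) covers ((k-1) w, k w]; the center pixel (u = 0) joins bin 1
    idx = np.ceil(uu / width).astype(int)
    idx[idx < 1] = 1
    idx[idx > nb] = nb
    bin_values = np.full(nb, np.nan)
    for k in range(1, nb + 1):
        sel = idx == k
        if sel.any():
            bin_values[k - 1] = vals[sel].mean()
    peak = np.nanmax(bin_values)
    if peak > 0:
        bin_values = bin_values / peak
    bin_centers = (np.arange(1, nb + 1) - 0.5) / nb
    return RadialProfile(
        bin_values=bin_values,
        bin_centers=bin_centers,
        chosen_angle_deg=angle,
        window_width_um=cfg.window_width_um,
        source=hm.source,
        layer_id=hm.layer_id,
    )


def fit_cubic(profile: RadialProfile) -> CubicFit:
    """Least-squares cubic fit to the profile's (bin center, value) pairs."""
    x = np.asarray(profile.bin_centers, dtype=float)
    y = np.asarray(profile.bin_values, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 finite bins for a cubic fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate bin centers")
    coeffs, *_ = np.polyfit(x, y, 3, full=True)
    resid = y - np.polyval(coeffs, x)
    return CubicFit(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        d=float(coeffs[3]),
        residual_sse=float(np.sum(resid**2)),
    )


# --------------------------------------------------------------------------
# population aggregation
# --------------------------------------------------------------------------

def population_heatmap(hms: Sequence[Heatmap]) -> Heatmap:
    """Rescale heatmaps to the largest side, sum pixelwise, re-normalize.

    Resampling is bilinear.  All inputs must share source (and layer, when
    set).
    """
    hms = list(hms)
    if not hms:
        raise ValueError("need at least one heatmap")
    src = {h.source for h in hms}
    if len(src) > 1:
        raise ValueError(f"mixed heatmap sources: {sorted(src)}")
    layers = {h.layer_id for h in hms if h.layer_id is not None}
    if len(layers) > 1:
        raise ValueError(f"mixed heatmap layers: {sorted(layers)}")
    target = max(h.side_px for h in hms)
    acc = np.zeros((target, target), dtype=float)
    for h in hms:
        if h.side_px == target:
            acc += h.grid
        else:
            acc += resize(
                h.grid, (target, target), order=1, preserve_range=True,
                anti_aliasing=False,
            )
    peak = acc.max()
    if peak > 0:
        acc = acc / peak
    n_used = sum(h.n_blobs_used for h in hms)
    diams = np.array(
        [(h.mean_blob_diameter_um, h.n_blobs_used) for h in hms
         if np.isfinite(h.mean_blob_diameter_um)]
    )
    mean_diam = (
        float(np.average(diams[:, 0], weights=diams[:, 1])) if diams.size else float("nan")
    )
    ref = min(hms, key=lambda h: h.side_px != target)
    return Heatmap(
        grid=acc,
        um_per_px=ref.side_um / target,
        normalized=True,
        n_blobs_used=n_used,
        mean_blob_diameter_um=mean_diam,
        source=hms[0].source,
        layer_id=hms[0].layer_id,
        empty=peak <= 0,
    )


def mean_blob_diameter(areas_um2: Sequence[float]) -> float:
    """Mean equivalent-area diameter 2 sqrt(area / pi) of the used blobs."""
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one blob")
    return float(np.mean(2.0 * np.sqrt(areas / math.pi)))
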