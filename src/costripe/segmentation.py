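"""CO-map preprocessing and blob segmentation.

The segmentation recipe mirrors the classic histology workflow for mapping
cytochrome-oxidase (CO) blobs in V1: low-pass filter the stained section,
flatten staining inhomogeneity with a local ("bell-shaped") histogram
equalization, then segment the blobs as the darkest 33% of pixels of the
flattened image.  Blob centers are the darkest pixel of each blob (with
extra centers for elongated, multi-peaked blobs) and interblob centers are
the brightest non-blob pixels on the straight path between adjacent blob
centers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import truncnorm
from skimage.draw import line as draw_line
from skimage.feature import peak_local_max
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

from .image import COMap

log = logging.getLogger(__name__)


class DegenerateImageError(ValueError):
    """All valid pixels equal: the dark-fraction quantile is undefined."""


@dataclass
class BlobSet:
    """Segmented blobs with centers and interblob center points.

    ``labels`` is an integer grid with blob ids 1..n (0 = interblob).
    ``blob_centers`` maps blob id to an (k, 2) µm array of centers (k >= 1;
    several for elongated blobs).  ``interblob_centers`` is an (m, 2) µm
    array.  Areas are in µm² and ``equivalent_diameter_um[b] =
    2 sqrt(area_b / pi)``.
    """

    labels: np.ndarray
    um_per_px: float
    blob_centers: dict[int, np.ndarray] = field(default_factory=dict)
    interblob_centers: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )
    #: per interblob center, the indices (into all_blob_centers) of the two
    #: adjacent blob centers whose connecting segment produced it
    interblob_center_sources: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )
    per_blob_area_um2: dict[int, float] = field(default_factory=dict)
    equivalent_diameter_um: dict[int, float] = field(default_factory=dict)

    @property
    def n_blobs(self) -> int:
        return len(self.per_blob_area_um2)

    @property
    def blob_mask(self) -> np.ndarray:
        return self.labels > 0

    def all_blob_centers(self) -> np.ndarray:
        """All blob centers as one (n, 2) µm array (blob-id order)."""
        if not self.blob_centers:
            return np.empty((0, 2))
        return np.concatenate(
            [self.blob_centers[b] for b in sorted(self.blob_centers)]
        )

    def blob_id_of_center(self) -> np.ndarray:
        """Blob id aligned with :meth:`all_blob_centers` rows."""
        if not self.blob_centers:
            return np.empty(0, dtype=int)
        return np.concatenate(
            [
                np.full(len(self.blob_centers[b]), b, dtype=int)
                for b in sorted(self.blob_centers)
            ]
        )


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

_EQ_LEVELS = 1024  # 10-bit quantization for the local-rank filter


def preprocess_co(
    comap: COMap,
    lowpass_sigma_um: float,
    eq_window_um: float,
    bell_sd: float = 1 / 6,
    background_sigma_um: float | None = None,
) -> COMap:
    """Low-pass, staining-background division, bell-shaped local equalization.

    Three steps: (1) a Gaussian low-pass of scale ``lowpass_sigma_um``;
    (2) division by the large-scale staining background (a Gaussian of scale
    ``background_sigma_um``, default half the equalization window), removing
    smooth multiplicative staining gradients; (3) local histogram
    equalization in a sliding square window of side ``eq_window_um``, with
    each pixel's local rank mapped through the quantile function of a
    truncated normal centered mid-scale (mean 0.5, sd ``bell_sd`` of the
    scale, truncated to [0, 1]).  The combination redistributes the local
    histograms around the center of the intensity scale while preserving the
    local dark-to-bright ordering the blob threshold relies on.

    Output intensities lie in [0, 1]; the valid mask is unchanged.
    """
    if lowpass_sigma_um <= 0 or eq_window_um <= 0:
        raise ValueError("lowpass_sigma_um and eq_window_um must be positive")
    win_px = int(round(eq_window_um / comap.um_per_px))
    if win_px < 3:
        raise ValueError("equalization window smaller than 3 px")
    if background_sigma_um is None:
        background_sigma_um = eq_window_um / 2

    img = comap.intensity.astype(float).copy()
    valid = comap.valid_mask

    def _nc_gaussian(field: np.ndarray, sigma_px: float) -> np.ndarray:
        # normalized convolution: invalid pixels carry no weight
        num = ndimage.gaussian_filter(np.where(valid, field, 0.0), sigma_px)
        den = ndimage.gaussian_filter(valid.astype(float), sigma_px)
        return np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)

    smooth = _nc_gaussian(img, lowpass_sigma_um / comap.um_per_px)
    background = _nc_gaussian(smooth, background_sigma_um / comap.um_per_px)
    pos = np.abs(background) > 1e-12
    smooth = np.where(pos & valid, smooth / np.where(pos, background, 1.0), 0.0)

    vals = smooth[valid]
    if vals.size == 0:
        raise DegenerateImageError("no valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        # flat image: equalization is a no-op by construction
        return COMap(
            intensity=np.where(valid, smooth, 0.0),
            um_per_px=comap.um_per_px,
            valid_mask=valid.copy(),
            modality=comap.modality,
        )
    quant = np.zeros(comap.shape, dtype=np.uint16)
    quant[valid] = np.round((smooth[valid] - lo) / (hi - lo) * (_EQ_LEVELS - 1)).astype(
        np.uint16
    )
    footprint = footprint_rectangle((win_px, win_px))
    eq = rank.equalize(quant, footprint=footprint, mask=valid)
    local_rank = eq.astype(float) / (_EQ_LEVELS - 1)

    # map the (uniform) local rank through a bell-shaped target histogram
    a, b = (0.0 - 0.5) / bell_sd, (1.0 - 0.5) / bell_sd
    bell = truncnorm(a, b, loc=0.5, scale=bell_sd)
    out = np.zeros(comap.shape, dtype=float)
    out[valid] = bell.ppf(np.clip(local_rank[valid], 0.0, 1.0))
    return COMap(
        intensity=out,
        um_per_px=comap.um_per_px,
        valid_mask=valid.copy(),
        modality=comap.modality,
    )


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def default_min_area_um2(blob_diameter_um: float) -> float:
    """Speck filter: area of a circle of one-third the target blob diameter."""
    return math.pi * (blob_diameter_um / 6) ** 2


def segment_blobs(
    comap: COMap, dark_fraction: float = 0.33, min_area_um2: float = 0.0
) -> BlobSet:
    """Segment blobs as the darkest ``dark_fraction`` of valid pixels.

    The threshold is the ``dark_fraction`` quantile of valid-pixel
    intensities, taken as the order statistic of rank
    ``floor(dark_fraction * N)``; pixels *strictly below* it are blob, so
    with all-distinct intensities exactly ``floor(dark_fraction * N)``
    pixels are marked and threshold-tied pixels are excluded.  Connected
    components (8-connectivity) smaller than ``min_area_um2`` revert to
    interblob.
    """
    if not (0 < dark_fraction < 1):
        raise ValueError("dark_fraction must be in (0, 1)")
    vals = comap.valid_values()
    if vals.size == 0 or np.all(vals == vals.flat[0]):
        raise DegenerateImageError("all valid pixels equal; threshold undefined")
    k = int(math.floor(dark_fraction * vals.size))
    threshold = np.partition(vals, k)[k]
    blob_px = comap.valid_mask & (comap.intensity < threshold)

    labels, n = ndimage.label(blob_px, structure=np.ones((3, 3), dtype=int))
    px_area = comap.um_per_px**2
    if n and min_area_um2 > 0:
        sizes = ndimage.sum_labels(blob_px, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes * px_area < min_area_um2) + 1
        if small.size:
            labels[np.isin(labels, small)] = 0
    # relabel sequentially
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=int)
    remap[ids] = np.arange(1, ids.size + 1)
    labels = remap[labels]

    areas = {}
    diam = {}
    for b in range(1, ids.size + 1):
        a = float(np.count_nonzero(labels == b)) * px_area
        areas[b] = a
        diam[b] = 2.0 * math.sqrt(a / math.pi)
    return BlobSet(
        labels=labels,
        um_per_px=comap.um_per_px,
        per_blob_area_um2=areas,
        equivalent_diameter_um=diam,
    )


def find_blob_centers(
    blobs: BlobSet,
    comap: COMap,
    multi_center_min_spacing_um: float | None = None,
) -> BlobSet:
    """Mark each blob's darkest pixel; add extra minima for elongated blobs.

    Every blob receives its global-minimum pixel as a center.  When
    ``multi_center_min_spacing_um`` is given, additional local intensity
    minima at least that far from every already-accepted center, and darker
    than the blob's 25th intensity percentile, are added as extra centers —
    capturing the multiple CO peaks of significantly elongated blobs.
    """
    if blobs.n_blobs == 0:
        log.warning("find_blob_centers: empty BlobSet")
        return replace(blobs, blob_centers={})
    upx = blobs.um_per_px
    centers: dict[int, np.ndarray] = {}
    objects = ndimage.find_objects(blobs.labels)
    for b in range(1, blobs.n_blobs + 1):
        sl = objects[b - 1]
        sub_lbl = blobs.labels[sl] == b
        sub_img = comap.intensity[sl]
        masked = np.where(sub_lbl, sub_img, np.inf)
        r0, c0 = np.unravel_index(np.argmin(masked), masked.shape)
        pts = [(c0, r0)]
        if multi_center_min_spacing_um is not None:
            spacing_px = max(int(round(multi_center_min_spacing_um / upx)), 1)
            q25 = np.percentile(sub_img[sub_lbl], 25)
            cand = peak_local_max(
                -sub_img,
                min_distance=spacing_px,
                labels=sub_lbl.astype(int),
                exclude_border=False,
            )
            # deepest first, keep those below the 25th percentile and spaced out
            cand = cand[np.argsort(sub_img[cand[:, 0], cand[:, 1]])]
            for r, c in cand:
                if sub_img[r, c] > q25:
                    continue
                if all(math.hypot(c - x, r - y) >= spacing_px for x, y in pts):
                    pts.append((c, r))
        off = np.array([sl[1].start, sl[0].start], dtype=float)
        centers[b] = (np.asarray(pts, dtype=float) + off) * upx
    return replace(blobs, blob_centers=centers)


def find_interblob_centers(blobs: BlobSet, comap: COMap) -> BlobSet:
    """Brightest non-blob pixel between each pair of adjacent blob centers.

    Adjacency is the Delaunay triangulation of all blob centers, with edges
    longer than twice the median edge length discarded (guards against
    convex-hull artifacts).  For each retained edge, the straight pixel
    segment between the two centers is scanned and its brightest valid,
    non-blob pixel becomes an interblob center.
    """
    pts = blobs.all_blob_centers()
    if len(pts) < 2:
        log.warning("find_interblob_centers: fewer than 2 blob centers")
        return replace(blobs, interblob_centers=np.empty((0, 2)))
    edges = _adjacency_edges(pts)
    upx = blobs.um_per_px
    found: list[tuple[float, float]] = []
    sources: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in edges:
        r0, c0 = int(round(pts[i, 1] / upx)), int(round(pts[i, 0] / upx))
        r1, c1 = int(round(pts[j, 1] / upx)), int(round(pts[j, 0] / upx))
        rr, cc = draw_line(r0, c0, r1, c1)
        ok = (
            (rr >= 0) & (rr < blobs.labels.shape[0])
            & (cc >= 0) & (cc < blobs.labels.shape[1])
        )
        rr, cc = rr[ok], cc[ok]
        free = (blobs.labels[rr, cc] == 0) & comap.valid_mask[rr, cc]
        if not free.any():
            continue
        rr, cc = rr[free], cc[free]
        k = int(np.argmax(comap.intensity[rr, cc]))
        key = (int(rr[k]), int(cc[k]))
        if key not in seen:
            seen.add(key)
            found.append((cc[k] * upx, rr[k] * upx))
            sources.append((i, j))
    return replace(
        blobs,
        interblob_centers=np.asarray(found, dtype=float).reshape(-1, 2),
        interblob_center_sources=np.asarray(sources, dtype=int).reshape(-1, 2),
    )


def _adjacency_edges(
    pts: np.ndarray, max_edge_factor: float = 1.4
) -> list[tuple[int, int]]:
    """Delaunay edges of blob centers, pruned at ``max_edge_factor`` x median.

    In quasi-hexagonal mosaics the Delaunay triangulation occasionally flips
    a rhombus diagonal, producing edges between next-nearest neighbors at
    ~1.7x the typical spacing (and hull artifacts up to far longer); the
    default cutoff keeps nearest-ring edges only.
    """
    n = len(pts)
    if n == 2:
        return [(0, 1)]
    try:
        tri = Delaunay(pts)
        edge_set = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                edge_set.add((int(i), int(j)))
        edges = sorted(edge_set)
    except Exception:
        # (near-)collinear configuration: fall back to nearest-neighbor chain
        tree = cKDTree(pts)
        k = min(3, n)
        _, idx = tree.query(pts, k=k)
        edges = sorted(
            {tuple(sorted((i, int(j)))) for i in range(n) for j in idx[i][1:]}
        )
    lengths = np.array([np.linalg.norm(pts[i] - pts[j]) for i, j in edges])
    cutoff = max_edge_factor * np.median(lengths)
    return [e for e, L in zip(edges, lengths) if L <= cutoff]


def voronoi_centerline(
    shape: tuple[int, int],
    um_per_px: float,
    centers_um: np.ndarray,
    group_of_center: np.ndarray | None = None,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Interblob centerline: boundary pixels between Voronoi cells of blobs.

    Each pixel is assigned to its nearest blob center; pixels adjacent to a
    differently-assigned pixel form the centerline.  ``group_of_center``
    merges the cells of centers belonging to one (elongated) blob so no
    boundary is drawn inside a blob; ``exclude_mask`` (e.g. the blob mask)
    removes pixels from the result.
    """
    centers_um = np.asarray(centers_um, dtype=float).reshape(-1, 2)
    n = centers_um.shape[0]
    if group_of_center is None:
        group_of_center = np.arange(n)
    group_of_center = np.asarray(group_of_center)
    if n < 2 or np.unique(group_of_center).size < 2:
        return np.zeros(shape, dtype=bool)
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * um_per_px
    _, nearest = cKDTree(centers_um).query(pix)
    label = group_of_center[nearest].reshape(shape)
    boundary = np.zeros(shape, dtype=bool)
    diff_r = label[:, 1:] != label[:, :-1]
    boundary[:, 1:] |= diff_r
    boundary[:, :-1] |= diff_r
    diff_d = label[1:, :] != label[:-1, :]
    boundary[1:, :] |= diff_d
    boundary[:-1, :] |= diff_d
    if exclude_mask is not None:
        boundary &= ~np.asarray(exclude_mask, dtype=bool)
    return boundary


def blobset_centerline(blobs: BlobSet, shape: tuple[int, int]) -> np.ndarray:
    """Voronoi centerline of a segmented BlobSet's centers (grouped by blob)."""
    return voronoi_centerline(
        shape,
        blobs.um_per_px,
        blobs.all_blob_centers(),
        group_of_center=blobs.blob_id_of_center(),
    )


def apply_center_overrides(blobs: BlobSet, overrides: str | Path | pd.DataFrame) -> BlobSet:
    """Apply manual center corrections from a CSV table.

    Columns: ``action`` (add/remove), ``kind`` (blob/interblob), ``blob_id``
    (ignored for interblob), ``x_um``, ``y_um``.  ``remove`` drops the
    nearest existing center of that kind.  This replaces the interactive
    visual inspection step of the original workflow.
    """
    df = overrides if isinstance(overrides, pd.DataFrame) else pd.read_csv(overrides)
    centers = {b: v.copy() for b, v in blobs.blob_centers.items()}
    inter = blobs.interblob_centers.copy()
    for row in df.itertuples(index=False):
        p = np.array([row.x_um, row.y_um], dtype=float)
        if row.kind == "blob":
            b = int(row.blob_id)
            if row.action == "add":
                cur = centers.get(b, np.empty((0, 2)))
                centers[b] = np.vstack([cur, p])
            elif row.action == "remove" and b in centers and len(centers[b]) > 1:
                d = np.linalg.norm(centers[b] - p, axis=1)
                centers[b] = np.delete(centers[b], int(np.argmin(d)), axis=0)
        elif row.kind == "interblob":
            if row.action == "add":
                inter = np.vstack([inter, p])
            elif row.action == "remove" and len(inter):
                d = np.linalg.norm(inter - p, axis=1)
                inter = np.delete(inter, int(np.argmin(d)), axis=0)
    return replace(blobs, blob_centers=centers, interblob_centers=inter)
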