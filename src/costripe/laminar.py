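"""Laminar depth profiles of fluorescent label.

A 500-µm-wide column spanning the full cortical depth is centered on the
densest fluorescent label in a section cut perpendicular to the layers; the
column is split into 100 equal depth bins from the pia (depth 0) to the
white-matter border (depth 1), bin means are normalized to their maximum,
and per-layer bin datasets are pooled across sections and cases for the
nonparametric group comparisons.

Depth is normalized distance between the pia and white-matter polylines: at
each image column the pia and white-matter rows are interpolated from the
traced curves and a pixel's depth is its fractional position between them.
For flat synthetic sections this reduces to the row coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image import COMap


@dataclass
class LaminarAnnotation:
    """Manually traced section geometry.

    ``pia_curve`` and ``wm_curve`` are (n, 2) pixel polylines (columns x,
    y); ``layer_boundaries_frac`` are the fractional depths separating the
    named layers, ordered from the pia.
    """

    pia_curve: np.ndarray
    wm_curve: np.ndarray
    layer_boundaries_frac: tuple[float, ...]
    layer_names: tuple[str, ...]
    case_id: str = ""
    stripe_type: str = ""  # {thin, pale, thick, mixed}

    def __post_init__(self) -> None:
        self.pia_curve = np.asarray(self.pia_curve, dtype=float).reshape(-1, 2)
        self.wm_curve = np.asarray(self.wm_curve, dtype=float).reshape(-1, 2)
        b = np.asarray(self.layer_boundaries_frac, dtype=float)
        if b.size and (np.any(np.diff(b) <= 0) or b.min() <= 0 or b.max() >= 1):
            raise ValueError("layer boundaries must be strictly increasing in (0,1)")
        if len(self.layer_names) != b.size + 1:
            raise ValueError("need one layer name per interval")

    def layer_of_depth(self, depth: np.ndarray) -> np.ndarray:
        """Layer index for normalized depths; half-open [lower, upper) bands."""
        bounds = np.asarray(self.layer_boundaries_frac, dtype=float)
        return np.searchsorted(bounds, np.asarray(depth), side="right")

    def pia_wm_rows(self, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated pia and white-matter rows at the given columns."""
        cols = np.asarray(cols, dtype=float)
        pia = np.interp(cols, self.pia_curve[:, 0], self.pia_curve[:, 1])
        wm = np.interp(cols, self.wm_curve[:, 0], self.wm_curve[:, 1])
        if np.any(wm <= pia):
            raise ValueError("pia must lie above the white matter everywhere")
        return pia, wm


@dataclass
class LaminarProfile:
    """Normalized 100-bin pia-to-white-matter intensity profile."""

    bin_values: np.ndarray  # NaN where a bin had no valid pixel
    layer_of_bin: np.ndarray  # layer index per bin
    layer_names: tuple[str, ...]
    normalized: bool = True
    section_id: str = ""
    case_id: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)

    @property
    def depth_of_bin(self) -> np.ndarray:
        n = self.n_bins
        return (np.arange(1, n + 1) - 0.5) / n

    def layer_values(self, layer_name: str) -> np.ndarray:
        """Finite bin values falling in the named layer."""
        idx = self.layer_names.index(layer_name)
        vals = self.bin_values[self.layer_of_bin == idx]
        return vals[np.isfinite(vals)]


@dataclass
class ColumnROI:
    """A vertical column of fixed physical width, pia to white matter."""

    col_start: int
    col_stop: int  # exclusive
    width_um: float


def locate_densest_column(
    fluor: COMap, annotation: LaminarAnnotation, width_um: float = 500.0
) -> ColumnROI:
    """Column position maximizing total label between pia and white matter.

    Scans every feasible horizontal position of a ``width_um``-wide column
    and sums valid fluorescence between the pia and white-matter curves;
    ties go to the smallest (leftmost) position.
    """
    w_px = max(int(round(width_um / fluor.um_per_px)), 1)
    n_rows, n_cols = fluor.shape
    if w_px > n_cols:
        raise ValueError("column wider than the image")
    cols = np.arange(n_cols)
    pia, wm = annotation.pia_wm_rows(cols)
    rows = np.arange(n_rows)[:, None]
    band = (rows >= pia[None, :]) & (rows <= wm[None, :])
    weight = np.where(band & fluor.valid_mask, fluor.intensity, 0.0)
    col_sums = weight.sum(axis=0)
    if not np.any(col_sums > 0):
        raise ValueError("no fluorescent label in the annotated band")
    window_sums = np.convolve(col_sums, np.ones(w_px), mode="valid")
    start = int(np.argmax(window_sums))  # argmax returns the first maximum
    return ColumnROI(col_start=start, col_stop=start + w_px, width_um=width_um)


def laminar_profile(
    fluor: COMap,
    column: ColumnROI,
    annotation: LaminarAnnotation,
    n_bins: int = 100,
    section_id: str = "",
) -> LaminarProfile:
    """Mean label intensity in equal depth bins, normalized to the maximum.

    Bin ``k`` (1-based) collects valid pixels whose normalized depth lies in
    ``[(k-1)/n, k/n)`` (last bin closed); bins with no valid pixel are NaN
    and excluded downstream.  Each bin's layer follows from its center depth.
    """
    if column.col_start < 0 or column.col_stop > fluor.shape[1]:
        raise ValueError("column outside the image")
    cols = np.arange(column.col_start, column.col_stop)
    pia, wm = annotation.pia_wm_rows(cols)
    rows = np.arange(fluor.shape[0])[:, None]
    depth = (rows - pia[None, :]) / (wm - pia)[None, :]
    sub = fluor.intensity[:, cols]
    valid = fluor.valid_mask[:, cols] & (depth >= 0) & (depth <= 1)

    idx = np.floor(depth * n_bins).astype(int)
    idx[depth >= 1.0] = n_bins - 1
    vals = np.full(n_bins, np.nan)
    flat_idx = idx[valid]
    flat_val = sub[valid]
    sums = np.bincount(flat_idx, weights=flat_val, minlength=n_bins)
    counts = np.bincount(flat_idx, minlength=n_bins)
    nonempty = counts > 0
    vals[nonempty] = sums[nonempty] / counts[nonempty]

    peak = np.nanmax(vals) if np.any(np.isfinite(vals)) else np.nan
    if np.isfinite(peak) and peak > 0:
        vals = vals / peak
    centers = (np.arange(1, n_bins + 1) - 0.5) / n_bins
    return LaminarProfile(
        bin_values=vals,
        layer_of_bin=annotation.layer_of_depth(centers),
        layer_names=tuple(annotation.layer_names),
        section_id=section_id,
        case_id=annotation.case_id,
    )


def average_case_profile(profiles: Sequence[LaminarProfile]) -> LaminarProfile:
    """Per-bin mean across a case's section profiles, re-normalized to 1."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    n = profiles[0].n_bins
    if any(p.n_bins != n for p in profiles):
        raise ValueError("profiles have mismatched bin counts")
    stack = np.vstack([p.bin_values for p in profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    peak = np.nanmax(mean) if np.any(np.isfinite(mean)) else np.nan
    if np.isfinite(peak) and peak > 0:
        mean = mean / peak
    return LaminarProfile(
        bin_values=mean,
        layer_of_bin=profiles[0].layer_of_bin.copy(),
        layer_names=profiles[0].layer_names,
        case_id=profiles[0].case_id,
        section_id="case-average",
    )


def layer_bin_dataset(
    case_profiles: dict[str, Sequence[LaminarProfile]],
    layer_name: str,
) -> np.ndarray:
    """Pooled per-bin values for one layer across a group of cases.

    For each case the bins falling in the layer are averaged across that
    case's section profiles (bin by bin); the resulting per-bin values are
    pooled over all cases of the group.  This is the sample the
    Mann-Whitney / Kruskal-Wallis comparisons run on.
    """
    pooled: list[float] = []
    for case_id, profiles in case_profiles.items():
        profiles = list(profiles)
        if not profiles:
            continue
        names = profiles[0].layer_names
        if layer_name not in names:
            raise ValueError(f"layer {layer_name!r} absent in case {case_id!r}")
        layer_idx = names.index(layer_name)
        stack = np.vstack([p.bin_values for p in profiles])
        with np.errstate(invalid="ignore"):
            mean_bins = np.nanmean(stack, axis=0)
        sel = profiles[0].layer_of_bin == layer_idx
        vals = mean_bins[sel]
        pooled.extend(vals[np.isfinite(vals)].tolist())
    return np.asarray(pooled, dtype=float)
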