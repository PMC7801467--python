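"""Calibrated 2D intensity maps.

The package's central raster container is :class:`COMap`: a single-channel
image of a stained or fluorescence-imaged cortical section together with its
physical calibration (µm per pixel) and a validity mask.  Pixels can become
invalid through registration (out-of-domain resampling), tissue damage, or a
user-supplied exclusion mask; invalid pixels are excluded from every
downstream intensity statistic rather than being zero-filled.

Coordinate conventions (used throughout the package):

* pixel indices are 0-based, ``x`` = column, ``y`` = row;
* a pixel's physical position is its center: ``µm = index * um_per_px``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class COMap:
    """A calibrated grayscale section image.

    Parameters
    ----------
    intensity : ndarray, shape (rows, cols)
        Pixel intensities (float).  Finite on valid pixels.
    um_per_px : float
        Physical pixel size in µm; must be positive.
    valid_mask : ndarray of bool, same shape, optional
        True where the pixel carries usable signal.  Defaults to all-valid.
    modality : {"co", "fluorescence"}
        Whether the image is a cytochrome-oxidase stain (dark = high enzyme
        activity, i.e. blobs are *dark*) or a fluorescent label image
        (bright = label).
    """

    intensity: np.ndarray
    um_per_px: float
    valid_mask: np.ndarray | None = None
    modality: str = "co"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D grid")
        if not (self.um_per_px > 0):
            raise ValueError("um_per_px must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.intensity.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.intensity.shape:
                raise ValueError("valid_mask shape must match intensity")
        if self.modality not in ("co", "fluorescence"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.intensity[self.valid_mask])):
            raise ValueError("non-finite intensity on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def valid_values(self) -> np.ndarray:
        """Intensities of valid pixels, flattened."""
        return self.intensity[self.valid_mask]

    def copy(self) -> "COMap":
        return replace(
            self,
            intensity=self.intensity.copy(),
            valid_mask=self.valid_mask.copy(),
            meta=dict(self.meta),
        )


def save_comap(path: str | Path, comap: COMap, **sidecar) -> None:
    """Write a COMap as 16-bit grayscale TIFF plus a JSON sidecar.

    Intensities are linearly rescaled to the uint16 range; the scale and
    offset are recorded in the sidecar so :func:`load_comap` round-trips the
    physical values.  Extra keyword arguments are stored verbatim in the
    sidecar (parameters, seeds, ground truth, ...).
    """
    path = Path(path)
    vals = comap.valid_values()
    lo = float(vals.min()) if vals.size else 0.0
    hi = float(vals.max()) if vals.size else 1.0
    span = hi - lo if hi > lo else 1.0
    scaled = np.zeros(comap.shape, dtype=np.uint16)
    scaled[comap.valid_mask] = np.round(
        (comap.intensity[comap.valid_mask] - lo) / span * 65535
    ).astype(np.uint16)
    tifffile.imwrite(path, scaled)
    sidecar_doc = {
        "um_per_px": comap.um_per_px,
        "modality": comap.modality,
        "intensity_offset": lo,
        "intensity_scale": span / 65535,
        "valid_mask_rle": _rle_encode(comap.valid_mask),
        "shape": list(comap.shape),
        "meta": comap.meta,
        **sidecar,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar_doc, indent=1, sort_keys=True)
    )


def load_comap(path: str | Path) -> COMap:
    """Read a COMap written by :func:`save_comap`."""
    path = Path(path)
    raw = tifffile.imread(path).astype(float)
    doc = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    intensity = raw * doc["intensity_scale"] + doc["intensity_offset"]
    valid = _rle_decode(doc["valid_mask_rle"], tuple(doc["shape"]))
    intensity[~valid] = doc["intensity_offset"]
    return COMap(
        intensity=intensity,
        um_per_px=doc["um_per_px"],
        valid_mask=valid,
        modality=doc["modality"],
        meta=doc.get("meta", {}),
    )


def _rle_encode(mask: np.ndarray) -> str:
    """Run-length encode a boolean grid (row-major) as 'start:len,...'."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return ""
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, stops = edges[::2], edges[1::2]
    return ",".join(f"{s}:{e - s}" for s, e in zip(starts, stops))


def _rle_decode(rle: str, shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    if rle:
        for run in rle.split(","):
            start, length = run.split(":")
            flat[int(start) : int(start) + int(length)] = True
    return flat.reshape(shape)
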