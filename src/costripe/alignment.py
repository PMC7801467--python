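"""Landmark-driven thin-plate-spline registration of serial sections.

Serial tangential sections are brought into a common frame by registering
the radial blood vessels that pierce them: corresponding landmark points are
placed on adjacent sections and a thin-plate spline (TPS) interpolant is
fitted pair by pair, then composed through the stack down to the reference
(most superficial) section.

The TPS warp minimizes the integral bending energy among all maps that
interpolate the landmarks; its closed form is an affine part plus a radial
kernel expansion with kernel ``U(r) = r^2 log r`` (``U(0) = 0``).  With
``regularization_lambda = 0`` the warp passes exactly through every landmark
pair; a positive lambda trades landmark fidelity for smoothness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import COMap


@dataclass
class PointSet:
    """Named set of 2D points in µm."""

    points: np.ndarray  # (n, 2), columns (x, y)
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


class DegenerateConfigurationError(ValueError):
    """Raised when landmarks are too few or collinear for a TPS fit."""


class AlignmentChainError(ValueError):
    """Raised when a pairwise landmark set is missing from a stack."""


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, with the removable singularity U(0) = 0
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass
class WarpModel:
    """A fitted thin-plate-spline map from one section frame to another."""

    control_points: PointSet
    affine_part: np.ndarray  # (2, 3): rows (x', y') = A @ [1, x, y]
    kernel_weights: np.ndarray  # (n, 2): columns (wx, wy)
    regularization_lambda: float = 0.0

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) µm points through the warp."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        ones = np.column_stack([np.ones(len(pts)), pts])
        out = ones @ self.affine_part.T
        if len(self.control_points):
            d = np.linalg.norm(
                pts[:, None, :] - self.control_points.points[None, :, :], axis=2
            )
            out = out + _tps_kernel(d) @ self.kernel_weights
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.transform(points)

    def to_json(self) -> str:
        return json.dumps(
            {
                "control_points": self.control_points.points.tolist(),
                "frame_id": self.control_points.frame_id,
                "affine_part": self.affine_part.tolist(),
                "kernel_weights": self.kernel_weights.tolist(),
                "regularization_lambda": self.regularization_lambda,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "WarpModel":
        doc = json.loads(text)
        return cls(
            control_points=PointSet(
                np.asarray(doc["control_points"]), doc.get("frame_id", "")
            ),
            affine_part=np.asarray(doc["affine_part"]),
            kernel_weights=np.asarray(doc["kernel_weights"]),
            regularization_lambda=doc["regularization_lambda"],
        )


def identity_warp() -> WarpModel:
    """A WarpModel that maps every point to itself."""
    return WarpModel(
        control_points=PointSet(np.empty((0, 2))),
        affine_part=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        kernel_weights=np.empty((0, 2)),
    )


@dataclass
class ComposedWarp:
    """Chain of warps applied left to right (function composition)."""

    stages: list = field(default_factory=list)

    def transform(self, points: np.ndarray) -> np.ndarray:
        out = np.asarray(points, dtype=float).reshape(-1, 2)
        for stage in self.stages:
            out = stage.transform(out)
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.transform(points)

    @property
    def is_identity(self) -> bool:
        return len(self.stages) == 0


def fit_thin_plate_spline(
    src: PointSet, dst: PointSet, regularization_lambda: float = 0.0
) -> WarpModel:
    """Fit the TPS warp carrying ``src`` landmarks onto ``dst``.

    With ``regularization_lambda = 0`` (the default, matching interactive
    landmark-registration tools) the fitted warp maps every source landmark
    exactly onto its destination.

    Raises
    ------
    DegenerateConfigurationError
        fewer than 3 points, mismatched counts, or a collinear source set.
    """
    if len(src) != len(dst):
        raise DegenerateConfigurationError("point counts differ")
    n = len(src)
    if n < 3:
        raise DegenerateConfigurationError("need at least 3 landmark pairs")
    if regularization_lambda < 0:
        raise ValueError("regularization_lambda must be >= 0")
    P = np.column_stack([np.ones(n), src.points])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src.points).max())) < 3:
        raise DegenerateConfigurationError("source landmarks are collinear")

    d = np.linalg.norm(src.points[:, None, :] - src.points[None, :, :], axis=2)
    K = _tps_kernel(d) + regularization_lambda * np.eye(n)
    # bordered system [[K, P], [P^T, 0]] [w; a] = [dst; 0]
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst.points
    sol = np.linalg.solve(L, rhs)
    weights = sol[:n]
    affine = sol[n:].T  # (2, 3) acting on [1, x, y]
    return WarpModel(
        control_points=PointSet(src.points.copy(), src.frame_id),
        affine_part=affine,
        kernel_weights=weights,
        regularization_lambda=regularization_lambda,
    )


def warp_image(
    img: COMap,
    warp,
    interpolation: str = "bilinear",
    out_shape: tuple[int, int] | None = None,
) -> COMap:
    """Resample ``img`` into a target frame.

    ``warp`` maps target-frame µm coordinates to source-frame µm coordinates
    (the pull-back convention standard in image resampling): the output
    pixel at physical position ``q`` takes the source intensity at
    ``warp(q)``.  Pixels whose pull-back lands outside the source image, or
    on invalid source pixels, are flagged invalid rather than zero-filled.
    """
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")
    out_shape = tuple(out_shape) if out_shape is not None else img.shape
    ys, xs = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    q = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * img.um_per_px
    p = warp.transform(q) if hasattr(warp, "transform") else warp(q)
    col = (p[:, 0] / img.um_per_px).reshape(out_shape)
    row = (p[:, 1] / img.um_per_px).reshape(out_shape)

    order = 0 if interpolation == "nearest" else 1
    coords = np.stack([row, col])
    out = ndimage.map_coordinates(
        img.intensity, coords, order=order, mode="constant", cval=np.nan
    )
    in_bounds = (
        (row >= -0.5) & (row <= img.shape[0] - 0.5)
        & (col >= -0.5) & (col <= img.shape[1] - 0.5)
    )
    if order == 1:
        # bilinear support must lie fully on valid, in-bounds pixels
        in_bounds = (
            (row >= 0) & (row <= img.shape[0] - 1)
            & (col >= 0) & (col <= img.shape[1] - 1)
        )
        vsup = ndimage.map_coordinates(
            img.valid_mask.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        valid = in_bounds & (vsup >= 1.0 - 1e-9)
    else:
        vnear = ndimage.map_coordinates(
            img.valid_mask.astype(np.uint8), coords, order=0, mode="constant", cval=0
        )
        valid = in_bounds & (vnear > 0)
    out = np.where(valid, out, 0.0)
    return COMap(
        intensity=out,
        um_per_px=img.um_per_px,
        valid_mask=valid,
        modality=img.modality,
    )


@dataclass
class SectionStack:
    """Serial sections with composed warps into the reference frame.

    ``to_reference[k]`` maps section-``k`` coordinates into the frame of
    section 0 (the most superficial section); ``from_reference[k]`` is the
    inverse-direction composition used to resample section ``k`` into the
    reference frame.  The reference section's composed warp is the identity.
    """

    sections: list
    to_reference: list
    from_reference: list

    def render_in_reference(self, k: int, interpolation: str = "bilinear") -> COMap:
        ref_shape = self.sections[0].shape
        return warp_image(
            self.sections[k],
            self.from_reference[k],
            interpolation=interpolation,
            out_shape=ref_shape,
        )


def align_stack(
    sections: Sequence[COMap],
    pairwise_landmarks: Sequence[tuple[PointSet, PointSet] | None],
    regularization_lambda: float = 0.0,
) -> SectionStack:
    """Compose pairwise TPS warps into a sequential stack.

    ``pairwise_landmarks[k]`` holds matched points ``(on section k+1, on
    section k)`` for each adjacent pair; composition is by function chaining
    (the warp for section ``k`` is the pairwise warp ``k -> k-1`` followed by
    the already-composed warp for ``k-1``), never by re-fitting.
    """
    sections = list(sections)
    n = len(sections)
    if n == 0:
        raise ValueError("empty stack")
    if len(pairwise_landmarks) != n - 1:
        raise AlignmentChainError(
            f"need {n - 1} pairwise landmark sets, got {len(pairwise_landmarks)}"
        )
    to_ref: list[ComposedWarp] = [ComposedWarp([])]
    from_ref: list[ComposedWarp] = [ComposedWarp([])]
    for k in range(1, n):
        pair = pairwise_landmarks[k - 1]
        if pair is None:
            raise AlignmentChainError(f"missing landmarks for pair {k - 1}-{k}")
        on_deeper, on_upper = pair
        fwd = fit_thin_plate_spline(on_deeper, on_upper, regularization_lambda)
        inv = fit_thin_plate_spline(on_upper, on_deeper, regularization_lambda)
        to_ref.append(ComposedWarp([fwd] + list(to_ref[k - 1].stages)))
        from_ref.append(ComposedWarp(list(from_ref[k - 1].stages) + [inv]))
    return SectionStack(sections=sections, to_reference=to_ref, from_reference=from_ref)


def read_landmarks_csv(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    """Read landmark files: columns section_id, point_id, x_px, y_px."""
    df = pd.read_csv(path, dtype={"section_id": str, "point_id": str})
    required = {"section_id", "point_id", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.section_id, {})[row.point_id] = (
            float(row.x_px),
            float(row.y_px),
        )
    return out


def landmark_pairs_from_table(
    table: dict[str, dict[str, tuple[float, float]]],
    section_order: Sequence[str],
    um_per_px: float,
) -> list[tuple[PointSet, PointSet]]:
    """Build adjacent-pair PointSets from a landmark table, matched by point_id."""
    pairs = []
    for deeper, upper in zip(section_order[1:], section_order[:-1]):
        shared = sorted(set(table.get(deeper, {})) & set(table.get(upper, {})))
        if len(shared) < 3:
            raise AlignmentChainError(
                f"sections {deeper!r}/{upper!r} share {len(shared)} landmarks (<3)"
            )
        a = np.array([table[deeper][p] for p in shared]) * um_per_px
        b = np.array([table[upper][p] for p in shared]) * um_per_px
        pairs.append((PointSet(a, deeper), PointSet(b, upper)))
    return pairs
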