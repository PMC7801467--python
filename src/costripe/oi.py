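"""Intrinsic-signal optical imaging: baseline corrections and difference maps.

Single-condition responses (trial-averaged frames per stimulus condition)
are corrected against the pre-stimulus baseline in one of three standard
ways — baseline subtraction, baseline division, or division by the
"cocktail blank" (the mean response over all conditions) — and condition
pairs are subtracted to reveal functional domains (orthogonal orientations;
low minus high spatial frequency).  Which correction gives the cleanest
maps is a judgment call for the experimenter; all three are exposed and
none is auto-selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ConditionStack:
    """Trial-averaged single-condition frames plus a baseline frame."""

    frames: dict[str, np.ndarray]
    baseline: np.ndarray | None = None
    modality: str = "orientation"  # or "sf"
    invalid_mask: np.ndarray | None = None  # True where flagged invalid

    def __post_init__(self) -> None:
        shapes = {np.asarray(f).shape for f in self.frames.values()}
        if self.baseline is not None:
            shapes.add(np.asarray(self.baseline).shape)
        if len(shapes) > 1:
            raise ValueError(f"frames have mismatched shapes: {shapes}")
        self.frames = {k: np.asarray(v, dtype=float) for k, v in self.frames.items()}
        if self.baseline is not None:
            self.baseline = np.asarray(self.baseline, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.frames.values())).shape


@dataclass
class DifferenceMap:
    """Corrected response difference between two conditions."""

    grid: np.ndarray
    pair: tuple[str, str]
    correction_mode: str
    invalid_mask: np.ndarray | None = None


def average_trials(
    trials: np.ndarray, bad_trials: np.ndarray | None = None
) -> np.ndarray:
    """Mean over the trial axis (axis 0), ignoring flagged bad trials."""
    trials = np.asarray(trials, dtype=float)
    if bad_trials is not None:
        keep = ~np.asarray(bad_trials, dtype=bool)
        if not keep.any():
            raise ValueError("all trials flagged bad")
        trials = trials[keep]
    return trials.mean(axis=0)


def baseline_correct(stack: ConditionStack, mode: str) -> ConditionStack:
    """Correct single-condition frames against a baseline.

    ``subtract``: frame − baseline.  ``divide``: frame / baseline.
    ``cocktail``: frame / (mean over all condition frames).  Division by
    zero-valued pixels flags those pixels invalid instead of propagating
    infinities.
    """
    if mode not in ("subtract", "divide", "cocktail"):
        raise ValueError("mode must be subtract, divide, or cocktail")
    if mode in ("subtract", "divide") and stack.baseline is None:
        raise ValueError(f"mode {mode!r} needs a baseline frame")
    if mode == "cocktail" and len(stack.frames) < 2:
        raise ValueError("cocktail blank needs at least 2 conditions")

    if mode == "subtract":
        denom = None
        ref = stack.baseline
    elif mode == "divide":
        denom = stack.baseline
    else:
        denom = np.mean(list(stack.frames.values()), axis=0)

    invalid = np.zeros(stack.shape, dtype=bool)
    if stack.invalid_mask is not None:
        invalid |= stack.invalid_mask
    out = {}
    if denom is None:
        for k, f in stack.frames.items():
            out[k] = f - ref
    else:
        zero = denom == 0
        invalid |= zero
        safe = np.where(zero, 1.0, denom)
        for k, f in stack.frames.items():
            out[k] = np.where(zero, 0.0, f / safe)
    return ConditionStack(
        frames=out,
        baseline=stack.baseline,
        modality=stack.modality,
        invalid_mask=invalid,
    )


def difference_map(
    stack: ConditionStack, cond_a: str, cond_b: str, correction_mode: str = ""
) -> DifferenceMap:
    """Subtract condition B from condition A (A − B).

    By convention, for spatial-frequency stacks A is the low-SF and B the
    high-SF condition.  The map is exactly antisymmetric in (A, B).
    """
    for c in (cond_a, cond_b):
        if c not in stack.frames:
            raise KeyError(f"condition {c!r} not in stack")
    return DifferenceMap(
        grid=stack.frames[cond_a] - stack.frames[cond_b],
        pair=(cond_a, cond_b),
        correction_mode=correction_mode,
        invalid_mask=None if stack.invalid_mask is None else stack.invalid_mask.copy(),
    )
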