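"""Sub-pixel rigid x-y registration within and across trials.

Shift estimation uses single-step DFT-upsampled cross-correlation
(scikit-image's ``phase_cross_correlation``); correction is applied by
periodic Fourier resampling, matching the simulator's motion model so
round-trips are exact.

Shift sign convention: ``estimate_shift(ref, target)`` returns the
displacement of the target's content *relative to* the reference —
``target ≈ translate(ref, dx, dy)``. ``shift_frame`` applies the inverse
translation, so ``shift_frame(target, estimate_shift(ref, target)) ≈ ref``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

from tastekit.io import TrialMovie
from tastekit.synthetic import translate_frame

__all__ = ["Shift", "RegistrationResult", "estimate_shift", "shift_frame", "register_session"]

REFERENCE_POLICIES = ("first-baseline", "per-trial", "global-mean")


@dataclass(frozen=True)
class Shift:
    dx: float
    dy: float
    error_metric: float = 0.0

    def __neg__(self) -> "Shift":
        return Shift(-self.dx, -self.dy, self.error_metric)

    def as_tuple(self) -> tuple[float, float]:
        return (self.dx, self.dy)


@dataclass
class RegistrationResult:
    registered_movie: TrialMovie
    shifts: list[Shift]
    reference_descriptor: str


def estimate_shift(reference: np.ndarray, target: np.ndarray, upsample: int = 20) -> Shift:
    """Estimate the (dx, dy) content displacement of ``target`` relative to
    ``reference``, refined to 1/``upsample`` pixel.

    Raises ``ValueError`` for constant images (correlation undefined) or
    mismatched shapes.
    """
    reference = np.asarray(reference, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if reference.shape != target.shape:
        raise ValueError(f"image shapes differ: {reference.shape} vs {target.shape}")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if np.ptp(reference) == 0 or np.ptp(target) == 0:
        raise ValueError("constant image: cross-correlation shift is undefined")
    (row_shift, col_shift), error, _ = phase_cross_correlation(
        reference, target, upsample_factor=upsample, normalization=None
    )
    # skimage reports the shift that moves the target back onto the
    # reference; the content displacement is its negation.
    return Shift(dx=float(-col_shift), dy=float(-row_shift), error_metric=float(error))


def shift_frame(frame: np.ndarray, shift: Shift | tuple[float, float]) -> np.ndarray:
    """Undo a content displacement: translate by (−dx, −dy), periodic boundaries."""
    if isinstance(shift, Shift):
        dx, dy = shift.dx, shift.dy
    else:
        dx, dy = shift
    return translate_frame(np.asarray(frame, dtype=np.float64), -dx, -dy)


def _build_reference(trials: Sequence[TrialMovie], policy: str | np.ndarray) -> tuple[np.ndarray | None, str]:
    if isinstance(policy, np.ndarray):
        return policy.astype(np.float64), "fixed external reference"
    if policy == "first-baseline":
        first = trials[0]
        ref = first.frames[: first.onset_frame].mean(axis=0)
        return ref, "mean of first trial's baseline frames"
    if policy == "global-mean":
        ref = np.mean(np.concatenate([t.frames for t in trials], axis=0), axis=0)
        return ref, "mean of all frames in session"
    if policy == "per-trial":
        return None, "first frame of each trial"
    raise ValueError(f"unknown reference policy {policy!r}; choose from {REFERENCE_POLICIES}")


def register_session(
    trials: Sequence[TrialMovie],
    policy: str | np.ndarray = "first-baseline",
    upsample: int = 20,
) -> list[RegistrationResult]:
    """Register every frame of every trial to a common reference.

    Default policy builds the reference from the first trial's pre-stimulus
    frames, aligning frames both within and across trials. Pass an ndarray
    for a fixed external reference, or ``"per-trial"`` to align each trial
    only to its own first frame.
    """
    if not trials:
        raise ValueError("need at least one trial")
    shapes = {t.frame_shape for t in trials}
    if len(shapes) > 1:
        raise ValueError(f"trials have mismatched frame shapes: {sorted(shapes)}")

    ref, descriptor = _build_reference(trials, policy)
    results: list[RegistrationResult] = []
    for trial in trials:
        trial_ref = trial.frames[0] if ref is None else ref
        shifts: list[Shift] = []
        registered = np.empty_like(trial.frames, dtype=np.float64)
        for i, frame in enumerate(trial.frames):
            s = estimate_shift(trial_ref, frame, upsample=upsample)
            shifts.append(s)
            registered[i] = shift_frame(frame, s)
        results.append(
            RegistrationResult(
                registered_movie=trial.with_frames(registered),
                shifts=shifts,
                reference_descriptor=descriptor,
            )
        )
    return results
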