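"""From registered movies to response statistics.

The summary statistics follow the source protocol exactly: F₀ is the mean
of the 20 frames immediately preceding stimulus onset; the peak response is
the mean of the two highest consecutive ΔF/F₀ frames during tastant
presentation; a fly "responds" to a tastant when its trial-averaged peak
exceeds its trial-averaged water peak by at least θ (0.15 absolute ΔF/F₀,
i.e. 15 percentage points, by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from tastekit.io import TrialMovie

__all__ = [
    "RawTrace",
    "DffTrace",
    "ResponderCall",
    "roi_trace",
    "compute_dff",
    "peak_response",
    "integrated_response",
    "fly_average",
    "classify_responder",
    "quantify_trial",
    "quantify_session",
]

DEFAULT_THETA = 0.15
DEFAULT_N_BASELINE = 20
MIN_TRIALS_FOR_CALL = 3


@dataclass
class RawTrace:
    """Mean ROI intensity per frame plus stimulus timing."""

    values: np.ndarray
    frame_rate: float
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not 0 <= self.onset_frame < self.offset_frame < len(self.values):
            raise ValueError("stimulus window outside trace")


@dataclass
class DffTrace:
    f0: float
    dff: np.ndarray
    frame_rate: float
    baseline_frames: np.ndarray
    stimulus_frames: np.ndarray


@dataclass
class ResponderCall:
    fly_id: str
    stimulus: str
    mean_peak: float
    water_mean_peak: float
    theta: float
    is_responder: bool
    n_trials: int
    n_water_trials: int


def roi_trace(movie: TrialMovie, roi: np.ndarray) -> RawTrace:
    """Unweighted per-frame mean over the ROI mask pixels."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != movie.frame_shape:
        raise ValueError(f"ROI shape {roi.shape} != frame shape {movie.frame_shape}")
    if not roi.any():
        raise ValueError("empty ROI mask")
    values = movie.frames[:, roi].mean(axis=1)
    return RawTrace(
        values=values,
        frame_rate=movie.frame_rate,
        onset_frame=movie.onset_frame,
        offset_frame=movie.offset_frame,
    )


def compute_dff(trace: RawTrace, n_baseline: int = DEFAULT_N_BASELINE) -> DffTrace:
    """ΔF/F₀ with F₀ = mean of the ``n_baseline`` frames immediately
    preceding stimulus onset.

    Rejects (rather than imputes) traces with non-finite values in the
    baseline or stimulus window, and non-positive F₀.
    """
    if trace.onset_frame < n_baseline:
        raise ValueError(
            f"only {trace.onset_frame} pre-stimulus frames; need {n_baseline} for the baseline"
        )
    baseline_frames = np.arange(trace.onset_frame - n_baseline, trace.onset_frame)
    stimulus_frames = np.arange(trace.onset_frame, trace.offset_frame + 1)
    checked = np.concatenate([baseline_frames, stimulus_frames])
    if not np.all(np.isfinite(trace.values[checked])):
        raise ValueError("non-finite trace values in baseline or stimulus window; trial rejected")
    f0 = float(trace.values[baseline_frames].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0 ({f0}); trial rejected")
    dff = (trace.values - f0) / f0
    return DffTrace(
        f0=f0,
        dff=dff,
        frame_rate=trace.frame_rate,
        baseline_frames=baseline_frames,
        stimulus_frames=stimulus_frames,
    )


def peak_response(dff: DffTrace, post_extension_s: float = 0.0) -> float:
    """Mean of the two highest consecutive ΔF/F₀ frames during presentation.

    Ties go to the earliest pair. ``post_extension_s`` optionally extends
    the search window past valve closure for slow transients (default off).
    """
    last = dff.stimulus_frames[-1] + int(round(post_extension_s * dff.frame_rate))
    last = min(last, len(dff.dff) - 1)
    window = dff.dff[dff.stimulus_frames[0] : last + 1]
    if len(window) < 2:
        raise ValueError("need at least 2 stimulus frames for the consecutive-pair peak")
    pair_means = (window[:-1] + window[1:]) / 2.0
    return float(pair_means[np.argmax(pair_means)])


def integrated_response(
    dff: DffTrace,
    window: tuple[int, int] | None = None,
    post_extension_s: float = 2.0,
) -> float:
    """Trapezoidal time-integral of ΔF/F₀ (units: ΔF/F₀ · s).

    Default window is the stimulus window extended ``post_extension_s``
    seconds past offset (the integration window is a configurable choice).
    """
    if window is None:
        start = int(dff.stimulus_frames[0])
        stop = int(dff.stimulus_frames[-1]) + int(round(post_extension_s * dff.frame_rate))
        stop = min(stop, len(dff.dff) - 1)  # default window clamps to trace end
    else:
        start, stop = window
    if start < 0 or stop >= len(dff.dff) or stop <= start:
        raise ValueError(f"integration window [{start}, {stop}] outside trace")
    return float(np.trapezoid(dff.dff[start : stop + 1], dx=1.0 / dff.frame_rate))


def fly_average(values: Sequence[float], included: Sequence[bool] | None = None) -> tuple[float, int]:
    """Mean over included trials; returns (mean, n_included).

    Trials are only dropped for delivery failures, flagged by the caller.
    All trials excluded is an error, not zero.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.ones(len(values), bool) if included is None else np.asarray(included, bool)
    if mask.shape != values.shape:
        raise ValueError("included flags must match values")
    if not mask.any():
        raise ValueError("all trials excluded; cannot average")
    return float(values[mask].mean()), int(mask.sum())


def classify_responder(
    mean_peak: float,
    water_mean_peak: float,
    theta: float = DEFAULT_THETA,
    *,
    fly_id: str = "",
    stimulus: str = "",
    n_trials: int = MIN_TRIALS_FOR_CALL,
    n_water_trials: int = MIN_TRIALS_FOR_CALL,
) -> ResponderCall:
    """Responder ⇔ mean_peak − water_mean_peak ≥ θ (inclusive).

    θ is in absolute ΔF/F₀ fraction: the default 0.15 means 15 percentage
    points. Requires ≥3 included trials behind each mean.
    """
    if n_trials < MIN_TRIALS_FOR_CALL or n_water_trials < MIN_TRIALS_FOR_CALL:
        raise ValueError(
            f"responder calls need >= {MIN_TRIALS_FOR_CALL} trials per stimulus "
            f"(got {n_trials} stimulus, {n_water_trials} water)"
        )
    return ResponderCall(
        fly_id=fly_id,
        stimulus=stimulus,
        mean_peak=float(mean_peak),
        water_mean_peak=float(water_mean_peak),
        theta=float(theta),
        is_responder=bool(mean_peak - water_mean_peak >= theta),
        n_trials=n_trials,
        n_water_trials=n_water_trials,
    )


def quantify_trial(
    movie: TrialMovie,
    roi: np.ndarray,
    n_baseline: int = DEFAULT_N_BASELINE,
    integration_post_s: float = 2.0,
) -> dict:
    """Convenience: ROI trace → ΔF/F₀ → peak and integrated statistics."""
    dff = compute_dff(roi_trace(movie, roi), n_baseline=n_baseline)
    return {
        "fly_id": movie.fly_id,
        "stimulus": movie.stimulus,
        "trial_index": movie.trial_index,
        "f0": dff.f0,
        "peak": peak_response(dff),
        "integrated": integrated_response(dff, post_extension_s=integration_post_s),
    }


def quantify_session(
    movies: Sequence[TrialMovie],
    roi: np.ndarray,
    n_baseline: int = DEFAULT_N_BASELINE,
    thetas: Sequence[float] = (0.10, 0.15, 0.20),
    integration_post_s: float = 2.0,
    water_stimulus: str = "water",
    included: Sequence[bool] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial and per-fly summary tables for a set of registered movies.

    Responder calls (one column per θ) are made only for fly × stimulus
    combinations with ≥3 included trials of both the stimulus and water.
    """
    inc = [True] * len(movies) if included is None else list(included)
    rows = []
    for movie, ok in zip(movies, inc):
        row = quantify_trial(movie, roi, n_baseline=n_baseline, integration_post_s=integration_post_s)
        row["included"] = bool(ok)
        rows.append(row)
    per_trial = pd.DataFrame(rows)

    fly_rows = []
    for (fly_id, stimulus), grp in per_trial.groupby(["fly_id", "stimulus"], sort=False):
        sub = grp[grp["included"]]
        if len(sub) == 0:
            continue
        fly_rows.append(
            {
                "fly_id": fly_id,
                "stimulus": stimulus,
                "mean_peak": sub["peak"].mean(),
                "mean_integrated": sub["integrated"].mean(),
                "n_trials": len(sub),
            }
        )
    per_fly = pd.DataFrame(fly_rows)
    if len(per_fly) == 0:
        return per_trial, per_fly

    water = per_fly[per_fly["stimulus"] == water_stimulus].set_index("fly_id")
    for theta in thetas:
        col = []
        for _, row in per_fly.iterrows():
            fly, stim = row["fly_id"], row["stimulus"]
            if (
                stim == water_stimulus
                or fly not in water.index
                or row["n_trials"] < MIN_TRIALS_FOR_CALL
                or water.loc[fly, "n_trials"] < MIN_TRIALS_FOR_CALL
            ):
                col.append(np.nan)
            else:
                call = classify_responder(
                    row["mean_peak"],
                    water.loc[fly, "mean_peak"],
                    theta=theta,
                    fly_id=str(fly),
                    stimulus=str(stim),
                    n_trials=int(row["n_trials"]),
                    n_water_trials=int(water.loc[fly, "n_trials"]),
                )
                col.append(call.is_responder)
        per_fly[f"responder_theta_{theta:g}"] = col
    return per_trial, per_fly
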