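"""Synthetic imaging sessions and behavioral datasets with ground truth.

Every generator draws from named substreams of a single seed, so identical
``(params, seed)`` produce bit-identical outputs and independent components
stay independent when parameters change.

Imaging model
-------------
Each trial movie is built as::

    clean_t = baseline_intensity * (1 + texture + b * w) * (1 + a * k(t) * w)

where ``texture`` is a fixed smooth random field (anatomical contrast the
registration stage can lock onto), ``b`` is the ROI's resting-fluorescence
elevation, ``w`` is a soft-edged disk ROI weight map, and ``k(t)`` is a
difference-of-exponentials fluorescence transient.
``a`` is the trial's true amplitude: ``schedule[stimulus] *
adaptation_factor**trial_index * LogNormal(mean=1, cv=trial_cv)``.

The transient kernel is calibrated per frame grid so that the pipeline's
peak statistic (mean of the two highest consecutive in-window frames)
equals exactly 1 for unit amplitude. True amplitudes are therefore
directly comparable to measured peak ΔF/F₀ values, and with noise and
drift off the measured peak equals the true amplitude to machine
precision.

Frames are then rigidly translated by a cumulative drift + jitter process
(periodic Fourier resampling, so registration round-trips are exact), and
photon (Poisson) plus Gaussian read noise are added at the detector.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from tastekit.io import TrialMovie

__all__ = [
    "RoiSpec",
    "ImagingSimParams",
    "SyntheticTrial",
    "BehaviorSimParams",
    "PERDataset",
    "DirectionalDataset",
    "substream",
    "transient_kernel",
    "make_imaging_trial",
    "make_imaging_session",
    "default_behavior_params",
    "make_per_dataset",
    "make_directional_dataset",
    "marginal_per_probability",
    "marginal_positive_test_probability",
]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Independent generator for a named substream of a master seed.

    The stream key is a stable (process-independent) hash of the names, so
    e.g. the noise stream of trial 3 never changes when the drift model of
    trial 2 does.
    """
    tag = "/".join(str(n) for n in names)
    digest = hashlib.blake2b(tag.encode(), digest_size=8).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiSpec:
    """Soft-edged disk standing in for a manually drawn axonal-projection ROI.

    ``radius`` delimits the full-weight core (the "true mask"); signal
    weight decays linearly to zero over ``soft_edge`` pixels beyond it.
    """

    center_row: float = 128.0
    center_col: float = 128.0
    radius: float = 30.0
    soft_edge: float = 4.0

    def weight_map(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dist = np.hypot(rr - self.center_row, cc - self.center_col)
        if self.soft_edge <= 0:
            return (dist <= self.radius).astype(np.float64)
        w = np.clip(1.0 - (dist - self.radius) / self.soft_edge, 0.0, 1.0)
        return w

    def true_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean full-weight core; ROI means over it recover amplitudes unbiased."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dist = np.hypot(rr - self.center_row, cc - self.center_col)
        return dist <= self.radius

    def validate(self, shape: tuple[int, int]) -> None:
        extent = self.radius + max(self.soft_edge, 0.0)
        if (
            self.center_row - extent < 0
            or self.center_col - extent < 0
            or self.center_row + extent > shape[0] - 1
            or self.center_col + extent > shape[1] - 1
        ):
            raise ValueError(f"ROI {self} extends outside {shape[0]}x{shape[1]} frame bounds")


@dataclass
class ImagingSimParams:
    frame_height: int = 256
    frame_width: int = 256
    frame_rate: float = 3.5
    stimulus_duration: float = 2.0
    n_baseline_frames: int = 20
    n_post_frames: int = 12
    n_trials_per_stimulus: int = 3
    roi_spec: RoiSpec = field(default_factory=RoiSpec)
    amplitude_schedule: Mapping[str, float] = field(
        default_factory=lambda: {"water": 0.0, "sucrose": 1.0, "acid_1pct": 0.5}
    )
    trial_cv: float = 0.2
    adaptation_factor: float = 1.0
    transient_rise_tau: float = 0.1
    transient_decay_tau: float = 0.4
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    drift_jitter_sd: float = 0.0
    photon_gain: float = 0.0  # counts per photon; 0 disables photon noise
    read_noise_sd: float = 0.0
    baseline_intensity: float = 1000.0
    texture_contrast: float = 0.25
    # resting-fluorescence elevation of the ROI: labeled projections are
    # visible at baseline, which is what anchors registration during
    # transients
    roi_baseline_contrast: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")
        if not 0.0 < self.adaptation_factor <= 1.0:
            raise ValueError("adaptation_factor must be in (0, 1]")
        if self.transient_rise_tau <= 0 or self.transient_decay_tau <= 0:
            raise ValueError("transient time constants must be positive")
        if any(a < 0 for a in self.amplitude_schedule.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.n_baseline_frames < 1:
            raise ValueError("need at least one baseline frame")
        self.roi_spec.validate((self.frame_height, self.frame_width))

    @property
    def n_stimulus_frames(self) -> int:
        return max(2, int(round(self.stimulus_duration * self.frame_rate)))

    @property
    def n_frames(self) -> int:
        return self.n_baseline_frames + self.n_stimulus_frames + self.n_post_frames

    @property
    def onset_frame(self) -> int:
        return self.n_baseline_frames

    @property
    def offset_frame(self) -> int:
        return self.onset_frame + self.n_stimulus_frames - 1


@dataclass
class SyntheticTrial:
    movie: TrialMovie
    truth: dict

    @property
    def true_amplitude(self) -> float:
        return self.truth["true_amplitude"]

    @property
    def true_shifts(self) -> np.ndarray:
        return self.truth["true_shifts"]


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials transient, zero for t<0, max 1 (continuous time).

    Peak time is ``rise_tau * log(1 + decay_tau/rise_tau)``.
    """
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("time constants must be positive")
    t = np.asarray(t, dtype=np.float64)
    raw = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise_tau)) * np.exp(-np.maximum(t, 0) / decay_tau), 0.0)
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return raw / peak


def kernel_frame_values(params: ImagingSimParams) -> np.ndarray:
    """Per-frame kernel values, rescaled so the two-highest-consecutive-frame
    mean inside the stimulus window is exactly 1.

    This calibration makes the true amplitude the exact noise-free value of
    the pipeline's peak statistic.
    """
    idx = np.arange(params.n_frames)
    t = (idx - params.onset_frame) / params.frame_rate
    k = transient_kernel(t, params.transient_rise_tau, params.transient_decay_tau)
    win = k[params.onset_frame : params.offset_frame + 1]
    pair_peak = np.max((win[:-1] + win[1:]) / 2.0)
    if pair_peak <= 0:
        raise ValueError("degenerate kernel: no positive values in stimulus window")
    return k / pair_peak


def kernel_integral(params: ImagingSimParams) -> float:
    """Closed-form time integral (ΔF/F₀·s per unit amplitude) of the
    calibrated kernel from onset to +infinity."""
    tr, td = params.transient_rise_tau, params.transient_decay_tau
    t_peak = tr * np.log1p(td / tr)
    peak = (1.0 - np.exp(-t_peak / tr)) * np.exp(-t_peak / td)
    # ∫ (1-e^{-t/tr}) e^{-t/td} dt = td - 1/(1/tr + 1/td)
    integral = td - 1.0 / (1.0 / tr + 1.0 / td)
    # same discrete-grid rescaling as kernel_frame_values
    idx = np.arange(params.n_frames)
    t = (idx - params.onset_frame) / params.frame_rate
    k = transient_kernel(t, tr, td)
    win = k[params.onset_frame : params.offset_frame + 1]
    pair_peak = np.max((win[:-1] + win[1:]) / 2.0)
    return integral / peak / pair_peak


def translate_frame(frame: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Translate image content by (+dx cols, +dy rows) with periodic boundaries."""
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("shift must be finite")
    if dx == 0.0 and dy == 0.0:
        return frame.copy()
    f = np.fft.fft2(frame)
    h, w = frame.shape
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    phase = np.exp(-2j * np.pi * (ky * dy + kx * dx))
    return np.real(np.fft.ifft2(f * phase))


def _trial_amplitude(
    params: ImagingSimParams, stimulus: str, trial_index: int, rng: np.random.Generator
) -> float:
    try:
        base = params.amplitude_schedule[stimulus]
    except KeyError:
        raise KeyError(f"stimulus {stimulus!r} not in amplitude schedule") from None
    mult = 1.0
    if params.trial_cv > 0:
        sigma2 = np.log1p(params.trial_cv**2)
        mult = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2))
    return base * params.adaptation_factor**trial_index * mult


def _texture(params: ImagingSimParams) -> np.ndarray:
    """Static anatomical contrast, shared by every trial of a session."""
    if params.texture_contrast <= 0:
        return np.zeros((params.frame_height, params.frame_width))
    rng = substream(params.seed, "texture")
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal((params.frame_height, params.frame_width))
    smooth = gaussian_filter(raw, sigma=3.0, mode="wrap")
    smooth /= np.abs(smooth).max()
    return params.texture_contrast * smooth


def make_imaging_trial(
    params: ImagingSimParams,
    stimulus: str,
    trial_index: int = 0,
    seed: int | None = None,
    *,
    drift_start: tuple[float, float] = (0.0, 0.0),
    _texture_map: np.ndarray | None = None,
) -> SyntheticTrial:
    """Generate one trial movie plus its ground-truth manifest.

    ``drift_start`` carries the cumulative drift over from earlier trials in
    a session.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    seed = params.seed if seed is None else seed
    shape = (params.frame_height, params.frame_width)
    params.roi_spec.validate(shape)

    amp_rng = substream(seed, "amplitude", stimulus, trial_index)
    drift_rng = substream(seed, "drift", stimulus, trial_index)
    noise_rng = substream(seed, "noise", stimulus, trial_index)

    amplitude = _trial_amplitude(params, stimulus, trial_index, amp_rng)
    k = kernel_frame_values(params)
    w = params.roi_spec.weight_map(shape)
    texture = _texture(params) if _texture_map is None else _texture_map

    # cumulative drift + per-frame jitter
    n = params.n_frames
    steps = np.tile(np.asarray(params.drift_per_frame, float), (n, 1))
    if params.drift_jitter_sd > 0:
        steps += drift_rng.normal(0.0, params.drift_jitter_sd, size=(n, 2))
    shifts = np.asarray(drift_start, float) + np.cumsum(steps, axis=0)
    if params.drift_per_frame == (0.0, 0.0) and params.drift_jitter_sd == 0 and drift_start == (0.0, 0.0):
        shifts = np.zeros((n, 2))

    base = params.baseline_intensity
    frames = np.empty((n,) + shape)
    for i in range(n):
        clean = base * (1.0 + texture + params.roi_baseline_contrast * w) * (1.0 + amplitude * k[i] * w)
        moved = translate_frame(clean, shifts[i, 0], shifts[i, 1])
        if params.photon_gain > 0:
            moved = noise_rng.poisson(np.maximum(moved, 0.0) / params.photon_gain) * params.photon_gain
            moved = moved.astype(np.float64)
        if params.read_noise_sd > 0:
            moved = moved + noise_rng.normal(0.0, params.read_noise_sd, size=shape)
        frames[i] = moved

    movie = TrialMovie(
        frames=frames,
        frame_rate=params.frame_rate,
        onset_frame=params.onset_frame,
        offset_frame=params.offset_frame,
        stimulus=stimulus,
        trial_index=trial_index,
    )
    truth = {
        "true_amplitude": amplitude,
        "true_shifts": shifts,
        "roi_mask": params.roi_spec.true_mask(shape),
        "stimulus_onset_frame": params.onset_frame,
        "stimulus_offset_frame": params.offset_frame,
        "kernel": k,
    }
    return SyntheticTrial(movie=movie, truth=truth)


def make_imaging_session(
    params: ImagingSimParams,
    stimulus_order: Sequence[str],
    seed: int | None = None,
) -> list[SyntheticTrial]:
    """Generate an ordered session of trials sharing one continuous drift
    process and one anatomical texture.

    ``stimulus_order`` is the full trial sequence (labels may repeat);
    per-stimulus trial indices count previous occurrences of the same label,
    which is what the adaptation factor decays with.
    """
    if not stimulus_order:
        raise ValueError("stimulus_order must be non-empty")
    seed = params.seed if seed is None else seed
    texture = _texture(params)
    counts: dict[str, int] = {}
    drift = (0.0, 0.0)
    out: list[SyntheticTrial] = []
    for stim in stimulus_order:
        idx = counts.get(stim, 0)
        counts[stim] = idx + 1
        trial = make_imaging_trial(
            params, stim, idx, seed=seed, drift_start=drift, _texture_map=texture
        )
        drift = tuple(trial.truth["true_shifts"][-1])
        out.append(trial)
    return out


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

STATES = ("fed", "starved_1d", "starved_2d")


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass
class BehaviorSimParams:
    """State-dependent dose-response generator for two-trial PER tests.

    Per fly × dose, P(PER on one trial) is
    ``logistic(baseline_logit + g_app(state)·A(dose) − g_av(state)·B(dose)
    + fly_offset)`` with ``fly_offset ~ Normal(0, fly_sigma)``; the two
    trials are conditionally independent given the fly offset. Appetitive
    gain rises and aversive gain falls with starvation, which produces the
    fed-aversive / starved-appetitive crossover.
    """

    n_groups: int = 4
    group_size: int = 17
    states: tuple[str, ...] = STATES
    doses: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0)
    appetitive_drive: Callable[[float], float] = lambda d: 6.0 * d / (d + 2.0)
    aversive_drive: Callable[[float], float] = lambda d: 3.0 * d / (d + 1.0)
    hunger_gain_appetitive: Mapping[str, float] = field(
        default_factory=lambda: {"fed": 1.0, "starved_1d": 2.5, "starved_2d": 4.0}
    )
    hunger_gain_aversive: Mapping[str, float] = field(
        default_factory=lambda: {"fed": 4.0, "starved_1d": 1.5, "starved_2d": 0.5}
    )
    baseline_logit: float = float(np.log(0.05 / 0.95))
    fly_sigma: float = 0.5
    sucrose_check_p: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 15 <= self.group_size <= 20:
            raise ValueError("group_size must be in [15, 20] to mirror the assay protocol")
        for s in self.states:
            if s not in self.hunger_gain_appetitive or s not in self.hunger_gain_aversive:
                raise ValueError(f"missing hunger gain for state {s!r}")

    def cell_logit(self, state: str, dose: float) -> float:
        if state not in self.states:
            raise ValueError(f"unknown state {state!r}")
        return (
            self.baseline_logit
            + self.hunger_gain_appetitive[state] * self.appetitive_drive(dose)
            - self.hunger_gain_aversive[state] * self.aversive_drive(dose)
        )

    def cell_probability(self, state: str, dose: float, fly_offset: float = 0.0) -> float:
        return float(_logistic(self.cell_logit(state, dose) + fly_offset))


def default_behavior_params(**overrides) -> BehaviorSimParams:
    return BehaviorSimParams(**overrides)


def null_behavior_params(**overrides) -> BehaviorSimParams:
    """Zero-effect generator: every cell shares the baseline response floor."""
    overrides.setdefault("hunger_gain_appetitive", {s: 0.0 for s in STATES})
    overrides.setdefault("hunger_gain_aversive", {s: 0.0 for s in STATES})
    return BehaviorSimParams(**overrides)


@dataclass
class PERDataset:
    """Two-trial PER outcomes in long form, one row per fly × tastant × dose.

    ``records`` columns: group_id, fly_id, state, tastant, dose, trial1,
    trial2, sucrose500_check. ``truth`` maps (group_id, fly_id, dose) to the
    generative per-trial P(PER).
    """

    records: pd.DataFrame
    truth: dict

    def __len__(self) -> int:
        return len(self.records)


def make_per_dataset(
    params: BehaviorSimParams,
    seed: int | None = None,
    tastant: str = "acetic_acid",
) -> PERDataset:
    """Simulate ``n_groups`` groups per state, each fly tested at every dose."""
    seed = params.seed if seed is None else seed
    rng = substream(seed, "per", tastant)
    rows = []
    truth: dict = {}
    for state in params.states:
        for g in range(params.n_groups):
            group_id = f"{state}_g{g}"
            for f in range(params.group_size):
                fly_id = f"{group_id}_f{f}"
                offset = rng.normal(0.0, params.fly_sigma) if params.fly_sigma > 0 else 0.0
                sucrose_ok = bool(rng.random() < params.sucrose_check_p)
                for dose in params.doses:
                    p = params.cell_probability(state, dose, offset)
                    t1, t2 = rng.random(2) < p
                    truth[(group_id, fly_id, dose)] = p
                    rows.append(
                        {
                            "group_id": group_id,
                            "fly_id": fly_id,
                            "state": state,
                            "tastant": tastant,
                            "dose": dose,
                            "trial1": bool(t1),
                            "trial2": bool(t2),
                            "sucrose500_check": sucrose_ok,
                        }
                    )
    return PERDataset(records=pd.DataFrame(rows), truth=truth)


def marginal_per_probability(
    params: BehaviorSimParams, state: str, dose: float, n_quad: int = 61
) -> float:
    """Marginal per-trial P(PER), integrating the fly offset by Gauss-Hermite."""
    if params.fly_sigma == 0:
        return params.cell_probability(state, dose)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    p = _logistic(params.cell_logit(state, dose) + params.fly_sigma * nodes)
    return float(np.sum(weights * p) / np.sum(weights))


def marginal_positive_test_probability(
    params: BehaviorSimParams, state: str, dose: float, n_quad: int = 61
) -> float:
    """Marginal P(positive two-trial test) = 1 − E[(1−p)²] over the fly effect."""
    if params.fly_sigma == 0:
        p = params.cell_probability(state, dose)
        return 1.0 - (1.0 - p) ** 2
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    p = _logistic(params.cell_logit(state, dose) + params.fly_sigma * nodes)
    return float(np.sum(weights * (1.0 - (1.0 - p) ** 2)) / np.sum(weights))


# ---------------------------------------------------------------------------
# Directional PER
# ---------------------------------------------------------------------------

DIRECTIONAL_OUTCOMES = ("toward", "away", "neither")


@dataclass
class DirectionalDataset:
    """Lateralized-PER trials: one row per full-PER trial with its outcome.

    ``trials`` columns: fly_id, side_stimulated ('L'/'R'), outcome
    ('toward'/'away'/'neither').
    """

    trials: pd.DataFrame
    truth: dict

    def __len__(self) -> int:
        return len(self.trials)


def make_directional_dataset(
    n_trials: int,
    p_toward: float,
    p_neither: float,
    seed: int = 0,
    n_flies: int = 9,
) -> DirectionalDataset:
    if p_toward < 0 or p_neither < 0 or p_toward + p_neither > 1 + 1e-12:
        raise ValueError("need p_toward + p_neither <= 1 with both non-negative")
    rng = substream(seed, "directional")
    p_away = max(0.0, 1.0 - p_toward - p_neither)
    outcomes = rng.choice(
        ["toward", "neither", "away"], size=n_trials, p=[p_toward, p_neither, p_away]
    )
    trials = pd.DataFrame(
        {
            "fly_id": [f"fly{(i % n_flies) + 1}" for i in range(n_trials)] if n_flies else [],
            "side_stimulated": ["L" if (i // 2) % 2 == 0 else "R" for i in range(n_trials)],
            "outcome": outcomes,
        }
    )
    truth = {"p_toward": p_toward, "p_neither": p_neither, "p_away": p_away}
    return DirectionalDataset(trials=trials, truth=truth)
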