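"""Movie, manifest and configuration I/O plus the end-to-end pipeline driver.

Conventions used throughout the package (stated once, here):

- pixel indices are 0-based ``(row, col)``;
- shifts are ``(dx, dy)`` in pixels with ``dx`` along columns and ``dy``
  along rows;
- frame indices are 0-based; stimulus windows are inclusive of both the
  onset and the offset frame.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("tastekit")

MANIFEST_SCHEMA_VERSION = 1


@dataclass
class TrialMovie:
    """A single-trial frame stack with stimulus timing metadata.

    ``frames`` has shape ``(n_frames, height, width)``; float internally,
    converted to 16-bit unsigned on disk.
    """

    frames: np.ndarray
    frame_rate: float
    onset_frame: int
    offset_frame: int
    stimulus: str = ""
    dose: float = 0.0
    trial_index: int = 0
    fly_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"movie must be 3-D (frames, rows, cols); got shape {self.frames.shape}")
        if not 0 <= self.onset_frame < self.offset_frame < self.n_frames:
            raise ValueError(
                f"invalid stimulus window [{self.onset_frame}, {self.offset_frame}] "
                f"for {self.n_frames}-frame movie"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def stimulus_frames(self) -> np.ndarray:
        """Frame indices during tastant presentation (onset..offset inclusive)."""
        return np.arange(self.onset_frame, self.offset_frame + 1)

    def with_frames(self, frames: np.ndarray) -> "TrialMovie":
        return dataclasses.replace(self, frames=frames)


def write_movie(movie: TrialMovie, path: str | Path) -> Path:
    """Write a movie as a multi-page 16-bit grayscale TIFF.

    Pixel values are clipped to [0, 65535] and rounded; the round-trip
    ``read_movie(write_movie(m))`` is bit-identical for integral data in
    range.
    """
    path = Path(path)
    data = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_movie(
    path: str | Path,
    frame_rate: float,
    onset_frame: int,
    offset_frame: int,
    **meta: Any,
) -> TrialMovie:
    """Read a multi-page grayscale TIFF into a :class:`TrialMovie`."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize format errors
        raise IOError(f"cannot read TIFF movie {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise IOError(f"{path}: expected a grayscale multi-page TIFF, got shape {data.shape}")
    return TrialMovie(
        frames=data.astype(np.float64),
        frame_rate=frame_rate,
        onset_frame=onset_frame,
        offset_frame=offset_frame,
        **meta,
    )


def write_roi_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean ROI mask as a single-page 8-bit TIFF (0/255)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)), photometric="minisblack")
    return path


def read_roi_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI mask not found: {path}")
    return np.asarray(tifffile.imread(path)) > 0


# ---------------------------------------------------------------------------
# Session manifest
# ---------------------------------------------------------------------------


@dataclass
class TrialEntry:
    """Per-trial record in a session manifest."""

    path: str
    stimulus: str
    dose: float
    trial_index: int
    onset_frame: int
    offset_frame: int
    n_frames: int
    fly_id: str = ""


@dataclass
class SessionManifest:
    """Describes the trials of one imaging session on disk."""

    frame_rate: float
    trials: list[TrialEntry]
    roi_path: str | None = None
    seed: int | None = None
    truth: dict[str, Any] | None = None
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "frame_rate": self.frame_rate,
            "roi_path": self.roi_path,
            "seed": self.seed,
            "trials": [dataclasses.asdict(t) for t in self.trials],
            "truth": self.truth,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SessionManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        version = raw.get("schema_version")
        if version != MANIFEST_SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported manifest schema version {version!r}")
        trials = [TrialEntry(**t) for t in raw["trials"]]
        return cls(
            frame_rate=raw["frame_rate"],
            trials=trials,
            roi_path=raw.get("roi_path"),
            seed=raw.get("seed"),
            truth=raw.get("truth"),
        )

    def validate_files(self, base_dir: str | Path) -> None:
        """Check that every trial TIFF exists and matches its declared frame count."""
        base = Path(base_dir)
        for entry in self.trials:
            p = base / entry.path
            if not p.exists():
                raise FileNotFoundError(f"trial movie missing: {p}")
            with tifffile.TiffFile(p) as tf:
                n = len(tf.pages)
            if n != entry.n_frames:
                raise ValueError(
                    f"trial {entry.stimulus}#{entry.trial_index} ({entry.path}): "
                    f"manifest declares {entry.n_frames} frames but file has {n}"
                )

    def load_trials(self, base_dir: str | Path) -> list[TrialMovie]:
        self.validate_files(base_dir)
        base = Path(base_dir)
        return [
            read_movie(
                base / e.path,
                frame_rate=self.frame_rate,
                onset_frame=e.onset_frame,
                offset_frame=e.offset_frame,
                stimulus=e.stimulus,
                dose=e.dose,
                trial_index=e.trial_index,
                fly_id=e.fly_id,
            )
            for e in self.trials
        ]


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Defaults mirror the source protocol: 20 baseline frames, θ=0.15,
    2 s stimulus windows, ≥3 trials per stimulus."""

    reference_policy: str = "first-baseline"
    upsample: int = 20
    n_baseline: int = 20
    theta: float = 0.15
    thetas: tuple[float, ...] = (0.10, 0.15, 0.20)
    integration_post_s: float = 2.0
    qc_policy: str = "compare_groups"
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["thetas"] = list(self.thetas)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    out_dir: str | Path,
) -> dict[str, Any]:
    """Register → quantify a session described by a manifest; write CSV tables
    and a machine-readable JSON summary.

    Returns the summary dict. Fails before registration if the ROI mask is
    missing.
    """
    from tastekit import quantify as qf
    from tastekit import registration as reg

    manifest_path = Path(manifest_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = SessionManifest.load(manifest_path)
    base_dir = manifest_path.parent

    if manifest.roi_path is None:
        raise FileNotFoundError("manifest has no ROI mask path; quantification needs an ROI")
    roi = read_roi_mask(base_dir / manifest.roi_path)

    trials = manifest.load_trials(base_dir)
    results = reg.register_session(trials, policy=config.reference_policy, upsample=config.upsample)

    shift_rows = []
    for t_idx, res in enumerate(results):
        for f_idx, s in enumerate(res.shifts):
            shift_rows.append(
                {"trial": t_idx, "frame": f_idx, "dx": s.dx, "dy": s.dy, "error": s.error_metric}
            )
    import pandas as pd

    pd.DataFrame(shift_rows).to_csv(out_dir / "shifts.csv", index=False)

    registered = [r.registered_movie for r in results]
    per_trial, per_fly = qf.quantify_session(
        registered,
        roi,
        n_baseline=config.n_baseline,
        thetas=config.thetas,
        integration_post_s=config.integration_post_s,
    )
    per_trial.to_csv(out_dir / "per_trial.csv", index=False)
    per_fly.to_csv(out_dir / "per_fly.csv", index=False)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_trials": len(trials),
        "n_flies": int(per_fly["fly_id"].nunique()) if len(per_fly) else 0,
        "tables": ["shifts.csv", "per_trial.csv", "per_fly.csv"],
        "config": config.to_dict(),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
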