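"""Raw-signal stage: autocalibration, non-wear and clipping detection, epoch grid.

The processing chain mirrors the first stage of standard wrist-accelerometer
pipelines: per-axis gain/offset correction estimated from still periods
(magnitude of a still accelerometer must equal 1 g), off-body detection from
sustained low variability, range-saturation flagging, and segmentation of the
stream into a fixed epoch grid (default 5 s) anchored at recording start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

# Epoch flag codes used throughout the package.
WEAR = 0
NONWEAR = 1
CLIPPED = 2
IMPUTED = 3  # assigned downstream, never by this module

FLAG_NAMES = {WEAR: "wear", NONWEAR: "nonwear", CLIPPED: "clipped", IMPUTED: "imputed"}

# Still-bout detection: 10 s windows with per-axis SD below 13 mg.
STILL_WINDOW_S = 10.0
STILL_SD_G = 0.013
# Non-wear: per 15-min block, judged on the surrounding 60-min window;
# >= 2 of 3 axes must have SD < 13 mg and range < 50 mg.
NONWEAR_BLOCK_S = 900
NONWEAR_WINDOW_S = 3600
NONWEAR_SD_G = 0.013
NONWEAR_RANGE_G = 0.050
# Clipping: epoch flagged when > 50% of samples on any axis sit at
# >= 0.99 of the device dynamic range.
CLIP_FRACTION_OF_RANGE = 0.99
CLIP_EPOCH_FRACTION = 0.5


@dataclass
class RawRecording:
    """One participant-wear of triaxial acceleration in gravitational units.

    ``samples`` is an (n, 3) float array in g; the device is assumed to report
    a symmetric dynamic range of ``dynamic_range_g`` (so representable values
    lie in [-range, +range]).
    """

    participant_id: str
    start_datetime: datetime
    sample_rate_hz: float
    samples: np.ndarray
    dynamic_range_g: float = 8.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s,x_g,y_g,z_g`` CSV plus a JSON sidecar."""
        path = Path(path)
        t = np.arange(self.n_samples) / self.sample_rate_hz
        df = pd.DataFrame(
            {"time_s": t, "x_g": self.samples[:, 0], "y_g": self.samples[:, 1],
             "z_g": self.samples[:, 2]}
        )
        df.to_csv(path, index=False, float_format="%.6f")
        sidecar = {
            "participant_id": self.participant_id,
            "start_datetime": self.start_datetime.isoformat(),
            "sample_rate_hz": self.sample_rate_hz,
            "dynamic_range_g": self.dynamic_range_g,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawRecording":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path)
        return cls(
            participant_id=str(meta["participant_id"]),
            start_datetime=datetime.fromisoformat(meta["start_datetime"]),
            sample_rate_hz=float(meta["sample_rate_hz"]),
            samples=df[["x_g", "y_g", "z_g"]].to_numpy(),
            dynamic_range_g=float(meta.get("dynamic_range_g", 8.0)),
        )


@dataclass
class CalibrationResult:
    """Per-axis gain/offset fit from still windows.

    ``calibration_error_g`` is the mean absolute deviation of still-window
    magnitudes from 1 g after applying the fitted correction (the quantity the
    >0.01 g participant-exclusion rule is evaluated on).
    """

    scale: np.ndarray
    offset: np.ndarray
    calibration_error_g: float
    n_still: int
    calibrated: bool = True
    message: str = ""

    def apply(self, samples: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * samples


@dataclass
class WearMask:
    """Per-epoch wear status on the fixed epoch grid; one flag per epoch."""

    epoch_flags: np.ndarray
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        self.epoch_flags = np.asarray(self.epoch_flags, dtype=np.int8)

    @property
    def n_epochs(self) -> int:
        return self.epoch_flags.size

    def labels(self) -> list[str]:
        return [FLAG_NAMES[int(f)] for f in self.epoch_flags]


# ---------------------------------------------------------------------------
# Autocalibration
# ---------------------------------------------------------------------------

def find_still_windows(rec: RawRecording, window_s: float = STILL_WINDOW_S,
                       sd_threshold_g: float = STILL_SD_G) -> np.ndarray:
    """Mean vectors of non-overlapping windows whose per-axis SD is below threshold.

    Returns an (m, 3) array of still-window mean accelerations in g.
    """
    w = int(round(window_s * rec.sample_rate_hz))
    if w < 2:
        raise ValueError("window too short for the sample rate")
    n_win = rec.n_samples // w
    if n_win == 0:
        return np.empty((0, 3))
    x = rec.samples[: n_win * w].reshape(n_win, w, 3)
    sd = x.std(axis=1)
    still = np.all(sd < sd_threshold_g, axis=1)
    return x[still].mean(axis=1)


def autocalibrate(
    rec: RawRecording,
    min_still_windows: int = 10,
    min_orientation_spread_g: float = 0.15,
    max_iter: int = 100,
    tol_g: float = 1e-6,
) -> tuple[RawRecording, CalibrationResult]:
    """Estimate per-axis gain and offset so still-window magnitudes equal 1 g.

    Iteratively reweighted least squares on the still-window mean vectors:
    each iteration projects the corrected means onto the unit sphere and
    regresses, per axis, the projected coordinate on the raw coordinate.
    Iteration stops when the mean absolute magnitude error improves by less
    than ``tol_g`` or after ``max_iter`` rounds.

    The fit is declared unidentifiable (and the recording passed through
    uncorrected) when fewer than ``min_still_windows`` still windows exist or
    when the still orientations span less than ``min_orientation_spread_g``
    on at least two axes — a single resting orientation cannot separate gain
    from offset.
    """
    means = find_still_windows(rec)
    n_still = means.shape[0]

    def error_of(scale: np.ndarray, offset: np.ndarray) -> float:
        if n_still == 0:
            return np.nan
        corrected = offset + scale * means
        return float(np.abs(np.linalg.norm(corrected, axis=1) - 1.0).mean())

    identity = (np.ones(3), np.zeros(3))
    if n_still < min_still_windows:
        res = CalibrationResult(*identity, error_of(*identity), n_still,
                                calibrated=False, message="too few still windows")
        return rec, res
    spread = means.max(axis=0) - means.min(axis=0)
    if np.sum(spread >= min_orientation_spread_g) < 2:
        res = CalibrationResult(*identity, error_of(*identity), n_still,
                                calibrated=False,
                                message="insufficient orientation diversity")
        return rec, res

    scale = np.ones(3)
    offset = np.zeros(3)
    prev_err = error_of(scale, offset)
    for _ in range(max_iter):
        corrected = offset + scale * means
        norms = np.linalg.norm(corrected, axis=1)
        closest = corrected / norms[:, None]
        # robust weights: down-weight windows far from the sphere
        w = np.minimum(1.0 / np.maximum(np.abs(norms - 1.0), 1e-6), 100.0)
        new_scale = np.empty(3)
        new_offset = np.empty(3)
        for a in range(3):
            A = np.column_stack([np.ones(n_still), means[:, a]])
            Aw = A * w[:, None]
            beta, *_ = np.linalg.lstsq(Aw, closest[:, a] * w, rcond=None)
            new_offset[a], new_scale[a] = beta
        if np.any(new_scale <= 0):
            break
        scale, offset = new_scale, new_offset
        err = error_of(scale, offset)
        if prev_err - err < tol_g:
            prev_err = min(err, prev_err)
            break
        prev_err = err

    result = CalibrationResult(scale, offset, error_of(scale, offset), n_still)
    corrected_rec = replace(rec, samples=result.apply(rec.samples))
    return corrected_rec, result


# ---------------------------------------------------------------------------
# Non-wear and clipping
# ---------------------------------------------------------------------------

def detect_nonwear(rec: RawRecording, epoch_s: float = 5.0) -> WearMask:
    """Flag 15-min blocks as non-wear from the surrounding 60-min window.

    A block is non-wear when, for at least 2 of 3 axes, the window SD is
    below 13 mg and the window range below 50 mg. Block labels broadcast to
    the epoch grid. Recordings shorter than one window are evaluated on the
    available span.
    """
    n_epochs = n_whole_epochs(rec, epoch_s)
    flags = np.full(n_epochs, WEAR, dtype=np.int8)
    rate = rec.sample_rate_hz
    epochs_per_block = int(round(NONWEAR_BLOCK_S / epoch_s))
    n_blocks = int(np.ceil(n_epochs / epochs_per_block))
    half_win = NONWEAR_WINDOW_S / 2.0
    for b in range(n_blocks):
        centre_s = (b + 0.5) * NONWEAR_BLOCK_S
        lo = max(0, int(round((centre_s - half_win) * rate)))
        hi = min(rec.n_samples, int(round((centre_s + half_win) * rate)))
        win = rec.samples[lo:hi]
        if win.shape[0] < 2:
            continue
        sd = win.std(axis=0)
        rng = win.max(axis=0) - win.min(axis=0)
        quiet_axes = np.sum((sd < NONWEAR_SD_G) & (rng < NONWEAR_RANGE_G))
        if quiet_axes >= 2:
            e0 = b * epochs_per_block
            flags[e0: e0 + epochs_per_block] = NONWEAR
    return WearMask(flags, epoch_s)


def detect_clipping(rec: RawRecording, mask: WearMask) -> WearMask:
    """Mark epochs where any axis saturates the device range; overrides wear.

    An epoch is clipped when strictly more than half of its samples on some
    axis satisfy |a| >= 0.99 * dynamic_range_g.
    """
    bounds = epoch_sample_bounds(rec, mask.epoch_s)
    thresh = CLIP_FRACTION_OF_RANGE * rec.dynamic_range_g
    near_limit = np.abs(rec.samples) >= thresh  # (n, 3) boolean
    cum = np.vstack([np.zeros(3, dtype=np.int64),
                     np.cumsum(near_limit, axis=0)])
    flags = mask.epoch_flags.copy()
    for k in range(mask.n_epochs):
        lo, hi = bounds[k]
        counts = cum[hi] - cum[lo]
        if np.any(counts > CLIP_EPOCH_FRACTION * (hi - lo)):
            flags[k] = CLIPPED
    return WearMask(flags, mask.epoch_s)


def build_wear_mask(rec: RawRecording, epoch_s: float = 5.0) -> WearMask:
    """Non-wear detection followed by clipping override."""
    return detect_clipping(rec, detect_nonwear(rec, epoch_s))


# ---------------------------------------------------------------------------
# Epoch grid
# ---------------------------------------------------------------------------

def n_whole_epochs(rec: RawRecording, epoch_s: float = 5.0) -> int:
    if 86400 % epoch_s != 0:
        raise ValueError("epoch_s must divide 86400")
    return int(rec.duration_s // epoch_s)


def epoch_sample_bounds(rec: RawRecording, epoch_s: float = 5.0) -> np.ndarray:
    """Half-open sample-index windows [k*epoch_s, (k+1)*epoch_s) per epoch.

    Boundaries are computed in time so non-integer samples-per-epoch rates
    are handled; the trailing partial epoch is discarded.
    """
    n = n_whole_epochs(rec, epoch_s)
    edges_t = np.arange(n + 1) * epoch_s
    idx = np.ceil(edges_t * rec.sample_rate_hz - 1e-9).astype(int)
    idx = np.minimum(idx, rec.n_samples)
    return np.column_stack([idx[:-1], idx[1:]])


def segment_epochs(rec: RawRecording, epoch_s: float = 5.0) -> np.ndarray:
    """Alias for :func:`epoch_sample_bounds` (the epoch index map)."""
    return epoch_sample_bounds(rec, epoch_s)
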