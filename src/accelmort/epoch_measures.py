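"""The four epoch summary measures: ENMO, MAD, MIMS, Counts.

ENMO and MAD are simple vector-magnitude statistics of the calibrated signal
within each epoch. MIMS and Counts are filter chains applied to the whole
stream (resampling, band-pass filtering, rectification, integration or
quantised summation) whose per-epoch values are obtained by slicing the
processed stream on the epoch grid — never by filtering epoch-by-epoch, which
would corrupt the band-pass edges.

All fixed constants of the two filter chains live in ``MIMS_CONSTANTS`` and
``COUNTS_CONSTANTS`` and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signal_preprocess import (
    RawRecording,
    WearMask,
    epoch_sample_bounds,
    FLAG_NAMES,
)

MEASURES = ("enmo", "mad", "mims", "counts")

MIMS_CONSTANTS = {
    "resample_hz": 100.0,
    "band_hz": (0.2, 5.0),
    "filter_order": 4,
    "saturation_fraction": 0.95,   # of dynamic range; triggers extrapolation
    "extrapolate_cap_fraction": 1.5,
    "truncate_below": 1e-4,        # per-axis epoch integral floor
}

COUNTS_CONSTANTS = {
    "resample_hz": 30.0,
    "band_hz": (0.29, 1.66),
    "filter_order": 4,
    "decimate_to_hz": 10.0,
    "clip_g": 2.13,
    "deadband_g": 0.068,
    "quantisation_g": 1.0 / 128.0,
}


@dataclass
class EpochSeries:
    """Per-epoch values of the four measures plus validity flags on a 5 s grid."""

    participant_id: str
    start_datetime: datetime
    epoch_s: float
    values: dict[str, np.ndarray]       # measure -> (n_epochs,) array
    flags: np.ndarray                   # int8 codes from signal_preprocess
    has_value: np.ndarray | None = None  # set by imputation; None = flags==WEAR

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=np.int8)
        n = self.flags.size
        for m, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.size != n:
                raise ValueError(f"measure {m!r} length {v.size} != {n} flags")
            self.values[m] = v

    @property
    def n_epochs(self) -> int:
        return self.flags.size

    @property
    def epoch_start_times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_datetime, periods=self.n_epochs,
                             freq=timedelta(seconds=self.epoch_s))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"epoch_start_iso": self.epoch_start_times,
                           "flag": [FLAG_NAMES[int(f)] for f in self.flags]})
        for m in MEASURES:
            col = {"enmo": "enmo_mg", "mad": "mad_mg"}.get(m, m)
            df[col] = self.values[m]
        return df


# ---------------------------------------------------------------------------
# ENMO and MAD
# ---------------------------------------------------------------------------

def enmo(epoch_samples: np.ndarray) -> float:
    """Epoch mean of (vector magnitude − 1 g), negatives truncated to 0; mg."""
    if len(epoch_samples) == 0:
        raise ValueError("empty epoch")
    r = np.linalg.norm(np.asarray(epoch_samples, dtype=float), axis=1)
    return float(np.maximum(r - 1.0, 0.0).mean() * 1000.0)


def mad(epoch_samples: np.ndarray) -> float:
    """Epoch mean absolute deviation of the vector magnitude from its mean; mg."""
    if len(epoch_samples) == 0:
        raise ValueError("empty epoch")
    r = np.linalg.norm(np.asarray(epoch_samples, dtype=float), axis=1)
    return float(np.abs(r - r.mean()).mean() * 1000.0)


def _per_epoch_reduce(values: np.ndarray, bounds: np.ndarray, fn) -> np.ndarray:
    return np.array([fn(values[lo:hi]) for lo, hi in bounds])


def enmo_series(rec: RawRecording, epoch_s: float = 5.0) -> np.ndarray:
    bounds = epoch_sample_bounds(rec, epoch_s)
    r = np.linalg.norm(rec.samples, axis=1)
    pos = np.maximum(r - 1.0, 0.0)
    cum = np.concatenate([[0.0], np.cumsum(pos)])
    counts = bounds[:, 1] - bounds[:, 0]
    return (cum[bounds[:, 1]] - cum[bounds[:, 0]]) / counts * 1000.0


def mad_series(rec: RawRecording, epoch_s: float = 5.0) -> np.ndarray:
    bounds = epoch_sample_bounds(rec, epoch_s)
    r = np.linalg.norm(rec.samples, axis=1)
    return _per_epoch_reduce(r, bounds, lambda x: np.abs(x - x.mean()).mean()) * 1000.0


# ---------------------------------------------------------------------------
# MIMS
# ---------------------------------------------------------------------------

def _resample_linear(samples: np.ndarray, rate_in: float, rate_out: float,
                     duration_s: float) -> np.ndarray:
    """Linear interpolation of an (n, 3) stream onto a uniform grid."""
    t_in = np.arange(samples.shape[0]) / rate_in
    n_out = int(round(duration_s * rate_out))
    t_out = np.arange(n_out) / rate_out
    out = np.empty((n_out, samples.shape[1]))
    for a in range(samples.shape[1]):
        out[:, a] = np.interp(t_out, t_in, samples[:, a])
    return out


def _extrapolate_saturated(x: np.ndarray, rate_hz: float, dynamic_range_g: float,
                           sat_fraction: float, cap_fraction: float) -> np.ndarray:
    """Replace range-saturated runs on one axis by cubic-spline continuation.

    Saturated samples (|a| >= sat_fraction * range) are re-estimated from a
    spline fitted through the surrounding non-saturated samples and capped at
    cap_fraction * range in magnitude.
    """
    thresh = sat_fraction * dynamic_range_g
    saturated = np.abs(x) >= thresh
    if not saturated.any():
        return x
    good = ~saturated
    if good.sum() < 4:  # nothing to anchor a spline on
        return np.clip(x, -cap_fraction * dynamic_range_g,
                       cap_fraction * dynamic_range_g)
    t = np.arange(x.size) / rate_hz
    spline = CubicSpline(t[good], x[good], extrapolate=True)
    y = x.copy()
    y[saturated] = spline(t[saturated])
    cap = cap_fraction * dynamic_range_g
    return np.clip(y, -cap, cap)


def mims_series(rec: RawRecording, epoch_s: float = 5.0,
                constants: dict | None = None) -> np.ndarray:
    """Monitor-independent movement summary per epoch (sum over axes).

    Chain per axis: resample to 100 Hz → spline-extrapolate saturated runs →
    zero-phase band-pass 0.2–5 Hz (Butterworth order 4, forward-backward) →
    rectify → trapezoidal integral per epoch → truncate integrals below 1e-4
    to zero; the epoch value is the sum of the three axis integrals.
    """
    c = {**MIMS_CONSTANTS, **(constants or {})}
    if rec.sample_rate_hz < 2 * c["band_hz"][1]:
        raise ValueError("sample rate too low to represent the upper band edge")
    n_epochs = int(rec.duration_s // epoch_s)
    if n_epochs == 0:
        return np.empty(0)
    rate = c["resample_hz"]
    x = _resample_linear(rec.samples, rec.sample_rate_hz, rate, rec.duration_s)
    b, a = sps.butter(c["filter_order"],
                      [f / (rate / 2.0) for f in c["band_hz"]], btype="bandpass")
    per_axis = np.empty((n_epochs, 3))
    spe = int(round(epoch_s * rate))
    for ax in range(3):
        y = _extrapolate_saturated(x[:, ax], rate, rec.dynamic_range_g,
                                   c["saturation_fraction"],
                                   c["extrapolate_cap_fraction"])
        y = sps.filtfilt(b, a, y)
        y = np.abs(y)
        # trapezoid integral per epoch via the cumulative integral
        cum = np.concatenate([[0.0], np.cumsum((y[1:] + y[:-1]) / 2.0)]) / rate
        edges = np.arange(n_epochs + 1) * spe
        edges = np.minimum(edges, y.size - 1)
        integ = cum[edges[1:]] - cum[edges[:-1]]
        integ[integ < c["truncate_below"]] = 0.0
        per_axis[:, ax] = integ
    return per_axis.sum(axis=1)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def counts_series(rec: RawRecording, epoch_s: float = 5.0,
                  constants: dict | None = None,
                  axis_combination: str = "vector_norm") -> np.ndarray:
    """Accelerometer counts per epoch.

    Chain per axis: resample to 30 Hz → band-pass IIR (packaged coefficients)
    → decimate to 10 Hz → clip |a| at 2.13 g → rectify → dead-band below
    0.068 g → quantise to 1/128 g → sum within the epoch. Epoch value combines
    the three per-axis sums by Euclidean norm (default) or plain sum.
    """
    c = {**COUNTS_CONSTANTS, **(constants or {})}
    if rec.sample_rate_hz < 2 * c["band_hz"][1]:
        raise ValueError("sample rate too low to represent the upper band edge")
    if axis_combination not in ("vector_norm", "sum_axes"):
        raise ValueError("axis_combination must be vector_norm or sum_axes")
    n_epochs = int(rec.duration_s // epoch_s)
    if n_epochs == 0:
        return np.empty(0)
    rate = c["resample_hz"]
    dec = int(round(rate / c["decimate_to_hz"]))
    x = _resample_linear(rec.samples, rec.sample_rate_hz, rate, rec.duration_s)
    if "filter_ba" in c:
        b, a = c["filter_ba"]
    else:
        b, a = sps.butter(c["filter_order"],
                          [f / (rate / 2.0) for f in c["band_hz"]],
                          btype="bandpass")
    spe = int(round(epoch_s * c["decimate_to_hz"]))
    axis_sums = np.zeros((n_epochs, 3))
    zi = sps.lfilter_zi(b, a)
    for ax in range(3):
        # steady-state initial conditions: a constant input yields the DC
        # response immediately, so gravity produces no startup transient
        y, _ = sps.lfilter(b, a, x[:, ax], zi=zi * x[0, ax])
        y = y[::dec]
        y = np.clip(y, -c["clip_g"], c["clip_g"])
        y = np.abs(y)
        y[y < c["deadband_g"]] = 0.0
        y = np.floor(y / c["quantisation_g"]) * c["quantisation_g"]
        usable = (y.size // spe) * spe
        sums = y[:usable].reshape(-1, spe).sum(axis=1)
        axis_sums[: sums.size, ax] = sums[:n_epochs]
    if axis_combination == "vector_norm":
        return np.linalg.norm(axis_sums, axis=1)
    return axis_sums.sum(axis=1)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def compute_epoch_series(rec: RawRecording, mask: WearMask,
                         epoch_s: float = 5.0) -> EpochSeries:
    """All four measures on the epoch grid of a calibrated recording."""
    values = {
        "enmo": enmo_series(rec, epoch_s),
        "mad": mad_series(rec, epoch_s),
        "mims": mims_series(rec, epoch_s),
        "counts": counts_series(rec, epoch_s),
    }
    n = min(v.size for v in values.values())
    flags = mask.epoch_flags[:n]
    values = {m: v[:n] for m, v in values.items()}
    return EpochSeries(rec.participant_id, rec.start_datetime, epoch_s,
                       values, flags)
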