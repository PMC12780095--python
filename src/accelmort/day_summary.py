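"""Day-level exposures: imputation, valid days, AvAcc and the intensity gradient.

The two physical-activity exposures are computed per measure per valid
calendar day (midnight to midnight in the recording's local clock):

* **AvAcc** — the arithmetic mean of the day's epoch values, a proxy for
  total activity volume in the measure's own units.
* **IG (intensity gradient)** — the slope of ln(time accumulated) on
  ln(intensity-bin midpoint) across intensity bins, describing how activity
  is distributed across intensities (more negative = concentrated at low
  intensities).

Invalid epochs (non-wear / clipped) are imputed from the mean of the same
time-of-day slot on the remaining days; imputed epochs do not count toward
wear time, so imputation cannot manufacture valid days. Participants are
excluded for calibration error > 0.01 g, fewer than 3 valid days (> 16 h
wear), missing 15-min coverage of the 24-h cycle, an ENMO AvAcc above
100 mg, or falling outside the [0.5th, 99.5th] percentile of ENMO AvAcc or
ENMO IG; the trim is computed on ENMO only and the surviving participant set
is shared by all four measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .signal_preprocess import WEAR, IMPUTED, CalibrationResult
from .epoch_measures import EpochSeries, MEASURES

EXCLUSION_REASONS = ("calibration", "valid_days", "coverage", "avacc_gt_100",
                     "percentile_trim", "none")

VALID_DAY_WEAR_HOURS = 16.0       # strict: a day needs wear_hours > 16
CALIBRATION_ERROR_MAX_G = 0.01    # strict: excluded when error > 0.01 g
AVACC_CEILING_MG = 100.0          # strict: excluded when ENMO AvAcc > 100 mg
PERCENTILE_TRIM = (0.5, 99.5)
COVERAGE_PERIOD_S = 900           # 15-min periods of the 24-h cycle

DEFAULT_ENMO_BIN_WIDTH_MG = 25.0
DEFAULT_ENMO_BIN_CEILING_MG = 4000.0


@dataclass
class BinScheme:
    """Ascending intensity bins for the IG regression, in the measure's units."""

    measure: str
    edges: np.ndarray
    midpoints: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        if self.edges.size < 6:
            raise ValueError("need at least 5 bins")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        inside = (self.midpoints > self.edges[:-1]) & (self.midpoints < self.edges[1:])
        if not inside.all():
            raise ValueError("midpoints must lie inside their bins")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"measure": self.measure,
                             "edge_low": self.edges[:-1],
                             "edge_high": self.edges[1:],
                             "midpoint": self.midpoints})


def reference_enmo_bins(width_mg: float = DEFAULT_ENMO_BIN_WIDTH_MG,
                        ceiling_mg: float = DEFAULT_ENMO_BIN_CEILING_MG) -> BinScheme:
    """The reference scheme: equal-width ENMO bins from 0 to the ceiling."""
    edges = np.arange(0.0, ceiling_mg + width_mg / 2, width_mg)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return BinScheme("enmo", edges, mids)


@dataclass
class DaySummary:
    date: date
    wear_hours: float
    coverage_ok: bool
    valid: bool
    avacc: dict[str, float] = field(default_factory=dict)
    ig_slope: dict[str, float] = field(default_factory=dict)
    ig_intercept: dict[str, float] = field(default_factory=dict)
    ig_r2: dict[str, float] = field(default_factory=dict)


@dataclass
class ParticipantSummary:
    participant_id: str
    n_valid_days: int
    avacc: dict[str, float]
    ig: dict[str, float]
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with exclusion_reason")


# ---------------------------------------------------------------------------
# Slot bookkeeping
# ---------------------------------------------------------------------------

def _slot_day_layout(series: EpochSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each epoch to (day index, time-of-day slot index, calendar date).

    Pure arithmetic on the epoch grid: the grid is anchored at the recording
    start, so slot k's time of day advances by epoch_s per epoch from the
    start's seconds-of-midnight offset.
    """
    start = series.start_datetime
    slots_per_day = int(round(86400 / series.epoch_s))
    start_secs = (start.hour * 3600 + start.minute * 60 + start.second
                  + start.microsecond / 1e6)
    slot0 = int(start_secs // series.epoch_s)
    abs_slot = slot0 + np.arange(series.n_epochs, dtype=np.int64)
    slot = abs_slot % slots_per_day
    day = abs_slot // slots_per_day
    base = start.date()
    day_dates = np.array([base + timedelta(days=int(d))
                          for d in range(int(day.max()) + 1)], dtype=object)
    return day, slot, day_dates[day]


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_invalid(series: EpochSeries) -> EpochSeries:
    """Fill invalid epochs with the same-slot mean across the other days.

    Epochs flagged non-wear or clipped receive, per measure, the mean of the
    valid values at the identical time-of-day slot on all other recorded
    days. Slots with no valid value on any day stay invalid (``has_value``
    False) and count against 15-min coverage. On a single-day recording no
    imputation is possible.
    """
    day, slot, _ = _slot_day_layout(series)
    valid = series.flags == WEAR
    n_days = int(day.max()) + 1
    slots_per_day = int(round(86400 / series.epoch_s))

    new_values = {m: v.copy() for m, v in series.values.items()}
    new_flags = series.flags.copy()
    has_value = valid.copy()

    invalid_idx = np.flatnonzero(~valid)
    if invalid_idx.size and n_days >= 2:
        counts = np.zeros(slots_per_day)
        np.add.at(counts, slot[valid], 1)
        fillable = invalid_idx[counts[slot[invalid_idx]] > 0]
        for m, v in series.values.items():
            sums = np.zeros(slots_per_day)
            np.add.at(sums, slot[valid], v[valid])
            new_values[m][fillable] = (sums[slot[fillable]]
                                       / counts[slot[fillable]])
        new_flags[fillable] = IMPUTED
        has_value[fillable] = True

    return EpochSeries(series.participant_id, series.start_datetime,
                       series.epoch_s, new_values, new_flags, has_value)


def coverage_by_period(series: EpochSeries) -> np.ndarray:
    """Boolean per 15-min period of the 24-h cycle: every slot in the period
    has a value (wear or imputed) on at least one day."""
    _, slot, _ = _slot_day_layout(series)
    has = series.has_value if series.has_value is not None else series.flags == WEAR
    slots_per_day = int(round(86400 / series.epoch_s))
    slot_covered = np.zeros(slots_per_day, dtype=bool)
    np.add.at(slot_covered, slot[has], True)
    per_period = int(round(COVERAGE_PERIOD_S / series.epoch_s))
    return slot_covered.reshape(-1, per_period).all(axis=1)


# ---------------------------------------------------------------------------
# Day summaries
# ---------------------------------------------------------------------------

def valid_day_flags(series: EpochSeries) -> list[DaySummary]:
    """Wear hours and validity per calendar day; wear counts original wear only."""
    day, _, dates = _slot_day_layout(series)
    out: list[DaySummary] = []
    for d in range(int(day.max()) + 1):
        in_day = day == d
        if not in_day.any():
            continue
        wear_epochs = int(np.sum((series.flags == WEAR) & in_day))
        wear_hours = wear_epochs * series.epoch_s / 3600.0
        out.append(DaySummary(date=dates[in_day][0], wear_hours=wear_hours,
                              coverage_ok=True,
                              valid=wear_hours > VALID_DAY_WEAR_HOURS))
    return out


def average_acceleration(day_values: np.ndarray, day_has_value: np.ndarray) -> float:
    """Mean of the day's epoch values over epochs holding a value."""
    if not day_has_value.any():
        return float("nan")
    return float(day_values[day_has_value].mean())


def intensity_gradient(day_values: np.ndarray, scheme: BinScheme,
                       epoch_s: float = 5.0,
                       min_nonempty_bins: int = 3) -> tuple[float, float, float]:
    """IG regression for one day: slope, intercept, R² of ln(minutes) on ln(midpoint).

    Time accumulated per intensity bin (in minutes) is regressed on the bin
    midpoints on log-log axes by ordinary least squares; bins with zero time
    are dropped (their log is undefined). Returns NaNs when fewer than
    ``min_nonempty_bins`` bins are occupied.
    """
    counts, _ = np.histogram(day_values, bins=scheme.edges)
    minutes = counts * epoch_s / 60.0
    occupied = minutes > 0
    if occupied.sum() < min_nonempty_bins:
        return float("nan"), float("nan"), float("nan")
    x = np.log(scheme.midpoints[occupied])
    y = np.log(minutes[occupied])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def summarise_days(series: EpochSeries, schemes: dict[str, BinScheme]) -> list[DaySummary]:
    """Validity plus per-measure AvAcc and IG for each calendar day."""
    day, _, _ = _slot_day_layout(series)
    has = series.has_value if series.has_value is not None else series.flags == WEAR
    days = valid_day_flags(series)
    for i, ds in enumerate(days):
        in_day = day == i
        if not ds.valid:
            continue
        for m in MEASURES:
            v = series.values[m][in_day]
            h = has[in_day]
            ds.avacc[m] = average_acceleration(v, h)
            if m in schemes:
                s, b, r2 = intensity_gradient(v[h], schemes[m], series.epoch_s)
                ds.ig_slope[m], ds.ig_intercept[m], ds.ig_r2[m] = s, b, r2
    return days


# ---------------------------------------------------------------------------
# Bin adjustment between measures
# ---------------------------------------------------------------------------

def fit_power_map(reference: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of the power model target = a * reference**b on
    log-log axes, using strictly positive pairs."""
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    pos = (reference > 0) & (target > 0)
    if pos.sum() < 10:
        raise ValueError("too few strictly positive pairs for the power fit")
    b, ln_a = np.polyfit(np.log(reference[pos]), np.log(target[pos]), 1)
    return float(np.exp(ln_a)), float(b)


def build_bins(measure: str, reference_scheme: BinScheme,
               reference_values: np.ndarray, target_values: np.ndarray) -> BinScheme:
    """Map the reference (ENMO) bin scheme into a target measure's units.

    Fits the monotone power model t = a·r^b on paired strictly positive
    epoch values and maps every edge and midpoint through it, producing
    "modelled" adjusted bins. A degenerate fit (b <= 0) falls back to
    quantile-matched edges.
    """
    if measure == reference_scheme.measure:
        return BinScheme(measure, reference_scheme.edges.copy(),
                         reference_scheme.midpoints.copy())
    try:
        a, b = fit_power_map(reference_values, target_values)
    except ValueError:
        a, b = np.nan, -1.0
    if not np.isfinite(b) or b <= 0:
        # quantile-matched fallback: map each reference edge through the
        # empirical quantile correspondence of the paired sample
        ref = np.asarray(reference_values, dtype=float)
        tgt = np.asarray(target_values, dtype=float)
        qs = np.interp(reference_scheme.edges, np.sort(ref),
                       np.sort(tgt))
        qs = np.maximum.accumulate(qs)
        qs += np.arange(qs.size) * 1e-9  # enforce strict increase
        mids = (qs[:-1] + qs[1:]) / 2.0
        scheme = BinScheme(measure, qs, mids)
        scheme.fallback = True  # type: ignore[attr-defined]
        return scheme
    edges = a * reference_scheme.edges ** b
    mids = a * reference_scheme.midpoints ** b
    return BinScheme(measure, edges, mids)


def build_all_schemes(reference_scheme: BinScheme,
                      paired_epochs: dict[str, np.ndarray]) -> dict[str, BinScheme]:
    """Adjusted bin schemes for every measure from a paired calibration sample."""
    ref = paired_epochs[reference_scheme.measure]
    return {m: build_bins(m, reference_scheme, ref, paired_epochs[m])
            for m in MEASURES}


# ---------------------------------------------------------------------------
# Participant summaries and exclusions
# ---------------------------------------------------------------------------

def summarise_participant(participant_id: str, days: list[DaySummary],
                          coverage_ok: bool = True,
                          min_valid_days: int = 3) -> ParticipantSummary:
    """Per-measure AvAcc and IG as the unweighted mean over valid days."""
    valid_days = [d for d in days if d.valid]
    n_valid = len(valid_days)
    avacc: dict[str, float] = {}
    ig: dict[str, float] = {}
    for m in MEASURES:
        av = [d.avacc[m] for d in valid_days if np.isfinite(d.avacc.get(m, np.nan))]
        avacc[m] = float(np.mean(av)) if av else float("nan")
        sl = [d.ig_slope[m] for d in valid_days
              if np.isfinite(d.ig_slope.get(m, np.nan))]
        ig[m] = float(np.mean(sl)) if sl else float("nan")
    excluded = False
    reason = "none"
    if n_valid < min_valid_days:
        excluded, reason = True, "valid_days"
    elif not coverage_ok:
        excluded, reason = True, "coverage"
    return ParticipantSummary(participant_id, n_valid, avacc, ig,
                              excluded, reason)


def apply_exclusions(summaries: list[ParticipantSummary],
                     calibs: dict[str, CalibrationResult] | None = None,
                     reference_measure: str = "enmo") -> list[ParticipantSummary]:
    """Apply the cohort exclusion cascade; the survivor set is shared by all
    four measures.

    Order: calibration error > 0.01 g; < 3 valid days; 15-min coverage;
    reference AvAcc > 100 mg; then the [0.5th, 99.5th] percentile trim on
    reference AvAcc and IG, computed on the set surviving the absolute rules.
    """
    out: list[ParticipantSummary] = []
    for s in summaries:
        reason = s.exclusion_reason
        cal = (calibs or {}).get(s.participant_id)
        if cal is not None and cal.calibration_error_g > CALIBRATION_ERROR_MAX_G:
            reason = "calibration"
        elif reason == "none" and s.avacc.get(reference_measure, np.nan) > AVACC_CEILING_MG:
            reason = "avacc_gt_100"
        out.append(ParticipantSummary(s.participant_id, s.n_valid_days,
                                      s.avacc, s.ig, reason != "none", reason))

    survivors = [s for s in out if not s.excluded]
    if not survivors:
        counts = pd.Series([s.exclusion_reason for s in out]).value_counts()
        raise RuntimeError(f"no participants survive exclusions: {counts.to_dict()}")

    av = np.array([s.avacc[reference_measure] for s in survivors])
    ig = np.array([s.ig[reference_measure] for s in survivors])
    lo_p, hi_p = PERCENTILE_TRIM
    av_lo, av_hi = np.percentile(av, [lo_p, hi_p])
    ig_lo, ig_hi = np.percentile(ig, [lo_p, hi_p])
    final: list[ParticipantSummary] = []
    for s in out:
        if not s.excluded:
            a, g = s.avacc[reference_measure], s.ig[reference_measure]
            if a < av_lo or a > av_hi or g < ig_lo or g > ig_hi:
                s = ParticipantSummary(s.participant_id, s.n_valid_days,
                                       s.avacc, s.ig, True, "percentile_trim")
        final.append(s)
    if not any(not s.excluded for s in final):
        raise RuntimeError("percentile trim removed every participant")
    return final


def summaries_to_frame(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"pid": s.participant_id, "n_valid_days": s.n_valid_days}
        for m in MEASURES:
            unit = "_mg" if m in ("enmo", "mad") else ""
            row[f"avacc_{m}{unit}"] = s.avacc.get(m, np.nan)
            row[f"ig_{m}"] = s.ig.get(m, np.nan)
        row["excluded"] = s.excluded
        row["exclusion_reason"] = s.exclusion_reason
        rows.append(row)
    return pd.DataFrame(rows)
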