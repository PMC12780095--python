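"""End-to-end orchestration: simulate → preprocess → measures → summaries →
agreement → survival, with a machine-readable run manifest.

A run is fully determined by its configuration (including the seed): rerun
with the same config reproduces every stochastic output bit-identically; only
the timings in the manifest differ. The manifest records, per stage, the
participant counts in/out and exclusion reasons (counts are conserved:
in = out + excluded) plus the inventory of files written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import day_summary as ds
from . import survival_models as sm
from .agreement import pairwise_agreement, agreement_to_frame
from .epoch_measures import MEASURES, EpochSeries, compute_epoch_series
from .signal_preprocess import RawRecording, autocalibrate, build_wear_mask
from .synthetic_data import (
    DEFAULT_COVARIATE_BETAS,
    REFERENCE_MEASURE,
    SimulationConfig,
    generate_covariates,
    generate_epoch_series,
    generate_raw_recording,
    simulate_survival,
)

log = logging.getLogger("accelmort")


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    excluded: dict[str, int] = field(default_factory=dict)
    seconds: float = 0.0
    note: str = ""

    def conserved(self) -> bool:
        return self.n_in == self.n_out + sum(self.excluded.values())


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[StageRecord] = field(default_factory=list)
    files: list[str] = field(default_factory=list)
    success: bool = False

    def to_json(self, path: Path) -> None:
        d = asdict(self)
        path.write_text(json.dumps(d, indent=1, sort_keys=True))

    def comparable(self) -> dict:
        """Manifest content with timings removed (for determinism checks)."""
        d = asdict(self)
        for s in d["stages"]:
            s.pop("seconds")
        return d


def config_hash(config: SimulationConfig) -> str:
    d = asdict(config)
    d["start_datetime"] = config.start_datetime.isoformat()
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-participant processing
# ---------------------------------------------------------------------------

def process_recording(rec: RawRecording, epoch_s: float = 5.0):
    """Calibrate, mask and compute the four measures for one raw recording."""
    calibrated, calib = autocalibrate(rec)
    mask = build_wear_mask(calibrated, epoch_s)
    series = compute_epoch_series(calibrated, mask, epoch_s)
    return series, calib


def summarise_series(series: EpochSeries, schemes: dict[str, ds.BinScheme]
                     ) -> ds.ParticipantSummary:
    """Impute, summarise days, check coverage, and build the participant row."""
    imputed = ds.impute_invalid(series)
    days = ds.summarise_days(imputed, schemes)
    coverage_ok = bool(ds.coverage_by_period(imputed).all())
    return ds.summarise_participant(series.participant_id, days, coverage_ok)


def _calibration_epoch_sample(config: SimulationConfig,
                              n_ref_participants: int = 10,
                              max_epochs: int = 50_000) -> dict[str, np.ndarray]:
    """Pooled paired epoch values used to derive the adjusted bin schemes."""
    pooled: dict[str, list[np.ndarray]] = {m: [] for m in MEASURES}
    k = min(n_ref_participants, config.n_participants)
    for i in range(k):
        s = generate_epoch_series(config, i)
        for m in MEASURES:
            pooled[m].append(s.values[m])
    out = {m: np.concatenate(v) for m, v in pooled.items()}
    n = out[REFERENCE_MEASURE].size
    if n > max_epochs:
        step = n // max_epochs + 1
        out = {m: v[::step] for m, v in out.items()}
    return out


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: SimulationConfig, out_dir: str | Path,
            covariate_set: str = "confounders",
            measures: tuple[str, ...] = MEASURES,
            covariate_betas: dict[str, float] | None = None) -> RunManifest:
    """Execute every stage for all four measures on one shared survivor cohort.

    In raw_signal mode per-participant epoch CSVs are written; in epoch_level
    mode (cohort scale) they are skipped to keep output sizes sane. Stages
    that cannot run (e.g. no survivors, too few events for a Cox fit) are
    marked skipped in the manifest rather than aborting the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash(config), config.seed)
    n = config.n_participants
    covariate_betas = (DEFAULT_COVARIATE_BETAS if covariate_betas is None
                       else covariate_betas)

    def record(path: Path) -> None:
        manifest.files.append(str(path.relative_to(out_dir)))

    # -- stage 1+2: simulate & process -------------------------------------
    t0 = time.time()
    calibs: dict = {}
    series_list: list[EpochSeries] = []
    if config.mode == "raw_signal":
        epoch_dir = out_dir / "epochs"
        epoch_dir.mkdir(exist_ok=True)
        for i in range(n):
            rec = generate_raw_recording(config, i)
            s, calib = process_recording(rec, config.epoch_s)
            calibs[s.participant_id] = calib
            series_list.append(s)
            p = epoch_dir / f"{s.participant_id}.csv"
            s.to_frame().to_csv(p, index=False, float_format="%.6g")
            record(p)
    else:
        series_list = [generate_epoch_series(config, i) for i in range(n)]
    manifest.stages.append(StageRecord("simulate_process", n, len(series_list),
                                       seconds=time.time() - t0))
    log.info("simulate/process: %d participants (%s mode)", n, config.mode)

    # -- stage 3: bin schemes ----------------------------------------------
    t0 = time.time()
    ref_scheme = ds.reference_enmo_bins()
    if config.mode == "epoch_level":
        paired = _calibration_epoch_sample(config)
    else:
        paired = {m: np.concatenate([s.values[m] for s in series_list])
                  for m in MEASURES}
    schemes = ds.build_all_schemes(ref_scheme, paired)
    p = out_dir / "bin_schemes.csv"
    pd.concat([schemes[m].to_frame() for m in MEASURES]).to_csv(
        p, index=False, float_format="%.8g")
    record(p)
    manifest.stages.append(StageRecord("bin_schemes", n, n,
                                       seconds=time.time() - t0))

    # -- stage 4: day summaries + exclusions --------------------------------
    t0 = time.time()
    summaries = [summarise_series(s, schemes) for s in series_list]
    try:
        summaries = ds.apply_exclusions(summaries, calibs)
        survivors_frame = ds.summaries_to_frame(summaries)
        excl = survivors_frame.loc[survivors_frame["excluded"],
                                   "exclusion_reason"].value_counts().to_dict()
        n_out = int((~survivors_frame["excluded"]).sum())
        note = ""
    except RuntimeError as exc:
        survivors_frame = ds.summaries_to_frame(summaries)
        excl = survivors_frame["exclusion_reason"].value_counts().to_dict()
        excl.pop("none", None)
        n_out = 0
        note = str(exc)
    p = out_dir / "participant_summary.csv"
    survivors_frame.to_csv(p, index=False, float_format="%.8g")
    record(p)
    manifest.stages.append(StageRecord("summarise_exclude", n, n_out, excl,
                                       time.time() - t0, note))
    log.info("summaries: %d in, %d survive, excluded %s", n, n_out, excl)

    survivors = survivors_frame[~survivors_frame["excluded"]].reset_index(drop=True)

    # -- stage 5: agreement --------------------------------------------------
    t0 = time.time()
    if len(survivors) >= 5:
        agree = agreement_to_frame(pairwise_agreement(survivors))
        p = out_dir / "agreement.csv"
        agree.to_csv(p, index=False, float_format="%.8g")
        record(p)
        manifest.stages.append(StageRecord("agreement", len(survivors),
                                           len(survivors),
                                           seconds=time.time() - t0))
    else:
        manifest.stages.append(StageRecord("agreement", len(survivors),
                                           len(survivors),
                                           seconds=time.time() - t0,
                                           note="skipped: too few survivors"))

    # -- stage 6: survival simulation ---------------------------------------
    t0 = time.time()
    cohort = None
    if len(survivors) >= 10 and survivors[f"ig_{REFERENCE_MEASURE}"].std() > 0:
        covs = generate_covariates(config)
        cohort = simulate_survival(survivors, config.effects, config.seed,
                                   config.entry_age_range,
                                   covariates=covs,
                                   covariate_betas=covariate_betas)
        cohort = sm.prepare_cohort(cohort, measures)
        p = out_dir / "cohort.csv"
        cols = (["pid", "entry_age", "exit_age", "event", "sex", "lifestyle",
                 "morbidity", "season_sin", "season_cos"]
                + [c for c in cohort.columns if c.startswith(("avacc_", "ig_",
                                                              "z_avacc_", "z_ig_"))])
        cohort[cols].to_csv(p, index=False, float_format="%.8g")
        record(p)
        manifest.stages.append(StageRecord("simulate_survival", len(survivors),
                                           len(cohort),
                                           seconds=time.time() - t0))
        log.info("survival cohort: %d participants, %d events",
                 len(cohort), int(cohort["event"].sum()))
    else:
        manifest.stages.append(StageRecord("simulate_survival", len(survivors),
                                           0, seconds=time.time() - t0,
                                           note="skipped: cohort too small"))

    # -- stage 7: survival models -------------------------------------------
    t0 = time.time()
    if cohort is not None and int(cohort["event"].sum()) >= sm.MIN_EVENTS:
        model_dir = out_dir / "models"
        model_dir.mkdir(exist_ok=True)
        quadrant_results = []
        for m in measures:
            res = sm.fit_mutual_cox(cohort, m, covariate_set)
            diag, refit = sm.ph_diagnostics(res)
            final = refit if refit is not None else res
            payload = {
                "measure": m,
                "covariate_set": covariate_set,
                "coefficients": final.params.round(10).to_dict(),
                "covariance": {
                    "columns": list(final.covariance.columns),
                    "values": np.asarray(final.covariance).round(12).tolist(),
                },
                "bic": round(final.bic, 6),
                "n": final.n,
                "n_events": final.n_events,
                "strata": final.strata,
                "ph_pvalues": diag["p"].round(10).to_dict(),
                "hr_curves": {
                    e: sm.hr_curve(final, e).round(8).to_dict(orient="list")
                    for e in ("avacc", "ig")
                },
            }
            p = model_dir / f"{m}_continuous.json"
            p.write_text(json.dumps(payload, indent=1, sort_keys=True))
            record(p)
            quadrant_results.append(
                sm.fit_quadrant_cox(cohort, m, covariate_set,
                                    strata=final.strata or None))
        p = out_dir / "quadrants.csv"
        sm.quadrants_to_frame(quadrant_results).to_csv(
            p, index=False, float_format="%.8g")
        record(p)
        manifest.stages.append(StageRecord("survival_models", len(cohort),
                                           len(cohort),
                                           seconds=time.time() - t0))
    else:
        n_in = 0 if cohort is None else len(cohort)
        manifest.stages.append(StageRecord("survival_models", n_in, n_in,
                                           seconds=time.time() - t0,
                                           note="skipped: too few events"))

    manifest.success = True
    manifest.files.append("manifest.json")
    manifest.to_json(out_dir / "manifest.json")
    return manifest
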