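"""Mutually adjusted spline Cox models and the quadrant model on the age
timescale.

The continuous model enters both standardized exposures (AvAcc and IG, per
measure) as natural cubic splines with three internal knots — boundary knots
at the 5th/95th percentile, internal knots at the 25th/50th/75th percentile
of values within the boundary — in one Cox proportional hazards model with
age as the underlying time axis (delayed entry at the age of accelerometer
wear) and Efron tie handling. Hazard-ratio curves are referenced at 0 SD
(the cohort mean). The quadrant model replaces the splines by a 4-category
exposure from median splits of AvAcc and IG with low/low as reference.

Model fitting is delegated to lifelines (which supports left truncation via
``entry_col``); Schoenfeld and martingale residual diagnostics are computed
here with explicit delayed-entry risk sets, because library residuals are
not available for left-truncated fits. The proportional-hazards test is the
Grambsch–Therneau statistic on scaled Schoenfeld residuals against attained
age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter

from .epoch_measures import MEASURES

COVARIATE_SETS: dict[str, list[str]] = {
    "confounders": ["sex", "lifestyle", "season_sin", "season_cos"],
    "confounders_mediators": ["sex", "lifestyle", "season_sin", "season_cos",
                              "morbidity"],
}
# covariates eligible for baseline-hazard stratification when they fail PH
CATEGORICAL_COVARIATES = ("sex", "lifestyle")

MIN_EVENTS = 30


# ---------------------------------------------------------------------------
# Standardisation and the season covariate
# ---------------------------------------------------------------------------

def standardise(values, ddof: int = 0) -> np.ndarray:
    """Z-scores: subtract the mean, divide by the (population) SD."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardise a constant (or non-finite) vector")
    return (v - v.mean()) / sd


def season_covariate(start_datetime: datetime) -> tuple[float, float]:
    """Two orthogonal sine functions of the fractional day of year."""
    year_start = datetime(start_datetime.year, 1, 1)
    d = (start_datetime - year_start).total_seconds() / 86400.0
    angle = 2.0 * np.pi * d / 365.25
    return float(np.sin(angle)), float(np.cos(angle))


# ---------------------------------------------------------------------------
# Natural cubic spline basis
# ---------------------------------------------------------------------------

@dataclass
class SplineSpec:
    """Knot layout for a natural cubic spline: boundary + internal knots."""

    boundary: tuple[float, float]
    internal: tuple[float, ...]

    def __post_init__(self) -> None:
        ks = self.all_knots
        if np.any(np.diff(ks) <= 0):
            raise ValueError("knots must be strictly increasing "
                             f"(got {ks.tolist()})")

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray([self.boundary[0], *self.internal, self.boundary[1]],
                          dtype=float)

    @property
    def n_basis(self) -> int:
        return len(self.internal) + 1

    @classmethod
    def from_values(cls, values, n_internal: int = 3,
                    boundary_percentiles: tuple[float, float] = (5.0, 95.0)
                    ) -> "SplineSpec":
        """Boundary knots at the 5th/95th percentile; internal knots at
        equally spaced percentiles (25/50/75 for three) of the values within
        the boundary."""
        v = np.asarray(values, dtype=float)
        lo, hi = np.percentile(v, boundary_percentiles)
        inside = v[(v >= lo) & (v <= hi)]
        if n_internal > 0:
            qs = np.linspace(0, 100, n_internal + 2)[1:-1]
            internal = tuple(np.percentile(inside, qs))
        else:
            internal = ()
        return cls((float(lo), float(hi)), internal)


def natural_spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    Truncated-power construction with the natural constraints: with knots
    ξ_1 < … < ξ_K (boundary included), the K−1 columns are x and
    d_k(x) − d_{K−1}(x) for k = 1..K−2, where
    d_k(x) = [(x−ξ_k)³_+ − (x−ξ_K)³_+] / (ξ_K − ξ_k). Extrapolation beyond
    either boundary is exactly linear. For zero internal knots this reduces
    to the single linear column.
    """
    x = np.asarray(x, dtype=float)
    knots = spec.all_knots
    K = knots.size

    def d(k: int) -> np.ndarray:
        num = (np.maximum(x - knots[k], 0.0) ** 3
               - np.maximum(x - knots[K - 1], 0.0) ** 3)
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    if K > 2:
        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Cohort preparation
# ---------------------------------------------------------------------------

def prepare_cohort(df: pd.DataFrame,
                   measures: tuple[str, ...] = MEASURES) -> pd.DataFrame:
    """Standardise per-measure exposures and derive the season covariate.

    Expects ``avacc_<m>*`` / ``ig_<m>`` columns plus ``wear_start`` dates and
    survival columns; adds ``z_avacc_<m>``, ``z_ig_<m>``, ``season_sin``,
    ``season_cos``.
    """
    out = df.copy()
    for m in measures:
        av_col = next(c for c in df.columns if c.startswith(f"avacc_{m}"))
        out[f"z_avacc_{m}"] = standardise(df[av_col])
        out[f"z_ig_{m}"] = standardise(df[f"ig_{m}"])
    if "wear_start" in df.columns:
        sincos = [season_covariate(pd.Timestamp(t).to_pydatetime())
                  for t in df["wear_start"]]
        out["season_sin"] = [s for s, _ in sincos]
        out["season_cos"] = [c for _, c in sincos]
    return out


# ---------------------------------------------------------------------------
# The mutually adjusted spline model
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Fitted mutually adjusted model with everything diagnostics need."""

    measure: str
    params: pd.Series
    covariance: pd.DataFrame
    blocks: dict[str, list[str]]            # exposure -> basis column names
    spline_specs: dict[str, SplineSpec]
    covariate_cols: list[str]
    bic: float
    log_likelihood: float
    n: int
    n_events: int
    strata: list[str] = field(default_factory=list)
    model: CoxPHFitter | None = None
    design: pd.DataFrame | None = None      # columns + entry/exit/event (+strata)

    def wald_block_tests(self) -> dict[str, tuple[float, int, float]]:
        """Joint Wald chi-square per exposure block: (statistic, df, p)."""
        out = {}
        for exposure, cols in self.blocks.items():
            beta = self.params[cols].to_numpy()
            V = self.covariance.loc[cols, cols].to_numpy()
            w = float(beta @ np.linalg.solve(V, beta))
            out[exposure] = (w, len(cols), float(stats.chi2.sf(w, len(cols))))
        return out


def _design_matrix(cohort: pd.DataFrame, measure: str,
                   covariate_set: str | list[str],
                   n_internal: int = 3, linear: bool = False
                   ) -> tuple[pd.DataFrame, dict, dict]:
    cov_cols = (COVARIATE_SETS[covariate_set]
                if isinstance(covariate_set, str) else list(covariate_set))
    blocks: dict[str, list[str]] = {}
    specs: dict[str, SplineSpec] = {}
    X = pd.DataFrame(index=cohort.index)
    for exposure in ("avacc", "ig"):
        z = cohort[f"z_{exposure}_{measure}"].to_numpy()
        spec = SplineSpec.from_values(z, n_internal=0 if linear else n_internal)
        basis = natural_spline_basis(z, spec)
        cols = [f"{exposure}_s{j}" for j in range(basis.shape[1])]
        for j, c in enumerate(cols):
            X[c] = basis[:, j]
        blocks[exposure] = cols
        specs[exposure] = spec
    for c in cov_cols:
        X[c] = cohort[c].to_numpy(dtype=float)
    return X, blocks, specs


def fit_mutual_cox(cohort: pd.DataFrame, measure: str,
                   covariate_set: str | list[str] = "confounders",
                   n_internal: int = 3, linear: bool = False,
                   strata: list[str] | None = None) -> CoxResult:
    """Fit the mutually adjusted Cox model for one measure.

    Partial likelihood with delayed entry (age timescale: risk sets are
    participants with entry_age < a <= exit_age), Efron ties, both exposures'
    natural-spline bases plus the covariate set in a single model; optional
    baseline-hazard stratification. BIC = −2·loglik + p·ln(number of events).
    """
    n_events = int(cohort["event"].sum())
    if n_events == 0:
        raise ValueError("no events: the partial likelihood carries no information")
    if n_events < MIN_EVENTS:
        raise ValueError(f"too few events ({n_events} < {MIN_EVENTS})")
    strata = list(strata or [])
    X, blocks, specs = _design_matrix(cohort, measure, covariate_set,
                                      n_internal, linear)
    # stratification removes the covariate from the linear predictor
    cov_cols = [c for c in X.columns
                if not any(c in cols for cols in blocks.values())]
    X = X.drop(columns=[c for c in strata if c in X.columns])
    cov_cols = [c for c in cov_cols if c not in strata]

    df = X.copy()
    df["entry_age"] = cohort["entry_age"].to_numpy(dtype=float)
    df["exit_age"] = cohort["exit_age"].to_numpy(dtype=float)
    df["event"] = cohort["event"].to_numpy(dtype=int)
    for s in strata:
        df[s] = cohort[s].to_numpy()

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # tight Newton tolerance: the spline columns are collinear enough
        # that the default leaves visible wobble along flat directions
        cph.fit(df, duration_col="exit_age", event_col="event",
                entry_col="entry_age", strata=strata or None,
                fit_options={"precision": 1e-9})
    p = len(cph.params_)
    bic = -2.0 * cph.log_likelihood_ + p * np.log(n_events)
    return CoxResult(
        measure=measure,
        params=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        blocks=blocks,
        spline_specs=specs,
        covariate_cols=cov_cols,
        bic=float(bic),
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        strata=strata,
        model=cph,
        design=df,
    )


def hr_curve(result: CoxResult, exposure: str,
             grid: np.ndarray | None = None, alpha: float = 0.05
             ) -> pd.DataFrame:
    """Hazard-ratio curve HR(s) = exp(f(s) − f(0)) with delta-method CIs.

    ``s`` is in SD units; the reference is 0 SD (cohort mean), where the HR
    is exactly 1 with a zero-width interval. Points beyond the boundary knots
    continue linearly (natural-spline extrapolation) and are flagged.
    """
    if grid is None:
        grid = np.linspace(-2.5, 2.5, 101)
    grid = np.asarray(grid, dtype=float)
    spec = result.spline_specs[exposure]
    cols = result.blocks[exposure]
    beta = result.params[cols].to_numpy()
    V = result.covariance.loc[cols, cols].to_numpy()
    basis = natural_spline_basis(grid, spec)
    basis0 = natural_spline_basis(np.array([0.0]), spec)
    c = basis - basis0
    log_hr = c @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", c, V, c))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = spec.boundary
    return pd.DataFrame({
        "sd": grid,
        "hr": np.exp(log_hr),
        "ci_lo": np.exp(log_hr - zcrit * se),
        "ci_hi": np.exp(log_hr + zcrit * se),
        "extrapolated": (grid < lo) | (grid > hi),
    })


# ---------------------------------------------------------------------------
# Residual diagnostics (delayed-entry aware)
# ---------------------------------------------------------------------------

def _schoenfeld_one_stratum(X: np.ndarray, entry: np.ndarray, exit_: np.ndarray,
                            event: np.ndarray, beta: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Schoenfeld residuals (one per event) with explicit risk-set sums.

    Risk set at event age t: entry < t <= exit. Returns (event ages,
    residual matrix d x p).
    """
    risk_score = np.exp(X @ beta)
    ev_idx = np.flatnonzero(event == 1)
    order = ev_idx[np.argsort(exit_[ev_idx], kind="stable")]
    times = exit_[order]
    resids = np.empty((order.size, X.shape[1]))
    for j, (i, t) in enumerate(zip(order, times)):
        at_risk = (entry < t) & (exit_ >= t)
        w = risk_score[at_risk]
        xbar = (w[:, None] * X[at_risk]).sum(axis=0) / w.sum()
        resids[j] = X[i] - xbar
    return times, resids


def schoenfeld_residuals(result: CoxResult) -> tuple[np.ndarray, np.ndarray]:
    """Event ages and Schoenfeld residuals for the fitted model (all strata)."""
    df = result.design
    cols = list(result.params.index)
    beta = result.params.to_numpy()
    groups = ([(None, df)] if not result.strata
              else list(df.groupby(result.strata, observed=True)))
    t_all, r_all = [], []
    for _, g in groups:
        t, r = _schoenfeld_one_stratum(
            g[cols].to_numpy(dtype=float),
            g["entry_age"].to_numpy(dtype=float),
            g["exit_age"].to_numpy(dtype=float),
            g["event"].to_numpy(dtype=int), beta)
        t_all.append(t)
        r_all.append(r)
    times = np.concatenate(t_all)
    resids = np.vstack(r_all)
    order = np.argsort(times, kind="stable")
    return times[order], resids[order]


def ph_test(result: CoxResult) -> pd.DataFrame:
    """Grambsch–Therneau proportional-hazards test per model term.

    Scaled Schoenfeld residuals r* = d·Cov(β̂)·s are regressed on attained
    age (the identity transform of the event times); the per-term statistic

        T_j = [Σ (g−ḡ) r*_j]² / (d · Var(β̂_j) · Σ(g−ḡ)²)

    is chi-square with 1 df under proportional hazards.
    """
    times, s = schoenfeld_residuals(result)
    d = times.size
    Vbeta = result.covariance.to_numpy()
    r_star = d * (s @ Vbeta)
    g = times - times.mean()
    num = (g[:, None] * r_star).sum(axis=0) ** 2
    denom = d * np.diag(Vbeta) * (g ** 2).sum()
    T = num / denom
    p = stats.chi2.sf(T, 1)
    return pd.DataFrame({"term": result.params.index, "chi2": T, "p": p}) \
        .set_index("term")


def martingale_residuals(result: CoxResult) -> np.ndarray:
    """Martingale residuals with a Breslow baseline and delayed entry.

    M_i = event_i − [Λ₀(exit_i) − Λ₀(entry_i)] · exp(x_i β), with the
    baseline cumulative hazard accumulated per stratum.
    """
    df = result.design
    cols = list(result.params.index)
    beta = result.params.to_numpy()
    M = np.empty(len(df))
    groups = ([(None, df)] if not result.strata
              else list(df.groupby(result.strata, observed=True)))
    for _, g in groups:
        X = g[cols].to_numpy(dtype=float)
        entry = g["entry_age"].to_numpy(dtype=float)
        exit_ = g["exit_age"].to_numpy(dtype=float)
        event = g["event"].to_numpy(dtype=int)
        w = np.exp(X @ beta)
        ev_times = np.unique(exit_[event == 1])
        increments = np.empty(ev_times.size)
        for k, t in enumerate(ev_times):
            at_risk = (entry < t) & (exit_ >= t)
            increments[k] = (event[exit_ == t].sum()) / w[at_risk].sum()
        cum = np.cumsum(increments)

        def Lambda0(a: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(ev_times, a, side="right")
            return np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)

        pos = df.index.get_indexer(g.index)
        M[pos] = event - (Lambda0(exit_) - Lambda0(entry)) * w
    return M


def martingale_linearity(result: CoxResult, covariate: str) -> float:
    """Functional-form check: p-value of the quadratic term when martingale
    residuals are regressed on the covariate and its square."""
    M = martingale_residuals(result)
    x = result.design[covariate].to_numpy(dtype=float)
    A = np.column_stack([np.ones_like(x), x, x ** 2])
    coef, _, _, _ = np.linalg.lstsq(A, M, rcond=None)
    resid = M - A @ coef
    dof = x.size - 3
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    tstat = coef[2] / np.sqrt(cov[2, 2])
    return float(2 * stats.t.sf(abs(tstat), dof))


def ph_diagnostics(result: CoxResult, alpha: float = 0.05,
                   refit_stratified: bool = True
                   ) -> tuple[pd.DataFrame, CoxResult | None]:
    """Per-term PH test plus linearity checks; stratified refit on failures.

    Covariates failing the Schoenfeld test at ``alpha`` are reported; when
    they are categorical the model is refit with baseline hazards stratified
    on them (their coefficients disappear from the refit). Continuous terms
    failing PH are reported only. Plain continuous covariates additionally
    get a martingale linearity p-value.
    """
    table = ph_test(result)
    table["fails_ph"] = table["p"] < alpha
    lin = {}
    for c in result.covariate_cols:
        if c not in CATEGORICAL_COVARIATES:
            lin[c] = martingale_linearity(result, c)
    table["linearity_p"] = pd.Series(lin).reindex(table.index)

    to_stratify = [c for c in result.covariate_cols
                   if c in CATEGORICAL_COVARIATES
                   and c in table.index and bool(table.loc[c, "fails_ph"])]
    refit = None
    if to_stratify and refit_stratified:
        # refit on the stored design: exposures are already basis columns and
        # lifelines drops strata columns from the regressors automatically
        df = result.design.copy()
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="exit_age", event_col="event",
                    entry_col="entry_age", strata=to_stratify,
                    fit_options={"precision": 1e-9})
        p = len(cph.params_)
        refit = CoxResult(
            measure=result.measure, params=cph.params_.copy(),
            covariance=cph.variance_matrix_.copy(), blocks=result.blocks,
            spline_specs=result.spline_specs,
            covariate_cols=[c for c in result.covariate_cols
                            if c not in to_stratify],
            bic=float(-2 * cph.log_likelihood_ + p * np.log(result.n_events)),
            log_likelihood=float(cph.log_likelihood_),
            n=result.n, n_events=result.n_events, strata=to_stratify,
            model=cph, design=df,
        )
    return table, refit


# ---------------------------------------------------------------------------
# Quadrant model
# ---------------------------------------------------------------------------

QUADRANTS = ("low/low", "low/high", "high/low", "high/high")


@dataclass
class QuadrantResult:
    measure: str
    medians: tuple[float, float]           # (avacc, ig) medians
    counts: dict[str, int]
    events: dict[str, int]
    hr: dict[str, tuple[float, float, float]]  # quadrant -> (hr, lo, hi)
    bic: float = float("nan")


def quadrant_assign(cohort: pd.DataFrame, measure: str
                    ) -> tuple[pd.Series, tuple[float, float]]:
    """Median-split labels (first word AvAcc, second IG); ties go to 'high'."""
    av = cohort[f"z_avacc_{measure}"].to_numpy(dtype=float)
    ig = cohort[f"z_ig_{measure}"].to_numpy(dtype=float)
    med_a, med_i = float(np.median(av)), float(np.median(ig))
    a_high = av >= med_a
    i_high = ig >= med_i
    labels = np.where(a_high, "high", "low")
    labels = np.char.add(np.char.add(labels, "/"),
                         np.where(i_high, "high", "low"))
    return pd.Series(labels, index=cohort.index, name="quadrant"), (med_a, med_i)


def fit_quadrant_cox(cohort: pd.DataFrame, measure: str,
                     covariate_set: str | list[str] = "confounders",
                     min_events_per_quadrant: int = 5,
                     strata: list[str] | None = None) -> QuadrantResult:
    """HRs with 95% CIs for the three non-reference quadrants (low/low ref),
    same covariates and age timescale as the continuous model."""
    labels, medians = quadrant_assign(cohort, measure)
    counts = {q: int((labels == q).sum()) for q in QUADRANTS}
    events = {q: int(cohort.loc[labels == q, "event"].sum()) for q in QUADRANTS}
    if any(c == 0 for c in counts.values()):
        raise ValueError(f"empty quadrant: {counts}")
    if any(e < min_events_per_quadrant for e in events.values()):
        raise ValueError(f"too few events per quadrant: {events}")

    cov_cols = (COVARIATE_SETS[covariate_set]
                if isinstance(covariate_set, str) else list(covariate_set))
    strata = list(strata or [])
    cov_cols = [c for c in cov_cols if c not in strata]
    df = pd.DataFrame(index=cohort.index)
    dummy_cols = []
    for q in QUADRANTS[1:]:
        col = "q_" + q.replace("/", "_")
        df[col] = (labels == q).astype(float)
        dummy_cols.append(col)
    for c in cov_cols:
        df[c] = cohort[c].to_numpy(dtype=float)
    df["entry_age"] = cohort["entry_age"].to_numpy(dtype=float)
    df["exit_age"] = cohort["exit_age"].to_numpy(dtype=float)
    df["event"] = cohort["event"].to_numpy(dtype=int)
    for s in strata:
        df[s] = cohort[s].to_numpy()

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="exit_age", event_col="event",
                entry_col="entry_age", strata=strata or None,
                fit_options={"precision": 1e-9})
    hr = {"low/low": (1.0, 1.0, 1.0)}
    zcrit = stats.norm.ppf(0.975)
    for q, col in zip(QUADRANTS[1:], dummy_cols):
        b = float(cph.params_[col])
        se = float(np.sqrt(cph.variance_matrix_.loc[col, col]))
        hr[q] = (float(np.exp(b)), float(np.exp(b - zcrit * se)),
                 float(np.exp(b + zcrit * se)))
    p = len(cph.params_)
    bic = float(-2 * cph.log_likelihood_ + p * np.log(df["event"].sum()))
    return QuadrantResult(measure, medians, counts, events, hr, bic)


def quadrants_to_frame(results: list[QuadrantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for q in QUADRANTS:
            h, lo, hi = r.hr[q]
            rows.append({"measure": r.measure, "quadrant": q,
                         "n": r.counts[q], "events": r.events[q],
                         "hr": h, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-complexity sweep
# ---------------------------------------------------------------------------

def compare_spline_complexity(cohort: pd.DataFrame, measure: str,
                              covariate_set: str | list[str] = "confounders",
                              k_list: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
                              ) -> pd.DataFrame:
    """BIC per spline complexity: a linear fit plus 1..7 internal knots.

    Fit failures are recorded per row without aborting the sweep; the
    ``best`` column marks the BIC argmin among converged rows.
    """
    rows = []
    for label, kwargs in ([("linear", {"linear": True})]
                          + [(f"{k}_knots", {"n_internal": k}) for k in k_list]):
        try:
            res = fit_mutual_cox(cohort, measure, covariate_set, **kwargs)
            rows.append({"complexity": label, "bic": res.bic,
                         "n_params": len(res.params), "error": ""})
        except Exception as exc:  # propagate per-row
            rows.append({"complexity": label, "bic": np.nan,
                         "n_params": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    valid = table["bic"].notna()
    table["best"] = False
    if valid.any():
        table.loc[table.loc[valid, "bic"].idxmin(), "best"] = True
    return table
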