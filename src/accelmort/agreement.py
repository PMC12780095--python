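"""Relative agreement of AvAcc and IG between measure pairs.

Pearson's r (Fisher-z confidence intervals) for both exposures, and the
intraclass correlation ICC(3,1) — two-way mixed effects, consistency,
single rater — for IG only: the ICC is sensitive to mean and scale
differences and AvAcc inherits its scale and unit from the measure, so a
consistency ICC across measures is only meaningful for the unit-free IG.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .epoch_measures import MEASURES


@dataclass
class AgreementResult:
    variable: str            # "avacc" or "ig"
    measure_a: str
    measure_b: str
    stat: str                # "pearson_r" or "icc"
    estimate: float
    ci_lo: float
    ci_hi: float
    n: int


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Product-moment correlation with a Fisher-z confidence interval.

    SE of the z-transform is 1/sqrt(n−3). Degenerate |r| = 1 is reported as
    a point interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return r, r, r
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, float(lo), float(hi)


def icc_consistency(matrix, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(3,1): two-way mixed effects, consistency, single rater.

    From the two-way ANOVA decomposition of an n subjects x k raters matrix:

        ICC = (MS_rows − MS_error) / (MS_rows + (k−1) MS_error)

    with the exact F-distribution confidence bounds for the consistency form.
    The matrix must be complete.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected an n x k matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (no missing cells)")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df_rows, df_err = n - 1, (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err

    if ms_err == 0:
        return 1.0, 1.0, 1.0
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    f_obs = ms_rows / ms_err
    f_lo = f_obs / stats.f.ppf(1 - alpha / 2, df_rows, df_err)
    f_hi = f_obs * stats.f.ppf(1 - alpha / 2, df_err, df_rows)
    lo = (f_lo - 1) / (f_lo + k - 1)
    hi = (f_hi - 1) / (f_hi + k - 1)
    return float(icc), float(lo), float(hi)


def pairwise_agreement(summaries: pd.DataFrame,
                       alpha: float = 0.05) -> list[AgreementResult]:
    """All 6 measure pairs: Pearson r for AvAcc and IG, ICC for IG only.

    ``summaries`` is the survivor cohort frame from ``summaries_to_frame``
    (excluded participants are dropped here if still present).
    """
    df = summaries
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    out: list[AgreementResult] = []
    for a, b in combinations(MEASURES, 2):
        for variable in ("avacc", "ig"):
            cols = []
            for m in (a, b):
                prefix = f"{variable}_{m}"
                col = next(c for c in df.columns if c.startswith(prefix))
                cols.append(df[col].to_numpy(dtype=float))
            x, y = cols
            r, lo, hi = pearson_ci(x, y, alpha)
            out.append(AgreementResult(variable, a, b, "pearson_r",
                                       r, lo, hi, x.size))
            if variable == "ig":
                icc, ilo, ihi = icc_consistency(np.column_stack([x, y]), alpha)
                out.append(AgreementResult(variable, a, b, "icc",
                                           icc, ilo, ihi, x.size))
    return out


def agreement_to_frame(results: list[AgreementResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "measure_a": r.measure_a,
        "measure_b": r.measure_b, "stat": r.stat, "estimate": r.estimate,
        "ci_lo": r.ci_lo, "ci_hi": r.ci_hi, "n": r.n,
    } for r in results])
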