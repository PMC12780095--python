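"""Independent reference computations used by the tests.

Everything here recomputes a quantity from its definition (explicit sums,
brute-force window scans, literal step-by-step filter chains) without calling
the package's implementation path, so agreement between the two is evidence,
not tautology. Filter-chain oracles share the packaged constants but apply
each step themselves.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


# ---------------------------------------------------------------------------
# Log-log histogram regression (power-law slope)
# ---------------------------------------------------------------------------

def loglog_histogram_slope(values: np.ndarray, bins: np.ndarray) -> float:
    """OLS slope of ln(count) on ln(bin midpoint), explicit formulas."""
    counts, edges = np.histogram(values, bins=bins)
    mids = (edges[:-1] + edges[1:]) / 2.0
    keep = counts > 0
    x = np.log(mids[keep])
    y = np.log(counts[keep])
    xc = x - x.mean()
    return float((xc * y).sum() / (xc * xc).sum())


def loglog_leastsquares(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form log-log least squares: returns (a, b) of y = a * x**b."""
    lx, ly = np.log(x), np.log(y)
    lxc = lx - lx.mean()
    b = (lxc * ly).sum() / (lxc * lxc).sum()
    ln_a = ly.mean() - b * lx.mean()
    return float(np.exp(ln_a)), float(b)


# ---------------------------------------------------------------------------
# Non-wear: brute-force sliding-window recomputation
# ---------------------------------------------------------------------------

def nonwear_blocks_bruteforce(samples: np.ndarray, rate_hz: float,
                              block_s: int = 900, window_s: int = 3600,
                              sd_g: float = 0.013, range_g: float = 0.050
                              ) -> np.ndarray:
    """Boolean per 15-min block, from a literal scan of the 60-min window."""
    n = samples.shape[0]
    n_blocks = int(np.ceil(n / rate_hz / block_s))
    out = np.zeros(n_blocks, dtype=bool)
    for b in range(n_blocks):
        centre = (b + 0.5) * block_s
        lo = max(0, int(round((centre - window_s / 2) * rate_hz)))
        hi = min(n, int(round((centre + window_s / 2) * rate_hz)))
        win = samples[lo:hi]
        if win.shape[0] < 2:
            continue
        quiet = 0
        for a in range(3):
            col = win[:, a]
            if col.std() < sd_g and (col.max() - col.min()) < range_g:
                quiet += 1
        out[b] = quiet >= 2
    return out


# ---------------------------------------------------------------------------
# MIMS / Counts: literal step-by-step chains (same constants, own code)
# ---------------------------------------------------------------------------

def mims_oracle(samples: np.ndarray, rate_hz: float, epoch_s: float,
                constants: dict, dynamic_range_g: float = 8.0) -> np.ndarray:
    """Step-by-step recomputation of the MIMS chain, per epoch."""
    resample_hz = constants["resample_hz"]
    t_in = np.arange(samples.shape[0]) / rate_hz
    dur = samples.shape[0] / rate_hz
    t_out = np.arange(int(round(dur * resample_hz))) / resample_hz
    b, a = sps.butter(constants["filter_order"],
                      [f / (resample_hz / 2) for f in constants["band_hz"]],
                      btype="bandpass")
    n_epochs = int(dur // epoch_s)
    spe = int(round(epoch_s * resample_hz))
    per_axis = np.zeros((n_epochs, 3))
    for ax in range(3):
        y = np.interp(t_out, t_in, samples[:, ax])
        # (saturation handling skipped: oracle fixtures stay inside range)
        assert np.abs(y).max() < constants["saturation_fraction"] * dynamic_range_g
        y = np.abs(sps.filtfilt(b, a, y))
        for k in range(n_epochs):
            seg = y[k * spe: (k + 1) * spe + 1]
            v = np.trapezoid(seg, dx=1.0 / resample_hz)
            per_axis[k, ax] = 0.0 if v < constants["truncate_below"] else v
    return per_axis.sum(axis=1)


def counts_oracle(samples: np.ndarray, rate_hz: float, epoch_s: float,
                  constants: dict, axis_combination: str = "vector_norm"
                  ) -> np.ndarray:
    """Step-by-step recomputation of the counts chain, per epoch."""
    resample_hz = constants["resample_hz"]
    t_in = np.arange(samples.shape[0]) / rate_hz
    dur = samples.shape[0] / rate_hz
    t_out = np.arange(int(round(dur * resample_hz))) / resample_hz
    b, a = sps.butter(constants["filter_order"],
                      [f / (resample_hz / 2) for f in constants["band_hz"]],
                      btype="bandpass")
    dec = int(round(resample_hz / constants["decimate_to_hz"]))
    spe = int(round(epoch_s * constants["decimate_to_hz"]))
    n_epochs = int(dur // epoch_s)
    axis_sums = np.zeros((n_epochs, 3))
    for ax in range(3):
        y = np.interp(t_out, t_in, samples[:, ax])
        y, _ = sps.lfilter(b, a, y, zi=sps.lfilter_zi(b, a) * y[0])
        y = y[::dec]
        y = np.minimum(np.maximum(y, -constants["clip_g"]), constants["clip_g"])
        y = np.abs(y)
        y = np.where(y < constants["deadband_g"], 0.0, y)
        q = constants["quantisation_g"]
        y = np.floor(y / q) * q
        for k in range(n_epochs):
            axis_sums[k, ax] = y[k * spe: (k + 1) * spe].sum()
    if axis_combination == "vector_norm":
        return np.sqrt((axis_sums ** 2).sum(axis=1))
    return axis_sums.sum(axis=1)


# ---------------------------------------------------------------------------
# Pearson / ICC explicit formulas
# ---------------------------------------------------------------------------

def pearson_fisher_oracle(x: np.ndarray, y: np.ndarray, alpha: float = 0.05
                          ) -> tuple[float, float, float]:
    """Correlation and Fisher-z CI from the definitional sums."""
    from scipy.stats import norm
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / (sxx * syy) ** 0.5
    z = 0.5 * np.log((1 + r) / (1 - r))
    half = norm.ppf(1 - alpha / 2) / (n - 3) ** 0.5
    lo = np.tanh(z - half)
    hi = np.tanh(z + half)
    return float(r), float(lo), float(hi)


def icc31_anova_oracle(m: np.ndarray) -> float:
    """ICC(3,1) from sums of squares written out by definition."""
    n, k = m.shape
    grand = m.sum() / m.size
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in m)
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((v - grand) ** 2 for v in m.ravel())
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


# ---------------------------------------------------------------------------
# Cox partial likelihood: brute force (Efron ties, delayed entry)
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta: np.ndarray, X: np.ndarray, entry: np.ndarray,
                       exit_: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood with explicit risk-set sums."""
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(exit_[event == 1]):
        D = np.flatnonzero((exit_ == t) & (event == 1))
        R = np.flatnonzero((entry < t) & (exit_ >= t))
        d = D.size
        sum_R = w[R].sum()
        sum_D = w[D].sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(sum_R - (l / d) * sum_D)
    return float(ll)


def cox_partial_gradient(beta: np.ndarray, X: np.ndarray, entry: np.ndarray,
                         exit_: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Gradient of the Efron partial log-likelihood, explicit sums."""
    beta = np.asarray(beta, dtype=float)
    w = np.exp(X @ beta)
    g = np.zeros_like(beta)
    for t in np.unique(exit_[event == 1]):
        D = np.flatnonzero((exit_ == t) & (event == 1))
        R = np.flatnonzero((entry < t) & (exit_ >= t))
        d = D.size
        sum_R = w[R].sum()
        sum_D = w[D].sum()
        num_R = (w[R, None] * X[R]).sum(axis=0)
        num_D = (w[D, None] * X[D]).sum(axis=0)
        g += X[D].sum(axis=0)
        for l in range(d):
            frac = l / d
            g -= (num_R - frac * num_D) / (sum_R - frac * sum_D)
    return g


def cox_newton_bruteforce(X: np.ndarray, entry: np.ndarray, exit_: np.ndarray,
                          event: np.ndarray, n_iter: int = 50,
                          tol: float = 1e-10) -> np.ndarray:
    """Newton's method on the brute-force partial likelihood (numeric Hessian)."""
    p = X.shape[1]
    beta = np.zeros(p)
    h = 1e-5
    for _ in range(n_iter):
        g = cox_partial_gradient(beta, X, entry, exit_, event)
        H = np.empty((p, p))
        for j in range(p):
            e = np.zeros(p)
            e[j] = h
            H[:, j] = (cox_partial_gradient(beta + e, X, entry, exit_, event)
                       - cox_partial_gradient(beta - e, X, entry, exit_, event)
                       ) / (2 * h)
        step = np.linalg.solve(H, g)
        beta = beta - step
        if np.abs(step).max() < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# Truncated-power natural-spline column-space check
# ---------------------------------------------------------------------------

def truncated_power_natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline column space built from the raw truncated-power
    basis {x, (x−ξ_k)³₊} with the natural (linear-tail) constraints imposed
    via explicit null-space algebra rather than the packaged recursion."""
    K = knots.size
    # full cubic truncated-power basis (without intercept / x²,x³ handled
    # through the constraint system)
    cols = [x, x ** 2, x ** 3]
    cols += [np.maximum(x - k, 0.0) ** 3 for k in knots]
    B = np.column_stack(cols)
    # natural constraints: second and third derivative vanish beyond the
    # boundary. Below ξ_1: coefficients of x², x³ are zero. Above ξ_K:
    # quadratic and cubic terms must cancel in total.
    #   c2 = 0 ; c3 = 0
    #   c3 + Σ a_k = 0           (cubic tail)
    #   2 c2 + 6 Σ a_k (x-term)… handled via: Σ a_k = 0 and Σ a_k ξ_k = 0
    ncol = B.shape[1]
    C = np.zeros((4, ncol))
    C[0, 1] = 1.0                      # c2 = 0
    C[1, 2] = 1.0                      # c3 = 0
    C[2, 3:] = 1.0                     # Σ a_k = 0
    C[3, 3:] = knots                   # Σ a_k ξ_k = 0
    # null space of C
    _, s, Vt = np.linalg.svd(C)
    null = Vt[np.sum(s > 1e-12):].T
    return B @ null
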