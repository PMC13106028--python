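"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives its quantity from first principles (explicit loops
and closed-form algebra) without calling the package implementation paths
it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

MONTH_DAYS = 30.4375


# ---------------------------------------------------------------------------
# phenotyping: explicit 17-window loop with closed-form OLS
# ---------------------------------------------------------------------------

def brute_classify_ehr(times_days, weights, bmis=None,
                       wl_threshold=0.05, p_threshold=0.05,
                       low_bmi=20.0):
    """Sliding-window weight-loss call, written from the contract.

    Returns (status, basis). Windows start 60, 57, ..., 12 months before the
    last record; each ends max(start-12, 6) months before; membership is
    end <= m < start in months-before-last. A WL window needs >= 3 points,
    negative slope, slope t-test p < 0.05, and annualized loss >= 5% of the
    mean in-window weight (with the documented 1e-9 roundoff guard).
    """
    t = np.asarray(times_days, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(t)
    t, w = t[order], w[order]
    if bmis is not None:
        bmis = list(np.asarray(bmis, dtype=object)[order])
    t_last = t[-1]
    mb = (t_last - t) / MONTH_DAYS

    wl_member = np.zeros(len(t), dtype=bool)
    any_wl = False
    for start in range(60, 11, -3):
        end = max(start - 12, 6)
        sel = (mb >= end) & (mb < start)
        n = int(sel.sum())
        if n < 3:
            continue
        x = t[sel] / MONTH_DAYS
        y = w[sel]
        if x.max() == x.min():
            continue
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        sse = float(np.sum(resid ** 2))
        ssy = float(np.sum((y - y.mean()) ** 2))
        if sse <= 1e-12 * max(ssy, 1.0):
            p = 0.0 if slope != 0 else 1.0
        else:
            se = np.sqrt(sse / (n - 2) / sxx)
            p = 2.0 * stats.t.sf(abs(slope / se), n - 2)
        alf = (-slope * 12.0) / y.mean()
        if slope < 0 and p < p_threshold and alf >= wl_threshold * (1 - 1e-9):
            any_wl = True
            wl_member |= sel

    final_weight = w[-1]
    final_bmi = None
    if bmis is not None:
        for b in reversed(bmis):
            if b is not None and np.isfinite(b):
                final_bmi = float(b)
                break

    case_slope = any_wl and (w[wl_member].max() > final_weight)
    case_bmi = final_bmi is not None and final_bmi < low_bmi
    if case_slope:
        return "case", "slope_window"
    if case_bmi:
        return "case", "low_bmi"
    return "control", "none"


# ---------------------------------------------------------------------------
# logistic regression: textbook Newton-Raphson
# ---------------------------------------------------------------------------

def newton_logistic(y, X, max_iter=200, tol=1e-12):
    """Plain Newton-Raphson MLE for logistic regression; (beta, se, p)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X.T * W) @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = (X.T * (p * (1 - p))) @ X
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return beta, se, pvals


# ---------------------------------------------------------------------------
# fixed-effects meta-analysis: direct formula evaluation
# ---------------------------------------------------------------------------

def brute_meta(betas, ses):
    """Inverse-variance pooling with heterogeneity, evaluated long-hand."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    w = 1.0 / ses ** 2
    bm = np.sum(w * betas) / np.sum(w)
    sm = np.sum(w) ** -0.5
    p = 2.0 * stats.norm.sf(abs(bm / sm))
    q = float(np.sum(w * (betas - bm) ** 2))
    k = len(betas)
    het_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    i2 = 0.0 if q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return bm, sm, p, q, i2, het_p
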