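"""Independent brute-force oracles used to validate the implementations.

Each oracle follows the defining formula directly (explicit pairwise loops,
exhaustive search, grid-refined likelihood maximization) and shares no code
path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by explicit pairwise template counting.

    Chebyshev tolerance ``r`` as a fraction of the series SD; templates
    ``0 .. N-m-1`` for both lengths; self-matches excluded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=0)
    if sd == 0:
        return 0.0
    ra = r * sd
    nt = n - m
    tm = sliding_window_view(x, m)[:nt]
    tm1 = sliding_window_view(x, m + 1)[:nt]
    a = b = 0
    for i in range(nt - 1):
        b += int(np.count_nonzero(np.max(np.abs(tm[i + 1:] - tm[i]), axis=1) <= ra))
        a += int(np.count_nonzero(np.max(np.abs(tm1[i + 1:] - tm1[i]), axis=1) <= ra))
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def auc_concordance(p_hat, y) -> float:
    """AUC as the all-pairs concordance proportion (ties count 1/2)."""
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = p_hat[y == 1]
    neg = p_hat[y == 0]
    total = len(pos) * len(neg)
    if total == 0:
        return math.nan
    score = 0.0
    for pp in pos:
        score += np.sum(pp > neg) + 0.5 * np.sum(pp == neg)
    return float(score) / total


def logistic_loglik(b0: float, b1: float, x, y) -> float:
    eta = b0 + b1 * np.asarray(x, dtype=float)
    return float(np.sum(np.asarray(y) * eta - np.logaddexp(0.0, eta)))


def logistic_grid_fit(x, y, span: float = 8.0, rounds: int = 7):
    """Maximize the single-predictor logistic likelihood by nested grid search."""
    b0c = b1c = 0.0
    width = span
    for _ in range(rounds):
        g0 = np.linspace(b0c - width, b0c + width, 41)
        g1 = np.linspace(b1c - width, b1c + width, 41)
        ll = np.array([[logistic_loglik(a, b, x, y) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0c, b1c = float(g0[i]), float(g1[j])
        width = width / 8.0
    return b0c, b1c


def autocorr_lag_search(x, fs: float, lag_range) -> float:
    """Stride frequency by exhaustive unbiased-autocorrelation lag search."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    denom = float(x @ x) / n
    best_lag, best_val = None, -np.inf
    lo = int(math.floor(fs / lag_range[1]))
    hi = int(math.ceil(fs / lag_range[0]))
    for lag in range(max(lo, 1), min(hi, n // 2)):
        c = float(x[: n - lag] @ x[lag:]) / (n - lag) / denom
        if c > best_val:
            best_val, best_lag = c, lag
    return fs / best_lag


def icc_two_way_by_hand(y: np.ndarray) -> float:
    """ICC(2,1) from explicit ANOVA sums of squares (loop form)."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum(
        (y[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
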