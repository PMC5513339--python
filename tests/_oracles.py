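"""Independent oracle implementations used only by the tests.

These deliberately use the slowest, most transparent formulation of each
quantity (explicit Newton/IRLS, exhaustive pair loops, direct groupby) so
that the package's optimized implementations are checked against code
that shares nothing with them.
"""

import numpy as np
from scipy.special import expit


def irls_logistic(y, X, offset=None, tol=1e-12, maxiter=100):
    """Plain Newton-Raphson / IRLS for logistic regression.

    X must already contain the intercept column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta + off
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def pairwise_c_index(pred, y, w=None):
    """Exhaustive O(n^2) loop over all (event, non-event) pairs."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y)
    w = np.ones_like(pred) if w is None else np.asarray(w, dtype=float)
    num = den = 0.0
    for i in range(len(y)):
        if y[i] != 1 or w[i] <= 0:
            continue
        for j in range(len(y)):
            if y[j] != 0 or w[j] <= 0:
                continue
            m = w[i] * w[j]
            den += m
            if pred[i] > pred[j]:
                num += m
            elif pred[i] == pred[j]:
                num += 0.5 * m
    return num / den


def truncate_by_sorting(weights, percentile):
    """Order-statistic cap: sort, linearly interpolate the percentile, clip."""
    w = np.sort(np.asarray(weights, dtype=float))
    rank = (percentile / 100.0) * (len(w) - 1)
    lo, hi = int(np.floor(rank)), int(np.ceil(rank))
    cap = w[lo] + (rank - lo) * (w[hi] - w[lo])
    return np.minimum(weights, cap)


def groupby_calibration(pred, y, w, group_ids):
    """Direct per-group weighted means, for checking binned curves."""
    out = {}
    for g in np.unique(group_ids):
        m = group_ids == g
        tot = w[m].sum()
        out[g] = (float((w[m] * pred[m]).sum() / tot), float((w[m] * y[m]).sum() / tot), float(tot))
    return out
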