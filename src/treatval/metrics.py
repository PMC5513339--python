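"""Weighted performance metrics: concordance, calibration-in-the-large,
and calibration curves.

The weighted c-index generalizes the usual concordance probability: over
all (event i, non-event j) pairs, each pair carries mass w_i * w_j, a pair
is concordant when the event has the higher predicted risk, and tied
predictions count one half. Unit weights recover the standard c-index
(the area under the ROC curve). The observed:expected ratio is the ratio
of the weighted mean outcome to the weighted mean predicted risk; both
metrics are invariant to rescaling all weights by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError

__all__ = [
    "PerformanceEstimate",
    "weighted_c_index",
    "weighted_oe_ratio",
    "calibration_curve",
    "smoothed_calibration",
]


@dataclass
class PerformanceEstimate:
    """Discrimination and calibration of one model on one analysis set."""

    c_index: float
    oe_ratio: float
    n_effective: int
    calibration_curve: pd.DataFrame | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.flags


def _validate(pred, y, w):
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(pred)
    else:
        w = np.asarray(w, dtype=float)
    if not (pred.shape == y.shape == w.shape):
        raise ValueError("pred, y and weights must share shape")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return pred, y, w


def weighted_c_index(pred, y, w=None) -> float:
    """Weighted concordance probability (pair mass w_i * w_j, ties 0.5).

    Computed in O(n log n): predictions are reduced to their unique sorted
    values, event and non-event weight totals are accumulated per value,
    and concordant mass is a cumulative sum. Equivalent to the exhaustive
    loop over all event/non-event pairs.
    """
    pred, y, w = _validate(pred, y, w)
    ev = (y == 1) & (w > 0)
    ne = (y == 0) & (w > 0)
    if not ev.any() or not ne.any():
        raise UndefinedMetricError(
            "c-index undefined: needs at least one event and one non-event with positive weight"
        )
    vals, inv = np.unique(pred, return_inverse=True)
    we = np.bincount(inv[ev], weights=w[ev], minlength=vals.size)
    wn = np.bincount(inv[ne], weights=w[ne], minlength=vals.size)
    cum_wn_below = np.concatenate(([0.0], np.cumsum(wn)[:-1]))
    concordant = float(we @ cum_wn_below) + 0.5 * float(we @ wn)
    total = float(we.sum() * wn.sum())
    return concordant / total


def weighted_oe_ratio(pred, y, w=None) -> float:
    """Observed:expected ratio, (sum w*y) / (sum w*pred).

    Returns 0.0 when the weighted event count is zero (callers flag this);
    raises if the weighted mean prediction is zero.
    """
    pred, y, w = _validate(pred, y, w)
    expected = float(w @ pred)
    if expected <= 0:
        raise UndefinedMetricError("O:E undefined: weighted mean prediction is zero")
    observed = float(w @ y)
    return observed / expected


def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    p = (cw - 0.5 * ws) / cw[-1]
    return np.interp(qs, p, xs)


def calibration_curve(pred, y, w=None, bins: int = 10) -> pd.DataFrame:
    """Grouped calibration curve over weighted quantile bins of predicted risk.

    Individuals are grouped into ``bins`` equal-mass groups of the
    weighted predicted-risk distribution. Per group the weighted mean
    prediction, the weighted observed outcome proportion, the bin midpoint
    and the weight mass are reported; masses sum to the total analysis
    mass. Groups that collapse (fewer distinct predictions than bins) are
    merged with a warning.
    """
    pred, y, w = _validate(pred, y, w)
    keep = w > 0
    pred, y, w = pred[keep], y[keep], w[keep]
    if pred.size == 0:
        raise UndefinedMetricError("calibration curve undefined on an empty analysis set")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    edges = _weighted_quantiles(pred, w, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    inner = np.unique(edges[1:-1])
    if inner.size < bins - 1:
        warnings.warn(
            f"fewer distinct predictions than bins; merged to {inner.size + 1} groups",
            stacklevel=2,
        )
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    grp = np.searchsorted(edges, pred, side="right") - 1
    k = edges.size - 1
    mass = np.bincount(grp, weights=w, minlength=k)
    nonempty = mass > 0
    wy = np.bincount(grp, weights=w * y, minlength=k)
    wp = np.bincount(grp, weights=w * pred, minlength=k)
    # bin midpoints from the actual per-group prediction range
    mins = np.full(k, np.inf)
    maxs = np.full(k, -np.inf)
    np.minimum.at(mins, grp, pred)
    np.maximum.at(maxs, grp, pred)
    mids = np.full(k, np.nan)
    mids[nonempty] = (mins[nonempty] + maxs[nonempty]) / 2
    df = pd.DataFrame(
        {
            "bin": np.arange(k)[nonempty],
            "bin_mid": mids[nonempty],
            "mean_pred": (wp[nonempty] / mass[nonempty]),
            "obs_prop": (wy[nonempty] / mass[nonempty]),
            "mass": mass[nonempty],
        }
    )
    return df.reset_index(drop=True)


def smoothed_calibration(pred, y, w=None, grid=None, bandwidth: float = 0.03) -> pd.DataFrame:
    """Kernel-smoothed calibration curve on a fixed grid (optional variant).

    Nadaraya-Watson regression of the outcome on predicted risk with a
    Gaussian kernel, weights multiplying the kernel mass. The grouped
    quantile-bin curve is the primary, deterministic estimator; this
    variant exists for plotting smooth curves.
    """
    pred, y, w = _validate(pred, y, w)
    if grid is None:
        grid = np.linspace(pred.min(), pred.max(), 50)
    grid = np.asarray(grid, dtype=float)
    obs = np.empty_like(grid)
    for i, g in enumerate(grid):
        kern = w * np.exp(-0.5 * ((pred - g) / bandwidth) ** 2)
        tot = kern.sum()
        obs[i] = (kern @ y) / tot if tot > 0 else np.nan
    return pd.DataFrame({"pred": grid, "obs_smooth": obs})
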