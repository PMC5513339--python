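"""Inverse-probability-of-treatment weights and percentile truncation.

Weighting untreated individuals by 1/(1-PS) reweights the untreated
subset of a cohort so that it resembles the full (untreated) target
population; the weighted untreated set then supports unbiased estimates
of model performance, provided the propensity model is correct and
positivity holds. The IPW-only strategy (no exclusion) additionally
weights treated individuals by 1/PS, the standard inverse probability of
the treatment actually received.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import PositivityError

__all__ = ["WeightVector", "compute_ipw_weights", "truncate_weights", "weight_diagnostics"]


@dataclass(frozen=True)
class WeightVector:
    """Per-individual weights plus the mask of individuals entering analysis."""

    weights: np.ndarray
    mask: np.ndarray  # bool; True = enters weighted analyses
    truncated_at: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if w.shape != m.shape:
            raise ValueError("weights and mask must share shape")
        if not np.all(np.isfinite(w[m])):
            raise ValueError("masked weights must be finite")
        if np.any(w[m] < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "mask", m)

    @property
    def masked_weights(self) -> np.ndarray:
        return self.weights[self.mask]

    def restrict(self, keep: np.ndarray) -> "WeightVector":
        """Narrow the analysis mask (logical AND with ``keep``)."""
        return replace(self, mask=self.mask & np.asarray(keep, dtype=bool))

    def summary(self) -> dict:
        w = self.masked_weights
        if w.size == 0:
            return {"n": 0}
        qs = np.percentile(w, [0, 25, 50, 75, 98, 100])
        return {
            "n": int(w.size),
            "min": float(qs[0]),
            "q25": float(qs[1]),
            "median": float(qs[2]),
            "q75": float(qs[3]),
            "p98": float(qs[4]),
            "max": float(qs[5]),
            "truncated_at": self.truncated_at,
        }


def compute_ipw_weights(ps: np.ndarray, treated: np.ndarray) -> WeightVector:
    """Inverse-probability weights from fitted propensity scores.

    Untreated individuals get w = 1/(1-PS); treated individuals get
    w = 1/PS (the inverse probability of the treatment they actually
    received), which the IPW-only strategy uses. Exclusion-based
    strategies subsequently drop treated individuals via the mask.

    Raises
    ------
    PositivityError
        If any untreated individual has PS = 1 (infinite weight), or any
        treated individual has PS = 0.
    """
    ps = np.asarray(ps, dtype=float)
    tr = np.asarray(treated, dtype=bool)
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("propensity scores must lie in [0, 1]")
    bad_untreated = (~tr) & (ps >= 1.0)
    if np.any(bad_untreated):
        i = int(np.argmax(bad_untreated))
        raise PositivityError(
            f"untreated individual {i} has PS = {ps[i]}: weight 1/(1-PS) is infinite",
            ps=float(ps[i]),
        )
    bad_treated = tr & (ps <= 0.0)
    if np.any(bad_treated):
        i = int(np.argmax(bad_treated))
        raise PositivityError(
            f"treated individual {i} has PS = {ps[i]}: weight 1/PS is infinite",
            ps=float(ps[i]),
        )
    w = np.where(tr, 1.0 / np.where(tr, ps, 1.0), 1.0 / (1.0 - np.where(tr, 0.0, ps)))
    return WeightVector(weights=w, mask=np.ones_like(tr, dtype=bool))


def truncate_weights(wv: WeightVector, percentile: float = 98.0) -> WeightVector:
    """Cap weights at a percentile of the masked weight distribution.

    The percentile is computed over the individuals entering the analysis
    (i.e. after any exclusion), and every masked weight above it is set to
    that percentile value. Truncation never increases a weight;
    percentile 100 is the identity.
    """
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    w = wv.masked_weights
    if w.size == 0:
        raise ValueError("cannot truncate an empty masked weight set")
    cap = float(np.percentile(w, percentile))
    new = wv.weights.copy()
    new[wv.mask] = np.minimum(w, cap)
    return WeightVector(weights=new, mask=wv.mask, truncated_at=percentile)


def weight_diagnostics(ps: np.ndarray, wv: WeightVector):
    """Per-individual diagnostics table: PS, weight, analysis-mask flag."""
    import pandas as pd

    ps = np.asarray(ps, dtype=float)
    if ps.shape != wv.weights.shape:
        raise ValueError("ps and weights must share shape")
    return pd.DataFrame(
        {
            "id": np.arange(ps.size),
            "ps": ps,
            "weight": wv.weights,
            "in_analysis": wv.mask,
        }
    )
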