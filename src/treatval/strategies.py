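"""Validation-analysis strategies for a (model, partially treated cohort) pair.

Six strategies make up the core comparison:

``reference_untreated``
    Counterfactual benchmark: all individuals, untreated outcomes. Only
    available in simulation; the performance the model would show in the
    untreated target population.
``ignore``
    All individuals, observed outcomes, unit weights — treatment ignored.
``exclude``
    Untreated subset only, unit weights.
``ipw``
    All individuals, weighted by the inverse probability of the treatment
    actually received (1/PS treated, 1/(1-PS) untreated).
``ipw_exclude``
    Untreated subset weighted by 1/(1-PS).
``ipw_trunc_exclude``
    As ``ipw_exclude``, weights truncated at a percentile (default 98th).

Two further strategies, ``recalibrate`` (intercept re-estimation) and
``model_treatment`` (treatment-indicator refit), are implemented but
labelled non-recommended: they adjust for case-mix along with treatment
and can misrepresent the original model's calibration. They are only run
when explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohorts import Cohort
from .errors import FittingError, PositivityError, UndefinedMetricError
from .fitting import (
    PrognosticModel,
    PropensityModel,
    fit_propensity_model,
    recalibrate_intercept,
    refit_with_treatment,
)
from .metrics import PerformanceEstimate, calibration_curve, weighted_c_index, weighted_oe_ratio
from .weighting import WeightVector, compute_ipw_weights, truncate_weights

__all__ = [
    "STRATEGIES",
    "CORE_STRATEGIES",
    "NON_RECOMMENDED",
    "StrategyOptions",
    "StrategyResult",
    "evaluate_strategy",
    "evaluate_strategies",
]

CORE_STRATEGIES = (
    "reference_untreated",
    "ignore",
    "exclude",
    "ipw",
    "ipw_exclude",
    "ipw_trunc_exclude",
)
NON_RECOMMENDED = ("recalibrate", "model_treatment")
STRATEGIES = CORE_STRATEGIES + NON_RECOMMENDED

_IPW_STRATEGIES = {"ipw", "ipw_exclude", "ipw_trunc_exclude"}


@dataclass(frozen=True)
class StrategyOptions:
    """Knobs shared by the strategies.

    truncation_percentile: weight-truncation percentile for
    ``ipw_trunc_exclude`` (the percentile is computed among the
    individuals entering the analysis, i.e. after exclusion).
    propensity_covariates: "predicted_risk" (default) or "raw_predictors".
    model_treatment_variant: "treatment_offset" or "treatment_refit".
    """

    truncation_percentile: float = 98.0
    propensity_covariates: str = "predicted_risk"
    with_curve: bool = False
    curve_bins: int = 10
    model_treatment_variant: str = "treatment_offset"


@dataclass
class StrategyResult:
    """Outcome of one strategy on one validation cohort."""

    strategy: str
    estimate: PerformanceEstimate
    n_analyzed: int
    weight_summary: dict = field(default_factory=dict)
    non_recommended: bool = False


def _analysis_arrays(
    strategy: str,
    model: PrognosticModel,
    val: Cohort,
    options: StrategyOptions,
    ps: np.ndarray | None,
):
    """Return (pred, y, weights, mask) defining the strategy's estimator."""
    pred = model.predict(val)
    untreated = np.asarray(val.treated, dtype=bool) == False  # noqa: E712
    ones = np.ones(len(val))
    all_mask = np.ones(len(val), dtype=bool)
    if strategy == "reference_untreated":
        return pred, val.y_untreated, WeightVector(ones, all_mask)
    if strategy == "ignore":
        return pred, val.y_observed, WeightVector(ones, all_mask)
    if strategy == "exclude":
        return pred, val.y_observed, WeightVector(ones, untreated)
    if strategy in _IPW_STRATEGIES:
        wv = compute_ipw_weights(ps, val.treated)
        if strategy == "ipw":
            return pred, val.y_observed, wv
        wv = wv.restrict(untreated)
        if strategy == "ipw_trunc_exclude":
            wv = truncate_weights(wv, options.truncation_percentile)
        return pred, val.y_observed, wv
    if strategy == "recalibrate":
        updated = recalibrate_intercept(model, val)
        return updated.predict(val), val.y_observed, WeightVector(ones, all_mask)
    if strategy == "model_treatment":
        updated = refit_with_treatment(model, val, options.model_treatment_variant)
        return updated.predict(val), val.y_observed, WeightVector(ones, all_mask)
    raise ValueError(f"unknown strategy {strategy!r}; known: {', '.join(STRATEGIES)}")


def _estimate(pred, y, wv: WeightVector, options: StrategyOptions) -> PerformanceEstimate:
    m = wv.mask
    p, yy, w = np.asarray(pred)[m], np.asarray(y)[m], wv.masked_weights
    flags: list[str] = []
    try:
        c = weighted_c_index(p, yy, w)
    except UndefinedMetricError:
        c = np.nan
        flags.append("c_index_undefined")
    try:
        oe = weighted_oe_ratio(p, yy, w)
        if float(w @ yy) == 0:
            flags.append("zero_weighted_events")
    except UndefinedMetricError:
        oe = np.nan
        flags.append("oe_undefined")
    curve = None
    if options.with_curve:
        try:
            curve = calibration_curve(p, yy, w, bins=options.curve_bins)
        except UndefinedMetricError:
            flags.append("curve_undefined")
    return PerformanceEstimate(
        c_index=c,
        oe_ratio=oe,
        n_effective=int(m.sum()),
        calibration_curve=curve,
        flags=tuple(flags),
    )


def _flagged(strategy: str, flag: str) -> StrategyResult:
    est = PerformanceEstimate(c_index=np.nan, oe_ratio=np.nan, n_effective=0, flags=(flag,))
    return StrategyResult(strategy, est, 0, non_recommended=strategy in NON_RECOMMENDED)


def strategy_arrays(
    model: PrognosticModel,
    val: Cohort,
    strategy: str,
    options: StrategyOptions = StrategyOptions(),
    propensity: PropensityModel | None = None,
):
    """The (pred, y, weights) triple a strategy's estimator runs on.

    Arrays are restricted to the analysis mask. Used for pooling
    individual-level rows across replicates (calibration curves).
    """
    ps = None
    if strategy in _IPW_STRATEGIES:
        if propensity is None:
            propensity = fit_propensity_model(val, model, options.propensity_covariates)
        ps = propensity.predict(val, model)
    pred, y, wv = _analysis_arrays(strategy, model, val, options, ps)
    m = wv.mask
    return np.asarray(pred)[m], np.asarray(y)[m], wv.masked_weights


def evaluate_strategies(
    model: PrognosticModel,
    val: Cohort,
    strategies=CORE_STRATEGIES,
    options: StrategyOptions = StrategyOptions(),
    propensity: PropensityModel | None = None,
) -> list[StrategyResult]:
    """Evaluate several strategies, fitting the propensity model once.

    The propensity model (when any IPW strategy is requested and none is
    supplied) is fitted on the full validation cohort and shared across
    the IPW variants: fit PS, compute weights, exclude, truncate, in that
    order. Strategy-level failures (degenerate analysis sets, propensity
    fit failure) are returned as flagged results, not raised.
    """
    strategies = list(strategies)
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}; known: {', '.join(STRATEGIES)}")
    ps = None
    ps_error = None
    if _IPW_STRATEGIES & set(strategies):
        try:
            if propensity is None:
                propensity = fit_propensity_model(val, model, options.propensity_covariates)
            ps = propensity.predict(val, model)
        except FittingError as e:
            ps_error = f"propensity_fit_failed:{type(e).__name__}"

    results = []
    for s in strategies:
        if s in _IPW_STRATEGIES and ps_error is not None:
            results.append(_flagged(s, ps_error))
            continue
        try:
            pred, y, wv = _analysis_arrays(s, model, val, options, ps)
        except (FittingError, PositivityError) as e:
            results.append(_flagged(s, f"strategy_failed:{type(e).__name__}"))
            continue
        est = _estimate(pred, y, wv, options)
        results.append(
            StrategyResult(
                strategy=s,
                estimate=est,
                n_analyzed=est.n_effective,
                weight_summary=wv.summary(),
                non_recommended=s in NON_RECOMMENDED,
            )
        )
    return results


def evaluate_strategy(
    model: PrognosticModel,
    val: Cohort,
    strategy: str,
    options: StrategyOptions = StrategyOptions(),
    propensity: PropensityModel | None = None,
) -> StrategyResult:
    """Evaluate a single strategy (convenience wrapper)."""
    return evaluate_strategies(model, val, [strategy], options, propensity)[0]
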