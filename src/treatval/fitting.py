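"""Logistic model fitting: the prognostic model, the treatment-propensity
model, and the model-updating procedures (intercept recalibration and
treatment-indicator refits).

All fits go through one maximum-likelihood kernel (:func:`fit_logistic`,
IRLS via statsmodels GLM with a binomial family), with a shared
convergence contract and structured errors for degenerate outcomes and
separation.

The updating procedures are implemented for completeness but are *not
recommended*: recalibration and treatment-indicator refits adjust for
case-mix differences along with treatment, and can mask mis-calibration
of the original model. Downstream strategy output labels them
accordingly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohorts import Cohort
from .errors import DegenerateOutcomeError, FittingError, SeparationError

__all__ = [
    "fit_logistic",
    "PrognosticModel",
    "PropensityModel",
    "UpdatedModel",
    "develop_prognostic_model",
    "predict_untreated_risk",
    "fit_propensity_model",
    "recalibrate_intercept",
    "refit_with_treatment",
    "save_model",
    "load_model",
]

#: Relative convergence tolerance and iteration cap of the IRLS kernel.
DEFAULT_TOL = 1e-8
DEFAULT_MAXITER = 100


def fit_logistic(
    y: np.ndarray,
    covariates: np.ndarray | None,
    offset: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
) -> np.ndarray:
    """Maximum-likelihood logistic regression with an implicit intercept.

    Parameters
    ----------
    y : binary vector
    covariates : (n, k) matrix or None
        Covariate columns; an intercept column is always prepended. None
        or k=0 fits an intercept-only model.
    offset : vector, optional
        Fixed additive term on the linear-predictor scale.

    Returns
    -------
    ndarray of length k+1: (intercept, coefficients...).

    Raises
    ------
    DegenerateOutcomeError
        If the outcome is all-zero or all-one.
    SeparationError
        If the data are (quasi-)completely separated, so the MLE diverges.
    FittingError
        On non-convergence within ``maxiter`` iterations, or a constant
        covariate column.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")
    if y.sum() == 0 or y.sum() == n:
        raise DegenerateOutcomeError(
            f"outcome is constant ({int(y[0])} for all {n} rows); logistic fit undefined"
        )
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        for j in range(covariates.shape[1]):
            if np.ptp(covariates[:, j]) == 0:
                raise FittingError(f"covariate column {j} is constant; drop it (intercept is implicit)")
        X = np.column_stack([np.ones(n), covariates])

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
        try:
            res = model.fit(maxiter=maxiter, tol=tol)
        except Exception as e:  # statsmodels raises on hard numerical failure
            raise FittingError(f"logistic fit failed: {e}") from e
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise SeparationError(
            "complete or quasi-complete separation detected; MLE does not exist",
            iterations=int(getattr(res, "fit_history", {}).get("iteration", maxiter)),
        )
    if not res.converged:
        raise FittingError(
            f"IRLS did not converge within {maxiter} iterations (tol={tol})",
            iterations=maxiter,
        )
    return np.asarray(res.params)


# ---------------------------------------------------------------------------
# Fitted-model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrognosticModel:
    """Two-predictor logistic prognostic model for untreated risk.

    The linear predictor LP0 = intercept + coef_x1*X1 + coef_x2*X2; the
    unobserved predictor U is never included.
    """

    intercept: float
    coef_x1: float
    coef_x2: float
    fitted_on: str = ""

    def linear_predictor(self, cohort: Cohort) -> np.ndarray:
        return self.intercept + self.coef_x1 * cohort.x1 + self.coef_x2 * cohort.x2

    def predict(self, cohort: Cohort) -> np.ndarray:
        return expit(self.linear_predictor(cohort))


@dataclass(frozen=True)
class PropensityModel:
    """Logistic model for the probability of receiving treatment.

    ``covariate_set`` is "predicted_risk" (single covariate: the
    prognostic model's predicted untreated risk — the default, matching a
    generating allocation that is logistic in risk) or "raw_predictors"
    (X1 and X2 entered linearly).
    """

    coefficients: tuple[float, ...]
    covariate_set: str = "predicted_risk"

    def predict(self, cohort: Cohort, model: PrognosticModel) -> np.ndarray:
        Xcols = _propensity_covariates(cohort, model, self.covariate_set)
        lp = self.coefficients[0] + Xcols @ np.asarray(self.coefficients[1:])
        return expit(lp)


@dataclass(frozen=True)
class UpdatedModel:
    """A prognostic model updated on the validation set.

    variant "recalibrated": LP1 = gamma_0 + LP0 (method: intercept-only
    refit with LP0 as offset). variant "treatment_offset": LP2 = gamma_0 +
    LP0 + gamma_tr*Tr. variant "treatment_refit": LP3 = gamma_0 +
    g1*X1 + g2*X2 + gamma_tr*Tr (full refit).
    """

    base: PrognosticModel
    variant: str
    gamma_0: float
    gamma_tr: float | None = None
    refit_coefs: tuple[float, float] | None = None

    def linear_predictor(self, cohort: Cohort) -> np.ndarray:
        if self.variant == "recalibrated":
            return self.gamma_0 + self.base.linear_predictor(cohort)
        if self.variant == "treatment_offset":
            return self.gamma_0 + self.base.linear_predictor(cohort) + self.gamma_tr * cohort.treated
        if self.variant == "treatment_refit":
            g1, g2 = self.refit_coefs
            return self.gamma_0 + g1 * cohort.x1 + g2 * cohort.x2 + self.gamma_tr * cohort.treated
        raise ValueError(f"unknown variant {self.variant!r}")

    def predict(self, cohort: Cohort) -> np.ndarray:
        return expit(self.linear_predictor(cohort))


# ---------------------------------------------------------------------------
# Fitting front-ends
# ---------------------------------------------------------------------------


def develop_prognostic_model(dev: Cohort) -> PrognosticModel:
    """Fit the two-predictor prognostic model on an untreated development cohort."""
    if dev.n_treated != 0:
        raise ValueError(
            "development cohort must be fully untreated; "
            f"{dev.n_treated} treated individuals present"
        )
    params = fit_logistic(dev.y_untreated, np.column_stack([dev.x1, dev.x2]))
    return PrognosticModel(*params, fitted_on=dev.scenario_id or "development")


def predict_untreated_risk(model: PrognosticModel, cohort: Cohort) -> np.ndarray:
    """Predicted untreated risk: expit(LP0) per individual."""
    return model.predict(cohort)


def _propensity_covariates(cohort: Cohort, model: PrognosticModel, covariate_set: str) -> np.ndarray:
    if covariate_set == "predicted_risk":
        return model.predict(cohort)[:, None]
    if covariate_set == "raw_predictors":
        return np.column_stack([cohort.x1, cohort.x2])
    raise ValueError(f"unknown covariate_set {covariate_set!r}")


def fit_propensity_model(
    val: Cohort, model: PrognosticModel, covariate_set: str = "predicted_risk"
) -> PropensityModel:
    """Fit the treatment-propensity model on the validation cohort.

    The unobserved predictor U is, by construction, never available to
    this model; under scenarios with a strong U it is an unmeasured
    confounder of treatment and outcome.
    """
    tr = np.asarray(val.treated, dtype=float)
    if tr.sum() == 0 or tr.sum() == len(tr):
        raise DegenerateOutcomeError(
            "propensity fit needs both treated and untreated individuals"
        )
    X = _propensity_covariates(val, model, covariate_set)
    params = fit_logistic(tr, X)
    return PropensityModel(tuple(params), covariate_set=covariate_set)


def recalibrate_intercept(model: PrognosticModel, val: Cohort) -> UpdatedModel:
    """Re-estimate the intercept on the full validation set (LP0 as offset).

    By the logistic score equation the recalibrated model's mean predicted
    risk equals the observed outcome incidence in the validation set.
    """
    lp0 = model.linear_predictor(val)
    params = fit_logistic(val.y_observed, None, offset=lp0)
    return UpdatedModel(base=model, variant="recalibrated", gamma_0=float(params[0]))


def refit_with_treatment(
    model: PrognosticModel, val: Cohort, variant: str = "treatment_offset"
) -> UpdatedModel:
    """Update the model with a treatment-use indicator.

    variant "treatment_offset" keeps the original coefficients fixed
    (LP0 enters as offset); "treatment_refit" re-estimates everything.
    """
    tr = np.asarray(val.treated, dtype=float)
    if tr.sum() == 0 or tr.sum() == len(tr):
        raise DegenerateOutcomeError("treatment indicator is constant in the validation set")
    if variant == "treatment_offset":
        params = fit_logistic(val.y_observed, tr[:, None], offset=model.linear_predictor(val))
        return UpdatedModel(
            base=model, variant=variant, gamma_0=float(params[0]), gamma_tr=float(params[1])
        )
    if variant == "treatment_refit":
        X = np.column_stack([val.x1, val.x2, tr])
        params = fit_logistic(val.y_observed, X)
        return UpdatedModel(
            base=model,
            variant=variant,
            gamma_0=float(params[0]),
            gamma_tr=float(params[3]),
            refit_coefs=(float(params[1]), float(params[2])),
        )
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Serialization: small keyed text (JSON) for exact reuse across runs
# ---------------------------------------------------------------------------


def save_model(model, path: str | Path) -> None:
    if isinstance(model, PrognosticModel):
        doc = {
            "kind": "prognostic",
            "intercept": model.intercept,
            "coef_x1": model.coef_x1,
            "coef_x2": model.coef_x2,
            "fitted_on": model.fitted_on,
        }
    elif isinstance(model, PropensityModel):
        doc = {
            "kind": "propensity",
            "coefficients": list(model.coefficients),
            "covariate_set": model.covariate_set,
        }
    elif isinstance(model, UpdatedModel):
        doc = {
            "kind": "updated",
            "variant": model.variant,
            "gamma_0": model.gamma_0,
            "gamma_tr": model.gamma_tr,
            "refit_coefs": list(model.refit_coefs) if model.refit_coefs else None,
            "base": {
                "intercept": model.base.intercept,
                "coef_x1": model.base.coef_x1,
                "coef_x2": model.base.coef_x2,
                "fitted_on": model.base.fitted_on,
            },
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    doc = json.loads(Path(path).read_text())
    kind = doc.pop("kind", None)
    if kind == "prognostic":
        return PrognosticModel(**doc)
    if kind == "propensity":
        doc["coefficients"] = tuple(doc["coefficients"])
        return PropensityModel(**doc)
    if kind == "updated":
        base = PrognosticModel(**doc.pop("base"))
        rc = doc.pop("refit_coefs")
        return UpdatedModel(base=base, refit_coefs=tuple(rc) if rc else None, **doc)
    raise ValueError(f"unknown model kind {kind!r} in {path}")
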