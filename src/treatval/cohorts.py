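"""Synthetic cohort generation.

Each individual has three independent mean-zero normal predictors (X1, X2
observed; U unobserved by the analyst), a true untreated outcome risk from
the scenario's logistic generating model, a treatment indicator drawn from
the allocation model, a post-treatment ("observed") risk obtained by
multiplying the outcome odds of treated individuals by the treatment odds
ratio, and two binary outcomes: the counterfactual untreated outcome and
the outcome actually observed.

Both potential outcomes are drawn from one shared uniform deviate per
individual, so a risk-lowering treatment can only switch an outcome from
1 to 0, never the reverse. Marginal outcome distributions are unaffected
by this coupling; independent redraws are available via
``couple_outcomes=False``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError
from .scenarios import (
    AllocationModelSpec,
    OutcomeModelSpec,
    ScenarioConfig,
    TreatmentEffectSpec,
)

__all__ = [
    "RngState",
    "Cohort",
    "draw_predictors",
    "compute_untreated_risk",
    "allocate_treatment",
    "treatment_odds_ratio",
    "apply_treatment_effect",
    "draw_outcomes",
    "generate_cohort",
    "generate_validation_pair",
]

#: Fixed column order of the delimited cohort export.
EXPORT_COLUMNS = [
    "id",
    "x1",
    "x2",
    "u",
    "risk_untreated",
    "treated",
    "risk_observed",
    "y_untreated",
    "y_observed",
]


@dataclass(frozen=True)
class RngState:
    """A labelled, reproducible random stream.

    The same (seed, label) pair always yields the same stream; distinct
    labels derived from one seed are statistically independent. Labels are
    hierarchical strings, e.g. ``"scenario_1/rep42/val"``.
    """

    seed: int
    label: str = ""

    def child(self, suffix: str) -> "RngState":
        label = f"{self.label}/{suffix}" if self.label else suffix
        return RngState(self.seed, label)

    def generator(self) -> np.random.Generator:
        key = zlib.crc32(self.label.encode())
        return np.random.Generator(np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(key,))))


@dataclass
class Cohort:
    """Individual-level arrays for one simulated data set."""

    x1: np.ndarray
    x2: np.ndarray
    u: np.ndarray
    risk_untreated: np.ndarray
    treated: np.ndarray
    risk_observed: np.ndarray
    y_untreated: np.ndarray
    y_observed: np.ndarray
    scenario_id: str = field(default="")

    def __post_init__(self):
        n = len(self.x1)
        for name in ("x2", "u", "risk_untreated", "treated", "risk_observed", "y_untreated", "y_observed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"cohort arrays must share length; '{name}' differs")

    def __len__(self) -> int:
        return len(self.x1)

    @property
    def n_treated(self) -> int:
        return int(self.treated.sum())

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row subset (boolean mask), preserving all columns."""
        return Cohort(
            *(getattr(self, c)[mask] for c in EXPORT_COLUMNS[1:]),
            scenario_id=self.scenario_id,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in EXPORT_COLUMNS[1:]})
        df.insert(0, "id", np.arange(len(df)))
        return df

    def to_csv(self, path) -> None:
        """Delimited export with the fixed column header."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scenario_id: str = "") -> "Cohort":
        missing = [c for c in EXPORT_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ConfigError(f"cohort table missing column(s): {missing}")
        return cls(
            *(df[c].to_numpy(dtype=float if c not in ("treated", "y_untreated", "y_observed") else int)
              for c in EXPORT_COLUMNS[1:]),
            scenario_id=scenario_id,
        )


def draw_predictors(n: int, predictor_sd: float, rng: RngState):
    """Draw the three independent normal predictor vectors X1, X2, U."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if predictor_sd <= 0:
        raise ValueError(f"predictor_sd must be > 0, got {predictor_sd}")
    g = rng.generator()
    x = g.normal(0.0, predictor_sd, size=(3, n))
    return x[0], x[1], x[2]


def compute_untreated_risk(x1, x2, u, outcome_model: OutcomeModelSpec) -> np.ndarray:
    """True untreated outcome risk from the logistic generating model."""
    lp = (
        outcome_model.intercept
        + outcome_model.beta_x1 * np.asarray(x1)
        + outcome_model.beta_x2 * np.asarray(x2)
        + outcome_model.beta_u * np.asarray(u)
    )
    return expit(lp)


def allocation_probability(risk_untreated: np.ndarray, allocation: AllocationModelSpec) -> np.ndarray:
    """Per-individual probability of receiving treatment."""
    risk = np.asarray(risk_untreated, dtype=float)
    if allocation.mode == "random":
        return np.full(risk.shape, allocation.p_fixed)
    return expit(allocation.b * risk - allocation.a)


def allocate_treatment(risk_untreated, allocation: AllocationModelSpec, rng: RngState) -> np.ndarray:
    """Bernoulli treatment indicator; probability may depend on true risk."""
    p = allocation_probability(risk_untreated, allocation)
    g = rng.generator()
    return (g.random(p.shape) < p).astype(np.int8)


def treatment_odds_ratio(risk_untreated, effect: TreatmentEffectSpec) -> np.ndarray:
    """The odds ratio applied to treated individuals, possibly risk-dependent."""
    risk = np.asarray(risk_untreated, dtype=float)
    if effect.mode == "constant":
        return np.full(risk.shape, effect.or_constant)
    return expit(-(effect.c + effect.d * risk))


def apply_treatment_effect(risk_untreated, treated, effect: TreatmentEffectSpec) -> np.ndarray:
    """Post-treatment risk: treated odds are multiplied by the effect OR.

    risk_observed = expit(logit(risk) + log(OR)) for treated individuals;
    untreated risks pass through unchanged.
    """
    risk = np.asarray(risk_untreated, dtype=float)
    if np.any(risk <= 0) or np.any(risk >= 1):
        raise ValueError("risks must lie strictly in (0, 1)")
    orr = treatment_odds_ratio(risk, effect)
    if np.any(orr <= 0):
        raise ValueError("treatment odds ratio must be > 0")
    treated = np.asarray(treated, dtype=bool)
    out = risk.copy()
    out[treated] = expit(logit(risk[treated]) + np.log(orr[treated]))
    return out


def draw_outcomes(risk_untreated, risk_observed, rng: RngState, couple: bool = True):
    """Draw (y_untreated, y_observed).

    With ``couple=True`` (default) one uniform deviate per individual
    thresholds both risks, so the two potential outcomes are monotonically
    coupled; otherwise they are drawn independently.
    """
    g = rng.generator()
    ru = np.asarray(risk_untreated, dtype=float)
    ro = np.asarray(risk_observed, dtype=float)
    udev = g.random(ru.shape)
    y_untreated = (udev < ru).astype(np.int8)
    if couple:
        y_observed = (udev < ro).astype(np.int8)
    else:
        y_observed = (g.random(ro.shape) < ro).astype(np.int8)
    return y_untreated, y_observed


def generate_cohort(
    config: ScenarioConfig,
    rng: RngState,
    treated: bool = True,
    n: int | None = None,
    couple_outcomes: bool = True,
) -> Cohort:
    """Generate one cohort under a scenario.

    With ``treated=False`` (a development set) no one receives treatment
    and observed quantities equal their untreated counterparts.
    """
    if n is None:
        n = config.n_val if treated else config.n_dev
    x1, x2, u = draw_predictors(n, config.predictor_sd, rng.child("predictors"))
    risk = compute_untreated_risk(x1, x2, u, config.outcome_model)
    if treated:
        tr = allocate_treatment(risk, config.allocation, rng.child("allocation"))
    else:
        tr = np.zeros(n, dtype=np.int8)
    risk_obs = apply_treatment_effect(risk, tr, config.effect)
    y_unt, y_obs = draw_outcomes(risk, risk_obs, rng.child("outcomes"), couple=couple_outcomes)
    return Cohort(x1, x2, u, risk, tr, risk_obs, y_unt, y_obs, scenario_id=config.id)


def generate_validation_pair(
    config: ScenarioConfig, rng: RngState, couple_outcomes: bool = True
) -> tuple[Cohort, Cohort]:
    """One untreated development cohort and one partially treated validation cohort."""
    dev = generate_cohort(config, rng.child("dev"), treated=False, couple_outcomes=couple_outcomes)
    val = generate_cohort(config, rng.child("val"), treated=True, couple_outcomes=couple_outcomes)
    return dev, val
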