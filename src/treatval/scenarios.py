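"""Scenario configurations for the simulation engine.

A scenario describes one simulated world: the logistic data-generating
model for the binary outcome (two observed predictors X1, X2 and an
optional unobserved predictor U), the treatment-allocation model (random,
or logistic in the true untreated risk), the treatment-effect model (a
constant odds ratio, or an odds ratio that varies with risk), and the
development / validation sample sizes.

Fifteen built-in scenarios are provided covering: risk-dependent and
random allocation, a near-deterministic risk-threshold allocation
(positivity violation), treatment effects from weak (OR 0.8) to strong
(OR 0.3), treated fractions of 25/50/75%, and an unobserved predictor of
increasing strength (coefficients 1, 2, 4). Scenario 1 is the default;
the others override individual components of it.

Configs round-trip through a flat keyed YAML format, one mapping per
scenario id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = [
    "OutcomeModelSpec",
    "AllocationModelSpec",
    "TreatmentEffectSpec",
    "ScenarioConfig",
    "builtin_scenario",
    "builtin_scenario_names",
    "load_scenarios",
    "save_scenarios",
]

#: Predictors are mean-zero normal with variance 0.2; configs carry the SD.
DEFAULT_PREDICTOR_SD = math.sqrt(0.2)


def _require_finite(name: str, value: float) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"field '{name}' must be a real number, got {value!r}")
    if not math.isfinite(v):
        raise ConfigError(f"field '{name}' must be finite, got {value!r}")
    return v


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Logistic outcome model: logit P(Y=1) = intercept + b1*X1 + b2*X2 + bu*U."""

    intercept: float
    beta_x1: float
    beta_x2: float
    beta_u: float

    def __post_init__(self):
        for f in ("intercept", "beta_x1", "beta_x2", "beta_u"):
            object.__setattr__(self, f, _require_finite(f, getattr(self, f)))


@dataclass(frozen=True)
class AllocationModelSpec:
    """Treatment-allocation model.

    mode "random": every individual is treated with probability ``p_fixed``.
    mode "risk_logistic": P(Tr) = expit(b * Risk - a), i.e. the printed
    form 1 / (1 + exp(a - b * Risk)) with the untreated risk as input.
    """

    mode: str
    p_fixed: float = 0.5
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.mode not in ("random", "risk_logistic"):
            raise ConfigError(
                f"field 'allocation_mode' must be 'random' or 'risk_logistic', got {self.mode!r}"
            )
        object.__setattr__(self, "p_fixed", _require_finite("p_fixed", self.p_fixed))
        object.__setattr__(self, "a", _require_finite("allocation_a", self.a))
        object.__setattr__(self, "b", _require_finite("allocation_b", self.b))
        if self.mode == "random" and not 0.0 <= self.p_fixed <= 1.0:
            raise ConfigError(f"field 'p_fixed' must be in [0, 1], got {self.p_fixed}")


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """Treatment-effect model on the odds scale.

    mode "constant": every treated individual's outcome odds are multiplied
    by ``or_constant``.
    mode "risk_dependent": OR(Risk) = 1 / (1 + exp(c + d * Risk)), so the
    effect strengthens or weakens with the untreated risk.
    """

    mode: str
    or_constant: float = 1.0
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self):
        if self.mode not in ("constant", "risk_dependent"):
            raise ConfigError(
                f"field 'effect_mode' must be 'constant' or 'risk_dependent', got {self.mode!r}"
            )
        object.__setattr__(self, "or_constant", _require_finite("or_constant", self.or_constant))
        object.__setattr__(self, "c", _require_finite("effect_c", self.c))
        object.__setattr__(self, "d", _require_finite("effect_d", self.d))
        if self.mode == "constant" and self.or_constant <= 0:
            raise ConfigError(f"field 'or_constant' must be > 0, got {self.or_constant}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulated world."""

    id: str
    outcome_model: OutcomeModelSpec
    allocation: AllocationModelSpec
    effect: TreatmentEffectSpec
    n_dev: int = 1000
    n_val: int = 1000
    predictor_sd: float = DEFAULT_PREDICTOR_SD
    #: Expected fraction treated in the validation set. Documentation only:
    #: it is an emergent property of the allocation model, checked
    #: empirically in tests, never enforced.
    target_treated_fraction: float = field(default=0.5)

    def __post_init__(self):
        if not isinstance(self.id, str) or not self.id:
            raise ConfigError("field 'id' must be a non-empty string")
        for f in ("n_dev", "n_val"):
            v = getattr(self, f)
            if not isinstance(v, int) or isinstance(v, bool) or v < 1:
                raise ConfigError(f"field '{f}' must be an integer >= 1, got {v!r}")
        object.__setattr__(
            self, "predictor_sd", _require_finite("predictor_sd", self.predictor_sd)
        )
        if self.predictor_sd <= 0:
            raise ConfigError(f"field 'predictor_sd' must be > 0, got {self.predictor_sd}")
        tf = _require_finite("target_treated_fraction", self.target_treated_fraction)
        if not 0.0 <= tf <= 1.0:
            raise ConfigError(f"field 'target_treated_fraction' must be in [0, 1], got {tf}")
        object.__setattr__(self, "target_treated_fraction", tf)


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

_DEFAULT = ScenarioConfig(
    id="scenario_1",
    outcome_model=OutcomeModelSpec(intercept=-1.50, beta_x1=1.0, beta_x2=1.0, beta_u=0.0),
    allocation=AllocationModelSpec(mode="risk_logistic", a=1.95, b=10.0),
    effect=TreatmentEffectSpec(mode="constant", or_constant=0.5),
    n_dev=1000,
    n_val=1000,
    target_treated_fraction=0.50,
)


def _variant(n: int, **overrides) -> ScenarioConfig:
    return replace(_DEFAULT, id=f"scenario_{n}", **overrides)


_BUILTINS: dict[str, ScenarioConfig] = {
    c.id: c
    for c in [
        _DEFAULT,
        _variant(2, allocation=AllocationModelSpec(mode="random", p_fixed=0.50)),
        _variant(3, effect=TreatmentEffectSpec(mode="risk_dependent", c=-1.0, d=5.0)),
        _variant(4, allocation=AllocationModelSpec(mode="risk_logistic", a=18.0, b=100.0)),
        _variant(
            5,
            allocation=AllocationModelSpec(mode="risk_logistic", a=3.30, b=10.0),
            effect=TreatmentEffectSpec(mode="constant", or_constant=0.3),
            target_treated_fraction=0.25,
        ),
        _variant(
            6,
            allocation=AllocationModelSpec(mode="risk_logistic", a=3.30, b=10.0),
            target_treated_fraction=0.25,
        ),
        _variant(
            7,
            allocation=AllocationModelSpec(mode="risk_logistic", a=3.30, b=10.0),
            effect=TreatmentEffectSpec(mode="constant", or_constant=0.8),
            target_treated_fraction=0.25,
        ),
        _variant(8, effect=TreatmentEffectSpec(mode="constant", or_constant=0.3)),
        _variant(9, effect=TreatmentEffectSpec(mode="constant", or_constant=0.8)),
        _variant(
            10,
            allocation=AllocationModelSpec(mode="risk_logistic", a=0.70, b=10.0),
            effect=TreatmentEffectSpec(mode="constant", or_constant=0.3),
            target_treated_fraction=0.75,
        ),
        _variant(
            11,
            allocation=AllocationModelSpec(mode="risk_logistic", a=0.70, b=10.0),
            target_treated_fraction=0.75,
        ),
        _variant(
            12,
            allocation=AllocationModelSpec(mode="risk_logistic", a=0.70, b=10.0),
            effect=TreatmentEffectSpec(mode="constant", or_constant=0.8),
            target_treated_fraction=0.75,
        ),
        _variant(
            13,
            outcome_model=OutcomeModelSpec(intercept=-1.55, beta_x1=1.0, beta_x2=1.0, beta_u=1.0),
            allocation=AllocationModelSpec(mode="risk_logistic", a=1.90, b=10.0),
        ),
        _variant(
            14,
            outcome_model=OutcomeModelSpec(intercept=-1.70, beta_x1=1.0, beta_x2=1.0, beta_u=2.0),
            allocation=AllocationModelSpec(mode="risk_logistic", a=1.80, b=10.0),
        ),
        _variant(
            15,
            outcome_model=OutcomeModelSpec(intercept=-2.15, beta_x1=1.0, beta_x2=1.0, beta_u=4.0),
            allocation=AllocationModelSpec(mode="risk_logistic", a=1.55, b=10.0),
        ),
    ]
}


def builtin_scenario_names() -> list[str]:
    """Ids of the built-in scenarios, in order."""
    return list(_BUILTINS)


def builtin_scenario(name: str) -> ScenarioConfig:
    """Return a built-in scenario by id (e.g. ``"scenario_1"``)."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ConfigError(
            f"unknown built-in scenario {name!r}; available: {', '.join(_BUILTINS)}"
        ) from None


# ---------------------------------------------------------------------------
# File I/O: flat keyed YAML, one mapping per scenario id
# ---------------------------------------------------------------------------

_SCALAR_KEYS = {
    "outcome_intercept",
    "outcome_beta_x1",
    "outcome_beta_x2",
    "outcome_beta_u",
    "allocation_mode",
    "p_fixed",
    "allocation_a",
    "allocation_b",
    "effect_mode",
    "or_constant",
    "effect_c",
    "effect_d",
    "n_dev",
    "n_val",
    "predictor_sd",
    "target_treated_fraction",
}


def _to_flat(cfg: ScenarioConfig) -> dict:
    d = {
        "outcome_intercept": cfg.outcome_model.intercept,
        "outcome_beta_x1": cfg.outcome_model.beta_x1,
        "outcome_beta_x2": cfg.outcome_model.beta_x2,
        "outcome_beta_u": cfg.outcome_model.beta_u,
        "allocation_mode": cfg.allocation.mode,
        "effect_mode": cfg.effect.mode,
        "n_dev": cfg.n_dev,
        "n_val": cfg.n_val,
        "predictor_sd": cfg.predictor_sd,
        "target_treated_fraction": cfg.target_treated_fraction,
    }
    if cfg.allocation.mode == "random":
        d["p_fixed"] = cfg.allocation.p_fixed
    else:
        d["allocation_a"] = cfg.allocation.a
        d["allocation_b"] = cfg.allocation.b
    if cfg.effect.mode == "constant":
        d["or_constant"] = cfg.effect.or_constant
    else:
        d["effect_c"] = cfg.effect.c
        d["effect_d"] = cfg.effect.d
    return d


def _from_flat(scenario_id: str, raw: dict) -> ScenarioConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario {scenario_id!r}: expected a mapping of keys to values")
    unknown = set(raw) - _SCALAR_KEYS
    if unknown:
        raise ConfigError(
            f"scenario {scenario_id!r}: unknown key(s) {sorted(unknown)}; "
            f"allowed keys: {sorted(_SCALAR_KEYS)}"
        )

    def get(key, default=None, required=False):
        if key in raw:
            return raw[key]
        if required:
            raise ConfigError(f"scenario {scenario_id!r}: missing required key '{key}'")
        return default

    outcome = OutcomeModelSpec(
        intercept=get("outcome_intercept", required=True),
        beta_x1=get("outcome_beta_x1", required=True),
        beta_x2=get("outcome_beta_x2", required=True),
        beta_u=get("outcome_beta_u", 0.0),
    )
    mode = get("allocation_mode", required=True)
    if mode == "random":
        allocation = AllocationModelSpec(mode="random", p_fixed=get("p_fixed", required=True))
    else:
        allocation = AllocationModelSpec(
            mode=mode,
            a=get("allocation_a", required=True) if mode == "risk_logistic" else 0.0,
            b=get("allocation_b", required=True) if mode == "risk_logistic" else 0.0,
        )
    emode = get("effect_mode", required=True)
    if emode == "constant":
        effect = TreatmentEffectSpec(mode="constant", or_constant=get("or_constant", required=True))
    else:
        effect = TreatmentEffectSpec(
            mode=emode,
            c=get("effect_c", required=True) if emode == "risk_dependent" else 0.0,
            d=get("effect_d", required=True) if emode == "risk_dependent" else 0.0,
        )
    return ScenarioConfig(
        id=scenario_id,
        outcome_model=outcome,
        allocation=allocation,
        effect=effect,
        n_dev=get("n_dev", 1000),
        n_val=get("n_val", 1000),
        predictor_sd=get("predictor_sd", DEFAULT_PREDICTOR_SD),
        target_treated_fraction=get("target_treated_fraction", 0.5),
    )


def load_scenarios(path: str | Path) -> list[ScenarioConfig]:
    """Load scenario configs from a YAML file.

    The file maps scenario ids to flat key/value blocks; unknown keys are
    rejected with an error naming the key. Ids must be unique (YAML itself
    silently keeps the last duplicate, so uniqueness is inherent).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigError(f"failed to parse {path}{loc}: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must map scenario ids to key/value blocks")
    return [_from_flat(str(sid), raw) for sid, raw in doc.items()]


def dump_scenarios(configs: list[ScenarioConfig]) -> str:
    """Serialize scenario configs to the YAML dialect :func:`load_scenarios` reads."""
    doc = {c.id: _to_flat(c) for c in configs}
    if len(doc) != len(configs):
        raise ConfigError("scenario ids must be unique within a file")
    return yaml.safe_dump(doc, sort_keys=False)


def save_scenarios(configs: list[ScenarioConfig], path: str | Path) -> None:
    """Write scenario configs to YAML in the format :func:`load_scenarios` reads."""
    Path(path).write_text(dump_scenarios(configs))
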