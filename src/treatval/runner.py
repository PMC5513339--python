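"""Monte-Carlo orchestration.

One *replicate* of a scenario generates a fresh untreated development
cohort and a partially treated validation cohort, develops the prognostic
model on the former, and evaluates the requested strategies on the
latter. A *scenario run* repeats this and summarizes the replicate
distribution of each metric as mean (SD). *Pooled calibration* instead
accumulates individual-level analysis rows across replicate blocks
(model refitted per block) and estimates one calibration curve per
strategy on the pooled rows.

Randomness is derived from a single master seed through labelled
substreams keyed by (scenario id, replicate index, purpose), so any
single replicate is reproducible in isolation and scenarios can run in
any order with identical results.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import RngState, generate_validation_pair
from .errors import FittingError
from .fitting import develop_prognostic_model
from .scenarios import ScenarioConfig, dump_scenarios
from .strategies import (
    CORE_STRATEGIES,
    StrategyOptions,
    StrategyResult,
    evaluate_strategies,
    strategy_arrays,
)
from .metrics import PerformanceEstimate, calibration_curve

__all__ = [
    "RunSpec",
    "ScenarioSummary",
    "run_replicate",
    "run_scenario",
    "pooled_calibration",
    "write_outputs",
]


@dataclass(frozen=True)
class RunSpec:
    """Everything needed to reproduce one simulation run."""

    scenarios: tuple[ScenarioConfig, ...]
    replicates: int = 1000
    master_seed: int = 0
    strategies: tuple[str, ...] = CORE_STRATEGIES
    options: StrategyOptions = StrategyOptions()
    pooled_n: int = 1_000_000

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.pooled_n < 1:
            raise ValueError("pooled_n must be >= 1")
        ids = [c.id for c in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario ids must be unique within a run")


@dataclass
class ScenarioSummary:
    """Mean (SD) of each metric per strategy, over non-flagged replicates."""

    scenario_id: str
    replicates: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    # stats[strategy] = {c_mean, c_sd, oe_mean, oe_sd, n_c, n_oe, n_flagged}

    def table_cell(self, strategy: str, metric: str) -> str:
        s = self.stats[strategy]
        return f"{s[f'{metric}_mean']:.2f} ({s[f'{metric}_sd']:.2f})"


def run_replicate(
    config: ScenarioConfig,
    replicate_index: int,
    master_seed: int,
    strategies=CORE_STRATEGIES,
    options: StrategyOptions = StrategyOptions(),
) -> list[StrategyResult]:
    """One simulation replicate; fully deterministic given its inputs.

    A development-fit failure flags every requested strategy for this
    replicate (the replicate is counted, never silently resampled).
    """
    rng = RngState(master_seed, f"{config.id}/rep{replicate_index}")
    dev, val = generate_validation_pair(config, rng)
    try:
        model = develop_prognostic_model(dev)
    except FittingError as e:
        est = PerformanceEstimate(np.nan, np.nan, 0, flags=(f"development_fit_failed:{type(e).__name__}",))
        return [StrategyResult(s, est, 0) for s in strategies]
    return evaluate_strategies(model, val, strategies, options)


def _rows_from_results(config_id: str, rep: int, results: list[StrategyResult]) -> list[dict]:
    return [
        {
            "scenario": config_id,
            "replicate": rep,
            "strategy": r.strategy,
            "c_index": r.estimate.c_index,
            "oe_ratio": r.estimate.oe_ratio,
            "n_effective": r.estimate.n_effective,
            "flags": ";".join(r.estimate.flags),
        }
        for r in results
    ]


def summarize_replicates(rows: pd.DataFrame) -> ScenarioSummary:
    """Aggregate replicate-level rows (one scenario) into mean/SD stats."""
    scenario_id = rows["scenario"].iloc[0]
    n_rep = rows["replicate"].nunique()
    summary = ScenarioSummary(scenario_id=scenario_id, replicates=n_rep)
    for strategy, grp in rows.groupby("strategy", sort=False):
        stat: dict[str, float] = {}
        for metric, col in (("c", "c_index"), ("oe", "oe_ratio")):
            vals = grp[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            stat[f"n_{metric}"] = int(ok.sum())
            if ok.sum() == 0:
                stat[f"{metric}_mean"] = math.nan
                stat[f"{metric}_sd"] = math.nan
            elif ok.sum() == 1:
                warnings.warn(
                    f"{scenario_id}/{strategy}: single usable replicate; SD reported as 0",
                    stacklevel=2,
                )
                stat[f"{metric}_mean"] = float(vals[ok][0])
                stat[f"{metric}_sd"] = 0.0
            else:
                stat[f"{metric}_mean"] = float(vals[ok].mean())
                stat[f"{metric}_sd"] = float(vals[ok].std(ddof=1))
        stat["n_flagged"] = int((grp["flags"] != "").sum())
        summary.stats[strategy] = stat
    return summary


def run_scenario(
    config: ScenarioConfig,
    replicates: int,
    master_seed: int,
    strategies=CORE_STRATEGIES,
    options: StrategyOptions = StrategyOptions(),
    progress: bool = False,
) -> tuple[ScenarioSummary, pd.DataFrame]:
    """Replicate loop for one scenario; returns (summary, replicate rows)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows: list[dict] = []
    for rep in range(replicates):
        results = run_replicate(config, rep, master_seed, strategies, options)
        rows.extend(_rows_from_results(config.id, rep, results))
        if progress and (rep + 1) % 200 == 0:
            print(f"  {config.id}: {rep + 1}/{replicates} replicates", flush=True)
    df = pd.DataFrame(rows)
    return summarize_replicates(df), df


def pooled_calibration(
    config: ScenarioConfig,
    pooled_n: int,
    strategies=("ignore", "exclude", "ipw_exclude"),
    bins: int = 10,
    master_seed: int = 0,
    options: StrategyOptions = StrategyOptions(),
) -> dict[str, pd.DataFrame]:
    """Calibration curves on pooled individual-level rows.

    Validation individuals are accumulated in blocks of ``config.n_val``
    (the development model is refitted for every block, so pooling N
    individuals is equivalent to combining N/n_val replicates) until at
    least ``pooled_n`` individuals have been generated; one curve per
    strategy is then computed on the pooled (pred, y, weight) rows.
    """
    if pooled_n < bins:
        raise ValueError("pooled_n must be >= bins")
    n_blocks = math.ceil(pooled_n / config.n_val)
    pools: dict[str, list] = {s: [] for s in strategies}
    for b in range(n_blocks):
        rng = RngState(master_seed, f"{config.id}/pool{b}")
        dev, val = generate_validation_pair(config, rng)
        try:
            model = develop_prognostic_model(dev)
        except FittingError:
            continue
        for s in strategies:
            try:
                pools[s].append(strategy_arrays(model, val, s, options))
            except FittingError:
                continue
    curves: dict[str, pd.DataFrame] = {}
    for s in strategies:
        if not pools[s]:
            raise FittingError(f"no usable blocks for strategy {s!r}")
        pred = np.concatenate([p for p, _, _ in pools[s]])
        y = np.concatenate([y_ for _, y_, _ in pools[s]])
        w = np.concatenate([w_ for _, _, w_ in pools[s]])
        curves[s] = calibration_curve(pred, y, w, bins=bins)
    return curves


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def _summary_table(summaries: list[ScenarioSummary], metric: str) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"scenario": s.scenario_id}
        for strat in s.stats:
            row[strat] = s.table_cell(strat, metric)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(
    spec: RunSpec,
    summaries: list[ScenarioSummary],
    replicate_rows: pd.DataFrame,
    curves: dict[str, dict[str, pd.DataFrame]] | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the run's file set and return the paths.

    Files: ``summary_oe.csv`` and ``summary_cindex.csv`` (scenario x
    strategy tables, cells formatted "mean (SD)" to two decimals),
    ``replicates.csv`` (per-replicate metric rows), ``curves.csv``
    (pooled calibration-curve points, if computed) and ``manifest.json``
    (seed, version, scenario-config hash). Reruns with the same spec
    produce byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {outdir} is not writable: {e}") from e

    config_hash = hashlib.sha256(dump_scenarios(list(spec.scenarios)).encode()).hexdigest()

    paths = {
        "summary_oe": outdir / "summary_oe.csv",
        "summary_cindex": outdir / "summary_cindex.csv",
        "replicates": outdir / "replicates.csv",
        "manifest": outdir / "manifest.json",
    }
    _summary_table(summaries, "oe").to_csv(paths["summary_oe"], index=False)
    _summary_table(summaries, "c").to_csv(paths["summary_cindex"], index=False)
    replicate_rows.to_csv(paths["replicates"], index=False, float_format="%.10g")
    if curves:
        frames = []
        for scenario_id, per_strategy in curves.items():
            for strategy, df in per_strategy.items():
                d = df.copy()
                d.insert(0, "strategy", strategy)
                d.insert(0, "scenario", scenario_id)
                frames.append(d)
        paths["curves"] = outdir / "curves.csv"
        pd.concat(frames, ignore_index=True).to_csv(paths["curves"], index=False, float_format="%.10g")
    manifest = {
        "package": "treatval",
        "version": __version__,
        "master_seed": spec.master_seed,
        "replicates": spec.replicates,
        "strategies": list(spec.strategies),
        "scenarios": [c.id for c in spec.scenarios],
        "config_sha256": config_hash,
        "truncation_percentile": spec.options.truncation_percentile,
        "propensity_covariates": spec.options.propensity_covariates,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1) + "\n")
    return paths
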