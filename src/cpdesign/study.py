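"""Declarative scenario-grid runner: simulate, fit, summarise.

A :class:`StudyConfig` spans the full design grid — error-precision by
drop-out probability by fitted sample size by replicate.  Within one
``(tau, p_d, replicate)`` cell a single dataset of ``n_individuals`` is
simulated once and every sample size ``k`` is fitted on its first-``k``
subset, preserving the within-replicate correlation across sample sizes.
Per-cell results are checkpointed as JSON so interrupted studies resume, and
cells are independent given their seeds, so results do not depend on
execution order or worker count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .mcmc import ChainSettings, run_chain
from .model import ShapeParams
from .simulate import (
    DEFAULT_DROPOUT_TIME,
    DEFAULT_TIMES,
    Scenario,
    simulate_dataset,
    subset_first_k,
)
from .summaries import (
    DEFAULT_DETECTION_THRESHOLDS,
    aggregate_replicates,
    replicate_stats,
)

__all__ = ["StudyConfig", "Task", "build_grid", "run_study", "summarize_study"]

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class StudyConfig:
    """Full specification of one simulation study.

    Defaults reproduce the cognitive-decline inspired design: trajectory
    ``(alpha, beta, delta) = (25, -1, -2)`` with change-point 5, waves at
    (0, 2, 4, 6, 8), drop-out time 4, change probability 0.5, three
    error-precisions, five drop-out probabilities, nine sample sizes and 150
    replicates — 20,250 fitted chains in all.
    """

    alpha: float = 25.0
    beta: float = -1.0
    delta: float = -2.0
    change_point: float = 5.0
    times: Sequence[float] = DEFAULT_TIMES
    t_d: float = DEFAULT_DROPOUT_TIME
    p_r: float = 0.5
    tau_grid: Sequence[float] = (0.05, 0.1, 0.2)
    pd_grid: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9)
    k_grid: Sequence[int] = (25, 50, 75, 100, 125, 150, 200, 300, 500)
    n_reps: int = 150
    n_individuals: int = 500
    chain: ChainSettings = field(default_factory=ChainSettings)
    h_values: Sequence[float] = DEFAULT_DETECTION_THRESHOLDS
    master_seed: int = 0
    out_dir: Optional[str] = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        for name in ("tau_grid", "pd_grid", "k_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if max(self.k_grid) > self.n_individuals:
            raise ValueError("k_grid values must not exceed n_individuals")
        if min(self.k_grid) < 1 or self.n_reps < 1:
            raise ValueError("k_grid values and n_reps must be positive")

    def shape(self, tau: float) -> ShapeParams:
        return ShapeParams(
            alpha=self.alpha,
            beta=self.beta,
            delta=self.delta,
            change_point=self.change_point,
            tau=tau,
        )

    def scenario(self, tau: float, p_d: float, seed: int = 0) -> Scenario:
        return Scenario(
            n=self.n_individuals,
            shape=self.shape(tau),
            p_r=self.p_r,
            p_d=p_d,
            times=tuple(self.times),
            t_d=self.t_d,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["times"] = list(self.times)
        d["tau_grid"] = list(self.tau_grid)
        d["pd_grid"] = list(self.pd_grid)
        d["k_grid"] = list(self.k_grid)
        d["h_values"] = list(self.h_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "chain" in d and isinstance(d["chain"], dict):
            d["chain"] = ChainSettings.from_dict(d["chain"])
        for name in ("times", "tau_grid", "pd_grid", "h_values"):
            if name in d:
                d[name] = tuple(float(v) for v in d[name])
        if "k_grid" in d:
            d["k_grid"] = tuple(int(v) for v in d["k_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class Task:
    """One fitted chain of the grid: a scenario cell, replicate and subset."""

    tau: float
    p_d: float
    rep: int
    k: int
    dataset_seed: int
    chain_seed: int


def _cell_seeds(config: StudyConfig, ti: int, pi: int, rep: int):
    """Deterministic seeds for one (tau, p_d, replicate) cell.

    Derived from (master seed, grid indices, replicate) so any dataset or
    chain of the grid can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(
        entropy=(int(config.master_seed) & _SEED_MASK, ti, pi, rep)
    )
    children = ss.spawn(1 + len(config.k_grid))
    data_seed = int(children[0].generate_state(1)[0] & _SEED_MASK)
    chain_seeds = [int(c.generate_state(1)[0] & _SEED_MASK) for c in children[1:]]
    return data_seed, chain_seeds


def build_grid(config: StudyConfig) -> List[Task]:
    """Enumerate every (scenario, replicate, k) task with its seeds.

    Cardinality is ``|tau_grid| * |pd_grid| * n_reps * |k_grid|``; tasks
    sharing a (tau, p_d, replicate) cell share one simulated dataset of
    ``n_individuals`` and fit nested first-``k`` subsets of it.
    """
    tasks: List[Task] = []
    for ti, tau in enumerate(config.tau_grid):
        for pi, p_d in enumerate(config.pd_grid):
            for rep in range(config.n_reps):
                data_seed, chain_seeds = _cell_seeds(config, ti, pi, rep)
                for k, cseed in zip(config.k_grid, chain_seeds):
                    tasks.append(
                        Task(
                            tau=tau,
                            p_d=p_d,
                            rep=rep,
                            k=int(k),
                            dataset_seed=data_seed,
                            chain_seed=cseed,
                        )
                    )
    return tasks


def _run_cell(config: StudyConfig, ti: int, pi: int, rep: int) -> List[dict]:
    """Simulate one cell's dataset and fit every k-subset; returns stats."""
    tau = config.tau_grid[ti]
    p_d = config.pd_grid[pi]
    data_seed, chain_seeds = _cell_seeds(config, ti, pi, rep)
    scenario = config.scenario(tau, p_d, seed=data_seed)
    data = simulate_dataset(scenario)
    results = []
    for k, cseed in zip(config.k_grid, chain_seeds):
        sub = subset_first_k(data, int(k))
        settings = replace(config.chain, seed=cseed)
        chain = run_chain(sub, settings, config.change_point, config.p_r)
        st = replicate_stats(
            chain, sub, config.change_point, h_values=config.h_values
        )
        st.update({"tau": tau, "p_d": p_d, "rep": rep, "k": int(k)})
        results.append(st)
    return results


def _run_cell_checkpointed(
    config: StudyConfig, ti: int, pi: int, rep: int, cells_dir: Optional[Path]
):
    name = f"cell_t{ti}_p{pi}_r{rep}.json"
    if cells_dir is not None:
        path = cells_dir / name
        if path.exists():
            return {"cell": name, "results": json.loads(path.read_text()), "error": None}
    try:
        results = _run_cell(config, ti, pi, rep)
    except Exception as exc:  # surface, do not abort the grid
        return {"cell": name, "results": None, "error": repr(exc)}
    if cells_dir is not None:
        (cells_dir / name).write_text(json.dumps(results))
    return {"cell": name, "results": results, "error": None}


def summarize_study(
    config: StudyConfig, stats: Sequence[dict]
) -> pd.DataFrame:
    """Aggregate per-replicate stats into one row per (tau, p_d, k) cell.

    Adds the derived ``expected_post_cp_n = k * (1 - p_d)`` column used as
    the x-axis of every design plot.
    """
    df = pd.DataFrame(list(stats))
    rows = []
    for (tau, p_d, k), group in df.groupby(["tau", "p_d", "k"], sort=True):
        scenario = config.scenario(float(tau), float(p_d))
        summary = aggregate_replicates(
            group.to_dict("records"),
            scenario,
            int(k),
            scenario_id=f"tau{tau:g}_pd{p_d:g}",
            h_values=config.h_values,
        )
        rows.append(summary.to_row())
    return pd.DataFrame(rows).sort_values(["tau", "p_d", "k"]).reset_index(drop=True)


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Execute the whole grid and return the scenario summary table.

    Cells run (optionally in parallel) over ``(tau, p_d, replicate)``; each
    simulates once and fits all k-subsets.  With an output directory set,
    per-cell results are checkpointed, a manifest of failures is written and
    the summary table is saved as ``summary.csv``.  Per-cell failures are
    recorded and skipped rather than aborting the run.
    """
    cells_dir = None
    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        cells_dir = out_dir / "cells"
        cells_dir.mkdir(parents=True, exist_ok=True)

    jobs = [
        (ti, pi, rep)
        for ti in range(len(config.tau_grid))
        for pi in range(len(config.pd_grid))
        for rep in range(config.n_reps)
    ]
    outputs = Parallel(n_jobs=config.n_jobs)(
        delayed(_run_cell_checkpointed)(config, ti, pi, rep, cells_dir)
        for ti, pi, rep in jobs
    )
    stats: List[dict] = []
    failures = []
    for out in outputs:
        if out["error"] is not None:
            failures.append({"cell": out["cell"], "error": out["error"]})
        else:
            stats.extend(out["results"])
    if not stats:
        raise RuntimeError(f"every cell failed; first failure: {failures[:1]}")
    summary = summarize_study(config, stats)
    if out_dir is not None:
        summary.to_csv(out_dir / "summary.csv", index=False)
        manifest = {
            "n_cells": len(jobs),
            "n_failed": len(failures),
            "failures": failures,
            "config": config.to_dict(),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
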