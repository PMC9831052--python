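"""Benchmark grid runner: the simulation study as a single call.

A :class:`BenchmarkGrid` describes a grid of network sizes and edge
probabilities (scenario 1, ER networks) or a fixed-network study
(scenario ``2-like``); each cell runs the full pipeline — generate a
master dataset, subsample it down the size schedule, aggregate the
criteria ratios — and the results are concatenated into one long-format
table, the machine-readable twin of the mean ± sd trajectory figures.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigError
from .evaluate import DEFAULT_SCHEDULE, subsampling_study
from .network import sparsity
from .simulate import (
    DEFAULT_PD_DELTA,
    DEFAULT_SIGMA_E,
    DEFAULT_SIGMA_EPS,
    SimulationConfig,
    child_seed,
    run_scenario1,
    run_scenario2_like,
    synthetic_mp_network,
)

__all__ = ["BenchmarkGrid", "run_benchmark", "load_grid", "save_grid"]

log = logging.getLogger(__name__)

_GRID_FIELDS = {
    "scenario",
    "p_values",
    "alpha0_values",
    "sizes",
    "iterations",
    "n_master",
    "sigma_eps",
    "sigma_e",
    "pd_delta",
    "seed",
    "thresholds",
}


@dataclass(frozen=True)
class BenchmarkGrid:
    """Experimental design of one benchmark run.

    ``scenario`` is ``"1"`` (generate an ER network per cell, cells are
    the cross product ``p_values × alpha0_values``) or ``"2-like"``
    (a synthetic fixed 20-node network; ``thresholds`` optionally maps
    sparsity labels to hard-threshold cutoffs, one cell each).
    """

    scenario: str = "1"
    p_values: tuple[int, ...] = (30,)
    alpha0_values: tuple[float, ...] = (0.3,)
    sizes: tuple[int, ...] = DEFAULT_SCHEDULE
    iterations: int = 100
    n_master: int = 1000
    sigma_eps: float = DEFAULT_SIGMA_EPS
    sigma_e: float = DEFAULT_SIGMA_E
    pd_delta: float = DEFAULT_PD_DELTA
    seed: int = 0
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in ("1", "2-like"):
            raise ConfigError(f"scenario must be '1' or '2-like', got {self.scenario!r}")
        if not self.p_values or not self.alpha0_values:
            raise ConfigError("p_values and alpha0_values must be non-empty")
        if self.iterations < 2:
            raise ConfigError(f"iterations must be >= 2, got {self.iterations}")


def run_benchmark(grid: BenchmarkGrid) -> pd.DataFrame:
    """Run every cell of the grid; return one long-format results table.

    Columns: scenario, p, alpha0, realized_sparsity, size, method,
    metric, mean, sd, iterations, seed.  A failing cell is logged and
    skipped so one pathological configuration cannot void a whole run;
    the failure count is reported at the end.
    """
    frames: list[pd.DataFrame] = []
    failures: list[str] = []
    cells = _cells(grid)
    for label, make_dataset, p, alpha0 in cells:
        t0 = time.perf_counter()
        try:
            ds = make_dataset()
            realized = sparsity(ds.net)
            cond = float(np.linalg.cond(ds.model.covariance))
            study = subsampling_study(
                ds,
                sizes=grid.sizes,
                iterations=grid.iterations,
                seed=child_seed(grid.seed, f"subsample:{label}"),
            )
        except Exception as exc:  # noqa: BLE001 - cell isolation is the point
            log.error("cell %s failed: %s", label, exc)
            failures.append(label)
            continue
        dt = time.perf_counter() - t0
        log.info(
            "cell %s: p=%d sparsity=%.3f cond(Sigma)=%.1f runtime=%.1fs",
            label, p, realized, cond, dt,
        )
        df = study.table.copy()
        df.insert(0, "scenario", grid.scenario)
        df.insert(1, "p", p)
        df.insert(2, "alpha0", alpha0)
        df.insert(3, "realized_sparsity", round(realized, 6))
        df["seed"] = grid.seed
        frames.append(df)
    if failures:
        log.warning("%d/%d cells failed: %s", len(failures), len(cells), failures)
    if not frames:
        raise ConfigError("every benchmark cell failed")
    return pd.concat(frames, ignore_index=True)


def _cells(grid: BenchmarkGrid):
    """Expand the grid into (label, dataset factory, p, alpha0) cells."""
    cells = []
    if grid.scenario == "1":
        for p in grid.p_values:
            for alpha0 in grid.alpha0_values:
                config = SimulationConfig(
                    p=p,
                    alpha0=alpha0,
                    n_master=grid.n_master,
                    sigma_eps=grid.sigma_eps,
                    sigma_e=grid.sigma_e,
                    pd_delta=grid.pd_delta,
                    seed=child_seed(grid.seed, f"cell:{p}:{alpha0}"),
                )
                cells.append(
                    (f"s1:p={p}:a={alpha0}", _factory1(config), p, alpha0)
                )
    else:
        net = synthetic_mp_network(seed=child_seed(grid.seed, "mp-network"))
        thresholds: Sequence[float | None] = grid.thresholds or (None,)
        for t in thresholds:
            config = SimulationConfig(
                p=net.p,
                alpha0=sparsity(net),
                n_master=grid.n_master,
                sigma_eps=grid.sigma_eps,
                sigma_e=grid.sigma_e,
                pd_delta=grid.pd_delta,
                seed=child_seed(grid.seed, f"cell:2like:{t}"),
            )
            cells.append(
                (
                    f"s2:t={t}",
                    _factory2(net, config, t),
                    net.p,
                    round(sparsity(net), 4),
                )
            )
    return cells


def _factory1(config: SimulationConfig):
    return lambda: run_scenario1(config)


def _factory2(net, config: SimulationConfig, threshold):
    return lambda: run_scenario2_like(net, config, threshold=threshold)


def load_grid(path: str | Path) -> BenchmarkGrid:
    """Parse a YAML grid document with strict schema validation.

    Unknown keys are errors: a typo in a noise-scale field must fail
    loudly rather than silently fall back to a default.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("grid document must be a mapping")
    unknown = set(doc) - _GRID_FIELDS
    if unknown:
        raise ConfigError(f"unknown grid keys: {sorted(unknown)}")
    for key in ("p_values", "alpha0_values", "sizes", "thresholds"):
        if key in doc:
            doc[key] = tuple(doc[key])
    try:
        return BenchmarkGrid(**doc)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def save_grid(grid: BenchmarkGrid, path: str | Path) -> None:
    from dataclasses import asdict

    doc = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(grid).items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
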