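"""Repeated-trial experiments over the estimator's independent variables.

The two experiments mirror the simulation study design: a fixed synthetic
dataset (ideal + noise ellipses) is estimated repeatedly with fresh RANSAC
seeds, and per-configuration averages and standard deviations of the
estimated center, orbit radius, consensus size and wall time are tabulated

* once sweeping ES (estimation samples per round) at fixed AAE, and
* once sweeping AAE (the angular tolerance) at fixed ES.

Standard deviations are population SDs over the repeats (so a single
repeat reports 0).  The "distance SD" column is the SD of each repeat's
Euclidean distance from the *mean* estimated center — a pure precision
measure; when the true center is known the mean distance from it (an
accuracy measure) is logged in an extra column.  Wall-clock times are
reported for orientation only; they depend on the host.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from dataclasses import replace as dc_replace
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .ransac import RansacConfig, estimate_hpom
from .simulate import PupilEllipse

__all__ = [
    "TrialMetrics",
    "run_trials",
    "run_trials_raw",
    "experiment_es_sweep",
    "experiment_aae_sweep",
    "DEFAULT_ES_GRID",
    "DEFAULT_AAE_GRID",
]

DEFAULT_ES_GRID = (2, 3, 4, 5, 7, 10, 14)
DEFAULT_AAE_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)

RAW_COLUMNS = [
    "repeat",
    "seed",
    "orcp_x",
    "orcp_y",
    "radius",
    "cost",
    "time_ms",
    "failed",
]


@dataclass(frozen=True)
class TrialMetrics:
    """Aggregates of one configuration's repeated runs (one table row)."""

    orcp_x_avg: float
    orcp_x_sd: float
    orcp_y_avg: float
    orcp_y_sd: float
    distance_sd: float
    radius_avg: float
    radius_sd: float
    cost_avg: float
    time_avg_ms: float
    time_sd_ms: float
    n_repeats: int
    n_failures: int = 0
    true_distance_avg: float = float("nan")


def _repeat_seeds(base_seed: int, repeats: int) -> np.ndarray:
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31, size=repeats)


def run_trials_raw(
    dataset: Sequence[PupilEllipse],
    cfg: RansacConfig,
    repeats: int,
    base_seed: int,
) -> pd.DataFrame:
    """Run the estimator ``repeats`` times; one row of raw results each.

    Per-repeat seeds are derived deterministically from ``base_seed``.
    A repeat whose estimation fails (e.g. every sampled subset
    degenerate) is recorded with NaN results and ``failed=True`` rather
    than aborting the experiment.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rows = []
    for i, seed in enumerate(_repeat_seeds(base_seed, repeats)):
        run_cfg = dc_replace(cfg, seed=int(seed))
        t0 = time.perf_counter()
        try:
            est = estimate_hpom(dataset, run_cfg)
            elapsed_ms = (time.perf_counter() - t0) * 1e3
            rows.append(
                (i, int(seed), est.orcp_x, est.orcp_y, est.radius, est.cost,
                 elapsed_ms, False)
            )
        except ValueError:
            elapsed_ms = (time.perf_counter() - t0) * 1e3
            rows.append(
                (i, int(seed), np.nan, np.nan, np.nan, np.nan, elapsed_ms, True)
            )
    return pd.DataFrame(rows, columns=RAW_COLUMNS)


def aggregate_raw(
    raw: pd.DataFrame, true_orcp: tuple[float, float] | None = None
) -> TrialMetrics:
    """Collapse a raw per-repeat table into one :class:`TrialMetrics` row."""
    ok = raw[~raw["failed"]]
    n_fail = int(raw["failed"].sum())
    if len(ok) == 0:
        nan = float("nan")
        return TrialMetrics(*(nan,) * 10, n_repeats=len(raw), n_failures=n_fail)
    sd = lambda v: float(np.std(v))  # population SD: one repeat -> 0
    mx, my = float(ok["orcp_x"].mean()), float(ok["orcp_y"].mean())
    dist_from_mean = np.hypot(ok["orcp_x"] - mx, ok["orcp_y"] - my)
    true_dist = float("nan")
    if true_orcp is not None:
        true_dist = float(
            np.hypot(ok["orcp_x"] - true_orcp[0], ok["orcp_y"] - true_orcp[1]).mean()
        )
    return TrialMetrics(
        orcp_x_avg=mx,
        orcp_x_sd=sd(ok["orcp_x"]),
        orcp_y_avg=my,
        orcp_y_sd=sd(ok["orcp_y"]),
        distance_sd=sd(dist_from_mean),
        radius_avg=float(ok["radius"].mean()),
        radius_sd=sd(ok["radius"]),
        cost_avg=float(ok["cost"].mean()),
        time_avg_ms=float(ok["time_ms"].mean()),
        time_sd_ms=sd(ok["time_ms"]),
        n_repeats=len(raw),
        n_failures=n_fail,
        true_distance_avg=true_dist,
    )


def run_trials(
    dataset: Sequence[PupilEllipse],
    cfg: RansacConfig,
    repeats: int,
    base_seed: int,
    true_orcp: tuple[float, float] | None = None,
) -> TrialMetrics:
    """Repeated estimation runs aggregated into one summary row."""
    return aggregate_raw(run_trials_raw(dataset, cfg, repeats, base_seed), true_orcp)


def _sweep(
    dataset: Sequence[PupilEllipse],
    configs: Sequence[tuple[str, float, RansacConfig]],
    repeats: int,
    base_seed: int,
    true_orcp: tuple[float, float] | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    summaries, raws = [], []
    for var_name, var_value, cfg in configs:
        raw = run_trials_raw(dataset, cfg, repeats, base_seed)
        metrics = aggregate_raw(raw, true_orcp)
        summaries.append({var_name: var_value, **metrics.__dict__})
        raw = raw.copy()
        raw.insert(0, var_name, var_value)
        raws.append(raw)
    return pd.DataFrame(summaries), pd.concat(raws, ignore_index=True)


def experiment_es_sweep(
    dataset: Sequence[PupilEllipse],
    es_grid: Sequence[int] = DEFAULT_ES_GRID,
    aae: float = 5.0,
    repeats: int = 200,
    iterations: int = 20000,
    base_seed: int = 0,
    true_orcp: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep the per-round sample count at fixed angular tolerance.

    Returns ``(summary, raw)``: one summary row per ES value, plus the
    per-repeat records behind them.
    """
    configs = [
        ("es", es, RansacConfig(es=es, aae=aae, iterations=iterations))
        for es in es_grid
    ]
    return _sweep(dataset, configs, repeats, base_seed, true_orcp)


def experiment_aae_sweep(
    dataset: Sequence[PupilEllipse],
    aae_grid: Sequence[float] = DEFAULT_AAE_GRID,
    es: int = 7,
    repeats: int = 200,
    iterations: int = 20000,
    base_seed: int = 0,
    true_orcp: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep the angular tolerance at fixed per-round sample count."""
    configs = [
        ("aae", aae, RansacConfig(es=es, aae=aae, iterations=iterations))
        for aae in aae_grid
    ]
    return _sweep(dataset, configs, repeats, base_seed, true_orcp)
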