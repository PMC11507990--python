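"""Robustness-parameter sweep: solve DAS/RAS over a Γ×α grid and evaluate.

For every (instance, Γ, α) cell the driver solves the model, audits the
schedule, computes patient metrics, and (optionally) evaluates the schedule
over seeded Monte-Carlo scenarios.  The headline sweep quantity is the
per-patient objective increase relative to the deterministic baseline,
expressed in NAWD; utilization and cancellation means come from the scenario
evaluation, with common random numbers across cells.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import Instance, RobustConfig
from .model import (
    DEFAULT_MIP_GAP,
    DEFAULT_TIME_LIMIT,
    max_operated_bound,
    solve_das,
    solve_ras,
)

__all__ = ["SweepGrid", "SweepResult", "run_sweep", "detect_saturation", "report", "read_sweep"]

log = logging.getLogger(__name__)

_COLUMNS = [
    "instance",
    "gamma",
    "alpha",
    "objective",
    "objective_das",
    "nawd_increase_per_patient",
    "nawd_increase_per_unscheduled",
    "operated",
    "max_operated",
    "op_t",
    "sw_t",
    "mean_utilization",
    "mean_canceled_per_block",
    "se_utilization",
    "se_canceled",
    "status",
    "gap",
    "wall_time",
]


@dataclass(frozen=True)
class SweepGrid:
    """The Γ×α grid.  ``gamma = 0`` is the deterministic (DAS) baseline and is
    always included so increases relative to it can be reported."""

    gammas: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8)
    alphas: tuple[float, ...] = (0.5, 1.0, 2.0)
    n_scenarios: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.gammas or not self.alphas:
            raise ValueError("gamma and alpha grids must be non-empty")
        gs = tuple(sorted(set(self.gammas) | {0}))
        object.__setattr__(self, "gammas", gs)


@dataclass
class SweepResult:
    """Long-format sweep table plus per-cell failure records."""

    frame: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    def cell(self, instance: str, gamma: int, alpha: float) -> pd.Series:
        f = self.frame
        m = (f.instance == instance) & (f.gamma == gamma) & (np.isclose(f.alpha, alpha))
        if not m.any():
            raise KeyError((instance, gamma, alpha))
        return f[m].iloc[0]

    def instances(self) -> list[str]:
        return list(self.frame.instance.unique())


def run_sweep(
    instances: Iterable[Instance],
    grid: SweepGrid,
    time_limit: float = DEFAULT_TIME_LIMIT,
    mip_gap: float = DEFAULT_MIP_GAP,
    evaluate: bool = True,
) -> SweepResult:
    """Solve and evaluate every grid cell for every instance.

    The DAS baseline (Γ=0) is solved once per instance and reused across α.
    Scenario evaluation uses ``grid.base_seed`` for every cell (common random
    numbers).  Solver failures are recorded in ``SweepResult.failures`` and
    the sweep continues.
    """
    rows: list[dict] = []
    failures: list[dict] = []
    for inst in instances:
        name = inst.name or f"instance{len(rows)}"
        das = solve_das(inst, time_limit=time_limit, mip_gap=mip_gap)
        bound = max_operated_bound(inst)
        das_eval = (
            das.simulate(grid.n_scenarios, base_seed=grid.base_seed) if evaluate else None
        )
        for alpha in grid.alphas:
            for gamma in grid.gammas:
                t0 = time.perf_counter()
                try:
                    if gamma == 0:
                        res, agg = das, das_eval
                    else:
                        res = solve_ras(
                            inst,
                            RobustConfig(gamma=gamma, alpha=alpha),
                            time_limit=time_limit,
                            mip_gap=mip_gap,
                        )
                        agg = (
                            res.simulate(grid.n_scenarios, base_seed=grid.base_seed)
                            if evaluate
                            else None
                        )
                except Exception as exc:  # record and continue
                    failures.append(
                        {"instance": name, "gamma": gamma, "alpha": alpha, "error": str(exc)}
                    )
                    log.warning("cell (%s, Γ=%d, α=%g) failed: %s", name, gamma, alpha, exc)
                    continue
                wall = time.perf_counter() - t0
                m = res.metrics().overall
                n_unsched = len(inst.patients) - res.n_operated
                inc = res.objective - das.objective
                rows.append(
                    {
                        "instance": name,
                        "gamma": gamma,
                        "alpha": alpha,
                        "objective": res.objective,
                        "objective_das": das.objective,
                        "nawd_increase_per_patient": inc / len(inst.patients),
                        "nawd_increase_per_unscheduled": (
                            inc / n_unsched if n_unsched else np.nan
                        ),
                        "operated": res.n_operated,
                        "max_operated": bound,
                        "op_t": int(m["op_t"]),
                        "sw_t": int(m["sw_t"]),
                        "mean_utilization": agg.mean_utilization if agg else np.nan,
                        "mean_canceled_per_block": (
                            agg.mean_canceled_per_block if agg else np.nan
                        ),
                        "se_utilization": agg.se_utilization if agg else np.nan,
                        "se_canceled": agg.se_canceled if agg else np.nan,
                        "status": res.status,
                        "gap": res.gap,
                        "wall_time": wall,
                    }
                )
                log.info(
                    "cell (%s, Γ=%d, α=%g): status=%s objective=%.2f gap=%s wall=%.2fs",
                    name, gamma, alpha, res.status, res.objective, res.gap, wall,
                )
    return SweepResult(frame=pd.DataFrame(rows, columns=_COLUMNS), failures=failures)


def detect_saturation(
    sweep: SweepResult, instance: str, alpha: float, tol: float = DEFAULT_MIP_GAP
) -> int:
    """Smallest Γ after which the objective stays constant for all larger Γ.

    Beyond this point every patient schedulable in a block is already counted
    at their maximum duration, so raising the budget further changes nothing.
    Constancy is judged within relative tolerance ``tol`` (default: the
    solver's acceptable gap, so MIP slack is not mistaken for growth).
    Requires the sweep to cover consecutive Γ values for this (instance, α).
    """
    f = sweep.frame
    sel = f[(f.instance == instance) & np.isclose(f.alpha, alpha)].sort_values("gamma")
    gammas = sel.gamma.to_numpy()
    if len(gammas) == 0:
        raise ValueError(f"no sweep cells for ({instance!r}, alpha={alpha})")
    if not np.array_equal(gammas, np.arange(gammas[0], gammas[0] + len(gammas))):
        raise ValueError(f"gamma grid for ({instance!r}, alpha={alpha}) is not consecutive")
    obj = sel.objective.to_numpy()
    scale = max(1.0, abs(obj[-1]))
    k = len(obj) - 1
    while k > 0 and abs(obj[k - 1] - obj[-1]) <= tol * scale:
        k -= 1
    return int(gammas[k])


def report(sweep: SweepResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the sweep as CSV tables and plot-ready figure data.

    Emits ``sweep.csv`` (full long table), pivot tables of operated counts
    and tardy counts by Γ, and long-format figure data for the NAWD increase,
    utilization and cancellations versus Γ per α.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    (out_dir / "figures").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    f = sweep.frame

    paths["sweep"] = out_dir / "sweep.csv"
    f.to_csv(paths["sweep"], index=False)

    if len(f):
        operated = f.pivot_table(
            index=["instance", "alpha"], columns="gamma", values="operated"
        )
        tardy = f.pivot_table(
            index=["instance", "alpha"],
            columns="gamma",
            values=["op_t", "sw_t"],
        )
    else:
        operated = tardy = pd.DataFrame()
    paths["operated_by_gamma"] = out_dir / "operated_by_gamma.csv"
    operated.to_csv(paths["operated_by_gamma"])
    paths["tardy_by_gamma"] = out_dir / "tardy_by_gamma.csv"
    tardy.to_csv(paths["tardy_by_gamma"])

    for key, col in [
        ("nawd_increase", "nawd_increase_per_patient"),
        ("utilization", "mean_utilization"),
        ("cancellations", "mean_canceled_per_block"),
    ]:
        p = out_dir / "figures" / f"{key}.csv"
        cols = ["instance", "alpha", "gamma", col]
        (f[cols] if len(f) else pd.DataFrame(columns=cols)).to_csv(p, index=False)
        paths[key] = p
    return paths


def read_sweep(path: str | Path) -> SweepResult:
    """Re-read a ``sweep.csv`` written by :func:`report`."""
    return SweepResult(frame=pd.read_csv(path)[_COLUMNS])
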