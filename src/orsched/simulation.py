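"""Monte-Carlo evaluation of a fixed schedule under realized surgery times.

Surgery durations are drawn from a lognormal distribution moment-matched on
the natural scale (mean ``tbar``, SD ``sigma``) and truncated from below at
``max(tbar - sigma, 30)`` minutes, so no realization is implausibly short.

A realization is applied to a schedule with the Longest-Processing-Time (LPT)
cancellation rule: within each block, surgeries run in decreasing order of
*mean* duration; a patient is operated whenever the block still has residual
time (strictly positive) when their turn comes — their realized duration may
overrun the residual, which is recorded as overtime — and once the residual
is exhausted the current patient and everyone after them are canceled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Assignment, Instance

__all__ = [
    "Realization",
    "BlockOutcome",
    "ScenarioResult",
    "ScenarioAggregate",
    "draw_realization",
    "lpt_evaluate",
    "evaluate_over_scenarios",
]

#: Minimum plausible surgery duration (minutes).
MIN_DURATION = 30.0


@dataclass(frozen=True)
class Realization:
    """One draw of surgery durations for every patient of an instance."""

    realized_duration: dict[str, float]
    draw: dict[str, float]
    seed: int


def draw_realization(instance: Instance, seed: int) -> Realization:
    """Draw one set of surgery times.

    Each patient's raw value ``r`` is lognormal with natural-scale mean
    ``tbar`` and SD ``sigma`` (log-scale parameters ``s^2 = ln(1 +
    sigma^2/tbar^2)``, ``mu = ln(tbar) - s^2/2``); the realized duration is
    ``max(r, tbar - sigma, 30)``.  ``sigma = 0`` degenerates to ``r = tbar``
    exactly.  Deterministic given ``seed``.
    """
    instance.require_durations()
    rng = np.random.default_rng(seed)
    draws: dict[str, float] = {}
    realized: dict[str, float] = {}
    for p in instance.patients:
        tbar, sigma = float(p.mean_duration), float(p.sd_duration)
        if sigma == 0.0:
            r = tbar
        else:
            s2 = np.log1p((sigma / tbar) ** 2)
            mu = np.log(tbar) - s2 / 2.0
            r = float(rng.lognormal(mean=mu, sigma=np.sqrt(s2)))
        draws[p.patient_id] = r
        realized[p.patient_id] = max(r, tbar - sigma, MIN_DURATION)
    return Realization(realized_duration=realized, draw=draws, seed=seed)


@dataclass(frozen=True)
class BlockOutcome:
    """Outcome of one block under one realization."""

    block_id: str
    operated_ids: tuple[str, ...]  # in LPT order
    canceled_ids: tuple[str, ...]  # suffix of the LPT order
    used_minutes: float
    capacity: float
    overtime_minutes: float

    @property
    def utilization(self) -> float:
        """Capacity fraction consumed, capped at 1 (empty block: 0)."""
        if self.capacity <= 0:
            return 0.0
        return min(self.used_minutes, self.capacity) / self.capacity

    @property
    def utilization_uncapped(self) -> float:
        return self.used_minutes / self.capacity if self.capacity > 0 else 0.0


@dataclass(frozen=True)
class ScenarioResult:
    """Per-block outcomes of applying a schedule to one realization."""

    blocks: dict[str, BlockOutcome]
    seed: int

    @property
    def n_canceled(self) -> int:
        return sum(len(b.canceled_ids) for b in self.blocks.values())

    @property
    def canceled_per_block(self) -> float:
        return self.n_canceled / len(self.blocks) if self.blocks else 0.0

    @property
    def mean_utilization(self) -> float:
        if not self.blocks:
            return 0.0
        return float(np.mean([b.utilization for b in self.blocks.values()]))


def lpt_evaluate(
    instance: Instance, assignment: Assignment, realization: Realization
) -> ScenarioResult:
    """Apply the LPT cancellation rule to a schedule under one realization."""
    by_block = assignment.block_patients(instance)
    outcomes: dict[str, BlockOutcome] = {}
    for b in instance.blocks:
        pids = by_block[b.block_id]
        missing = [pid for pid in pids if pid not in realization.realized_duration]
        if missing:
            raise ValueError(f"realization missing patients {missing}")
        # LPT on mean duration; ties broken by patient id for determinism
        order = sorted(
            pids, key=lambda pid: (-instance.patient(pid).mean_duration, pid)
        )
        residual = float(b.capacity)
        operated: list[str] = []
        canceled: list[str] = []
        used = 0.0
        for k, pid in enumerate(order):
            if residual > 0.0:
                dur = realization.realized_duration[pid]
                operated.append(pid)
                used += dur
                residual -= dur
            else:
                canceled = order[k:]
                break
        outcomes[b.block_id] = BlockOutcome(
            block_id=b.block_id,
            operated_ids=tuple(operated),
            canceled_ids=tuple(canceled),
            used_minutes=used,
            capacity=float(b.capacity),
            overtime_minutes=max(used - float(b.capacity), 0.0),
        )
    return ScenarioResult(blocks=outcomes, seed=realization.seed)


@dataclass
class ScenarioAggregate:
    """Scenario-averaged utilization and cancellation statistics.

    Means and standard errors over the scenario draws; per-scenario values
    retained for downstream trend tests.
    """

    n_scenarios: int
    base_seed: int
    utilization: np.ndarray = field(repr=False)  # per scenario, mean over blocks
    canceled_per_block: np.ndarray = field(repr=False)
    overtime_per_block: np.ndarray = field(repr=False)

    @property
    def mean_utilization(self) -> float:
        return float(self.utilization.mean())

    @property
    def mean_canceled_per_block(self) -> float:
        return float(self.canceled_per_block.mean())

    @property
    def mean_overtime_per_block(self) -> float:
        return float(self.overtime_per_block.mean())

    @property
    def se_utilization(self) -> float:
        return _se(self.utilization)

    @property
    def se_canceled(self) -> float:
        return _se(self.canceled_per_block)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": np.arange(self.n_scenarios),
                "seed": self.base_seed + np.arange(self.n_scenarios),
                "utilization": self.utilization,
                "canceled_per_block": self.canceled_per_block,
                "overtime_per_block": self.overtime_per_block,
            }
        )


def _se(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def evaluate_over_scenarios(
    instance: Instance,
    assignment: Assignment,
    n_scenarios: int = 100,
    base_seed: int = 0,
) -> ScenarioAggregate:
    """Evaluate a schedule over ``n_scenarios`` independent realizations.

    Scenario ``k`` uses seed ``base_seed + k``, one independent stream per
    scenario; evaluating two schedules with the same ``base_seed`` therefore
    uses common random numbers, which sharpens their comparison.
    """
    if n_scenarios < 1:
        raise ValueError("n_scenarios must be >= 1")
    util = np.empty(n_scenarios)
    canc = np.empty(n_scenarios)
    over = np.empty(n_scenarios)
    for k in range(n_scenarios):
        real = draw_realization(instance, seed=base_seed + k)
        res = lpt_evaluate(instance, assignment, real)
        util[k] = res.mean_utilization
        canc[k] = res.canceled_per_block
        over[k] = (
            float(np.mean([b.overtime_minutes for b in res.blocks.values()]))
            if res.blocks
            else 0.0
        )
    return ScenarioAggregate(
        n_scenarios=n_scenarios,
        base_seed=base_seed,
        utilization=util,
        canceled_per_block=canc,
        overtime_per_block=over,
    )
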