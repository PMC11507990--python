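"""Deterministic and cardinality-constrained robust advance-scheduling MILPs.

The deterministic model (DAS) assigns each waiting-list patient to at most one
OR block, minimizing the sum of urgency-weighted waiting/tardiness penalties,
with each block's capacity consumed at the *mean* surgery duration:

    min  sum_ij p_ij x_ij + sum_i q_i (1 - sum_j x_ij)
    s.t. sum_j x_ij <= 1                   for every patient i
         sum_i tbar_i x_ij <= gamma_j      for every block j
         x_ij binary

The robust model (RAS) replaces each capacity constraint with its budgeted
(cardinality-constrained) counterpart: the schedule must remain feasible when
any subset of at most Γ patients in the block require their maximum duration
``tbar_i + t_hat_i`` (with ``t_hat_i = alpha * sd_i``) while the rest take the
mean.  The inner worst-case maximization is linearized by LP duality with
auxiliaries ``zeta_j`` and ``pi_ij``:

    sum_i tbar_i x_ij + Γ zeta_j + sum_i pi_ij <= gamma_j
    zeta_j + pi_ij >= t_hat_i x_ij
    zeta_j, pi_ij >= 0

Both are solved through :func:`scipy.optimize.milp` (HiGHS).  Every solve is
audited: the objective is recomputed from the penalty formulas and, for the
robust model, the returned schedule is re-checked against the closed-form
worst case (:func:`robust_worst_case_load`).
"""

from __future__ import annotations

import contextlib
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .core import (
    Assignment,
    Instance,
    RobustConfig,
    scheduled_penalty,
    total_objective,
    unscheduled_penalty,
)
from .metrics import MetricsReport, compute_metrics

__all__ = [
    "AdvanceSchedulingModel",
    "SchedulingResults",
    "solve_das",
    "solve_ras",
    "robust_worst_case_load",
    "verify_robust_feasibility",
    "duality_gap_check",
    "max_operated_bound",
]

#: Default solver options: two-hour time limit, 0.1% acceptable relative gap.
DEFAULT_TIME_LIMIT = 7200.0
DEFAULT_MIP_GAP = 1e-3

_STATUS = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "unbounded"}


@contextlib.contextmanager
def _quiet_native_stdout():
    """Mute file-descriptor-level stdout while the MIP backend runs.

    The backend emits diagnostic lines directly on fd 1, bypassing
    ``sys.stdout``; temporarily pointing the descriptor at devnull keeps
    library and CLI output clean.
    """
    try:
        saved = os.dup(1)
    except OSError:
        yield
        return
    try:
        devnull = os.open(os.devnull, os.O_WRONLY)
        os.dup2(devnull, 1)
        os.close(devnull)
        yield
    finally:
        try:  # flush native buffers while fd 1 still points at devnull
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:
            pass
        os.dup2(saved, 1)
        os.close(saved)


def robust_worst_case_load(
    block_patients: list[tuple[float, float]], gamma: int
) -> float:
    """Worst-case total duration of a block under the budget Γ.

    ``block_patients`` lists ``(tbar, t_hat)`` of the patients scheduled in
    the block.  The inner maximization over subsets of at most Γ patients at
    their maximum duration has the closed-form solution: total mean load plus
    the ``min(gamma, n)`` largest deviations.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    tbar = [t for t, _ in block_patients]
    that = sorted((h for _, h in block_patients), reverse=True)
    return sum(tbar) + sum(that[: min(gamma, len(that))])


def verify_robust_feasibility(
    instance: Instance, assignment: Assignment, config: RobustConfig
) -> dict[str, tuple[bool, float]]:
    """Audit a schedule against the set-form robust capacity constraints.

    Returns per block ``(feasible, slack)`` where slack is capacity minus the
    closed-form worst-case load (negative when violated).  A schedule from
    the robust solver must pass for its own configuration; a deterministic
    schedule audited at Γ > 0 typically fails on tightly packed blocks.
    """
    out: dict[str, tuple[bool, float]] = {}
    by_block = assignment.block_patients(instance)
    for b in instance.blocks:
        pts = [
            (instance.patient(pid).mean_duration, config.deviation(instance.patient(pid)))
            for pid in by_block[b.block_id]
        ]
        load = robust_worst_case_load(pts, config.gamma)
        slack = b.capacity - load
        out[b.block_id] = (slack >= -1e-6, slack)
    return out


def duality_gap_check(
    block_patients: list[float],
    gamma: int,
    zeta: float,
    pi: list[float],
    tol: float = 1e-6,
) -> bool:
    """Check strong duality of the linearized worst-case term on one block.

    ``block_patients`` are the active deviations ``t_hat_i * x_ij`` of the
    block.  The primal inner problem (pick at most Γ of them) has optimum
    equal to the sum of the Γ largest values; its LP dual minimizes
    ``Γ zeta + sum(pi)`` subject to ``zeta + pi_i >= t_hat_i``.  The supplied
    ``(zeta, pi)`` must be dual-feasible (otherwise a ``ValueError`` reports
    the violation); the function then solves the dual LP and returns whether
    its optimum matches the closed form within ``tol``.
    """
    that = np.asarray(block_patients, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if zeta < -tol or (pi < -tol).any():
        raise ValueError("duals must be nonnegative")
    viol = that - (zeta + pi)
    if (viol > tol).any():
        bad = int(np.argmax(viol))
        raise ValueError(
            f"dual constraint violated for element {bad}: "
            f"zeta + pi = {zeta + pi[bad]:.6g} < t_hat = {that[bad]:.6g}"
        )
    closed = float(np.sort(that)[::-1][: min(gamma, len(that))].sum())
    if len(that) == 0:
        return abs(closed) <= tol
    # dual LP: min gamma*zeta + sum(pi) s.t. zeta + pi_i >= that_i, all >= 0
    n = len(that)
    c = np.concatenate([[float(gamma)], np.ones(n)])
    a = np.hstack([-np.ones((n, 1)), -np.eye(n)])
    with _quiet_native_stdout():
        res = linprog(c, A_ub=a, b_ub=-that, bounds=[(0, None)] * (n + 1), method="highs")
    if not res.success:
        raise RuntimeError(f"dual LP failed: {res.message}")
    return math.isclose(res.fun, closed, rel_tol=1e-9, abs_tol=tol)


def _penalty_arrays(instance: Instance) -> tuple[np.ndarray, np.ndarray]:
    p = np.array(
        [
            [scheduled_penalty(pt, b) for b in instance.blocks]
            for pt in instance.patients
        ]
    )
    q = np.array([unscheduled_penalty(pt, instance.horizon) for pt in instance.patients])
    return p, q


class AdvanceSchedulingModel:
    """Advance-scheduling MILP for a waiting-list instance.

    Parameters
    ----------
    instance
        Waiting list, OR blocks and horizon.
    robust
        ``None`` for the deterministic model; a :class:`RobustConfig` for the
        cardinality-constrained robust model.  ``gamma = 0`` or ``alpha = 0``
        yields the deterministic optimum by construction.
    time_limit, mip_gap
        Solver controls (seconds; relative optimality gap).

    Examples
    --------
    >>> res = AdvanceSchedulingModel(instance).fit()
    >>> res.objective, res.status
    >>> print(res.summary())
    """

    def __init__(
        self,
        instance: Instance,
        robust: RobustConfig | None = None,
        time_limit: float = DEFAULT_TIME_LIMIT,
        mip_gap: float = DEFAULT_MIP_GAP,
    ) -> None:
        instance.require_durations()
        self.instance = instance
        self.robust = robust
        self.time_limit = time_limit
        self.mip_gap = mip_gap

    @property
    def is_robust(self) -> bool:
        return self.robust is not None and self.robust.gamma > 0 and self.robust.alpha > 0

    def fit(self) -> "SchedulingResults":
        """Solve the MILP and return audited results."""
        inst = self.instance
        nI, nJ = len(inst.patients), len(inst.blocks)
        if nI == 0 or nJ == 0:
            schedule = {pt.patient_id: None for pt in inst.patients}
            _, q0 = _penalty_arrays(inst) if nI else (None, np.zeros(0))
            assignment = Assignment(
                schedule=schedule, objective=float(q0.sum()), status="optimal", gap=0.0
            )
            return SchedulingResults(self, assignment)

        p, q = _penalty_arrays(inst)
        tbar = np.array([pt.mean_duration for pt in inst.patients])
        cap = np.array([b.capacity for b in inst.blocks])

        nx = nI * nJ
        robust = self.is_robust
        if robust:
            that = np.array([self.robust.deviation(pt) for pt in inst.patients])
            gamma = self.robust.gamma
            nvar = nx + nJ + nx  # x, zeta, pi
        else:
            nvar = nx

        # objective: constant sum(q) + sum_ij (p_ij - q_i) x_ij
        c = np.zeros(nvar)
        c[:nx] = (p - q[:, None]).ravel()

        rows_a, cols_a, vals_a, rhs = [], [], [], []
        row = 0

        def add(cols, vals, b):
            nonlocal row
            rows_a.extend([row] * len(cols))
            cols_a.extend(cols)
            vals_a.extend(vals)
            rhs.append(b)
            row += 1

        # at most one block per patient
        for i in range(nI):
            add([i * nJ + j for j in range(nJ)], [1.0] * nJ, 1.0)
        # capacity
        for j in range(nJ):
            cols = [i * nJ + j for i in range(nI)]
            vals = list(tbar)
            if robust:
                cols.append(nx + j)  # zeta_j
                vals.append(float(gamma))
                cols.extend(nx + nJ + i * nJ + j for i in range(nI))  # pi_ij
                vals.extend([1.0] * nI)
            add(cols, vals, float(cap[j]))
        # dual-feasibility rows: t_hat_i x_ij - zeta_j - pi_ij <= 0
        if robust:
            for i in range(nI):
                if that[i] == 0.0:
                    continue
                for j in range(nJ):
                    add(
                        [i * nJ + j, nx + j, nx + nJ + i * nJ + j],
                        [float(that[i]), -1.0, -1.0],
                        0.0,
                    )

        a = sparse.csr_array(
            (vals_a, (rows_a, cols_a)), shape=(row, nvar), dtype=float
        )
        integrality = np.zeros(nvar)
        integrality[:nx] = 1
        ub = np.full(nvar, np.inf)
        ub[:nx] = 1.0
        with _quiet_native_stdout():
            res = milp(
                c,
                constraints=LinearConstraint(a, -np.inf, np.array(rhs)),
                integrality=integrality,
                bounds=Bounds(np.zeros(nvar), ub),
                options={"time_limit": self.time_limit, "mip_rel_gap": self.mip_gap},
            )
        if res.status == 2 or res.x is None:
            assignment = Assignment(
                schedule={pt.patient_id: None for pt in inst.patients},
                objective=float(q.sum()),
                status="infeasible" if res.status == 2 else _STATUS.get(res.status, "time_limit"),
                gap=None,
            )
            return SchedulingResults(self, assignment, raw=res)

        x = np.asarray(res.x[:nx]).reshape(nI, nJ)
        schedule: dict[str, str | None] = {}
        for i, pt in enumerate(inst.patients):
            j = int(np.argmax(x[i]))
            schedule[pt.patient_id] = (
                inst.blocks[j].block_id if x[i, j] > 0.5 else None
            )

        gap = res.mip_gap if res.mip_gap is not None else None
        if res.status == 0:
            status = "optimal" if (gap is None or gap <= self.mip_gap + 1e-12) else "gap_reached"
        else:
            status = _STATUS.get(res.status, "time_limit")

        zeta = pi = None
        if robust:
            zeta = {
                b.block_id: float(res.x[nx + j]) for j, b in enumerate(inst.blocks)
            }
            pi = {
                (pt.patient_id, b.block_id): float(res.x[nx + nJ + i * nJ + j])
                for i, pt in enumerate(inst.patients)
                for j, b in enumerate(inst.blocks)
            }

        assignment = Assignment(
            schedule=schedule,
            objective=float(res.fun + q.sum()),
            status=status,
            gap=gap,
            zeta=zeta,
            pi=pi,
        )
        results = SchedulingResults(self, assignment, raw=res)
        results._audit()
        return results


@dataclass
class SchedulingResults:
    """Fitted schedule with diagnostics.

    Attributes
    ----------
    assignment : Assignment
        The schedule, solver-reported objective, status and gap.
    """

    model: AdvanceSchedulingModel
    assignment: Assignment
    raw: object | None = None

    # convenience pass-throughs -------------------------------------------
    @property
    def instance(self) -> Instance:
        return self.model.instance

    @property
    def objective(self) -> float:
        return self.assignment.objective

    @property
    def status(self) -> str:
        return self.assignment.status

    @property
    def gap(self) -> float | None:
        return self.assignment.gap

    @property
    def n_operated(self) -> int:
        return len(self.assignment.operated_ids())

    def _audit(self) -> None:
        """Recompute the objective and (robust) feasibility; raise on mismatch."""
        recomputed = total_objective(self.instance, self.assignment)
        if not math.isclose(
            recomputed, self.assignment.objective, rel_tol=1e-6, abs_tol=1e-6
        ):
            raise RuntimeError(
                f"objective audit failed: solver {self.assignment.objective!r} "
                f"vs recomputed {recomputed!r}"
            )
        self.assignment.objective = recomputed
        if self.model.is_robust:
            audit = verify_robust_feasibility(
                self.instance, self.assignment, self.model.robust
            )
            bad = {b: s for b, (ok, s) in audit.items() if not ok}
            if bad:
                raise RuntimeError(f"robust feasibility audit failed: {bad}")

    def verify_feasibility(
        self, config: RobustConfig | None = None
    ) -> dict[str, tuple[bool, float]]:
        """Worst-case capacity audit of the schedule (default: own config)."""
        cfg = config or self.model.robust or RobustConfig(gamma=0, alpha=0.0)
        return verify_robust_feasibility(self.instance, self.assignment, cfg)

    def metrics(self) -> MetricsReport:
        return compute_metrics(self.instance, self.assignment)

    def simulate(self, n_scenarios: int = 100, base_seed: int = 0):
        """Monte-Carlo evaluation of this schedule (see ``orsched.simulation``)."""
        from .simulation import evaluate_over_scenarios

        return evaluate_over_scenarios(
            self.instance, self.assignment, n_scenarios=n_scenarios, base_seed=base_seed
        )

    def summary(self) -> str:
        cfg = self.model.robust
        head = [
            "Advance Scheduling Results",
            "=" * 60,
            f"model:            {'robust (RAS)' if self.model.is_robust else 'deterministic (DAS)'}",
        ]
        if cfg is not None:
            head.append(f"gamma, alpha:     {cfg.gamma}, {cfg.alpha}")
        head += [
            f"patients, blocks: {len(self.instance.patients)}, {len(self.instance.blocks)}",
            f"status:           {self.status} (gap {self.gap if self.gap is not None else 'n/a'})",
            f"objective (NAWD): {self.objective:.2f}",
            f"operated:         {self.n_operated} / {len(self.instance.patients)}",
            "",
            str(self.metrics()),
        ]
        return "\n".join(head)


def solve_das(
    instance: Instance,
    time_limit: float = DEFAULT_TIME_LIMIT,
    mip_gap: float = DEFAULT_MIP_GAP,
) -> SchedulingResults:
    """Solve the deterministic advance-scheduling model."""
    return AdvanceSchedulingModel(
        instance, robust=None, time_limit=time_limit, mip_gap=mip_gap
    ).fit()


def solve_ras(
    instance: Instance,
    config: RobustConfig,
    time_limit: float = DEFAULT_TIME_LIMIT,
    mip_gap: float = DEFAULT_MIP_GAP,
) -> SchedulingResults:
    """Solve the cardinality-constrained robust advance-scheduling model."""
    return AdvanceSchedulingModel(
        instance, robust=config, time_limit=time_limit, mip_gap=mip_gap
    ).fit()


def max_operated_bound(instance: Instance, time_limit: float = 600.0) -> int:
    """Maximum number of patients schedulable under mean-duration capacities.

    A knapsack-like MILP that maximizes the count of assigned patients,
    ignoring penalties; serves as an upper bound for any DAS/RAS schedule.
    """
    instance.require_durations()
    nI, nJ = len(instance.patients), len(instance.blocks)
    if nI == 0 or nJ == 0:
        return 0
    tbar = np.array([pt.mean_duration for pt in instance.patients])
    c = -np.ones(nI * nJ)
    rows, cols, vals, rhs = [], [], [], []
    r = 0
    for i in range(nI):
        rows += [r] * nJ
        cols += [i * nJ + j for j in range(nJ)]
        vals += [1.0] * nJ
        rhs.append(1.0)
        r += 1
    for j, b in enumerate(instance.blocks):
        rows += [r] * nI
        cols += [i * nJ + j for i in range(nI)]
        vals += list(tbar)
        rhs.append(float(b.capacity))
        r += 1
    a = sparse.csr_array((vals, (rows, cols)), shape=(r, nI * nJ), dtype=float)
    with _quiet_native_stdout():
        res = milp(
            c,
            constraints=LinearConstraint(a, -np.inf, np.array(rhs)),
            integrality=np.ones(nI * nJ),
            bounds=Bounds(0.0, 1.0),
            options={"time_limit": time_limit},
        )
    if res.x is None:
        raise RuntimeError(f"bound MILP failed: {res.message}")
    return int(round(-res.fun))
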