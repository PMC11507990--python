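"""Patient-centric metrics: waiting times, NAWD, tardiness, per urgency class.

Two entry points:

* :func:`initial_list_summary` describes a waiting list before any scheduling
  decision (counts, tardy counts, mean waiting time, NAWD, mean tardiness).
* :func:`compute_metrics` describes the outcome of a schedule, splitting every
  quantity between operated (``*_op``) and still-waiting (``*_sw``) patients.

Conventions used throughout:

* An operated patient's waiting time is ``w + d`` (days already waited plus
  the day of their block); a still-waiting patient's is ``w + D + 1``, the
  earliest they could possibly be operated after the horizon.
* NAWD (need-adjusted waiting days) is the waiting time times the urgency
  coefficient.
* Tardiness averages (``trd``) are taken over tardy patients only; a class
  with no tardy patients has no ``trd`` value (rendered ``-`` in tables).
* Overall rows are count-weighted means of class rows (tardy-count-weighted
  for ``trd``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import Assignment, Instance, urgency_coefficient

__all__ = [
    "ClassAggregate",
    "MetricsReport",
    "compute_metrics",
    "initial_list_summary",
    "summarize_class_aggregates",
]


def _mean(values: Sequence[float]) -> float | None:
    return sum(values) / len(values) if values else None


@dataclass(frozen=True)
class ClassAggregate:
    """Printed-table-level description of one urgency class of a waiting list."""

    class_id: int
    mwt: float
    count: int
    tardy_count: int
    mean_wait: float | None
    mean_tardiness: float | None = None
    #: urgency coefficient; if None it is derived as mwt_max / mwt
    urgency: float | None = None


def summarize_class_aggregates(
    aggregates: Sequence[ClassAggregate], mwt_max: float | None = None
) -> pd.DataFrame:
    """Waiting-list summary table from per-class aggregates.

    Computes, per class: ``p`` (count), ``t_p`` (tardy count), ``t_p/p``,
    ``wt`` (mean waiting days), ``wwt = wt * u`` (NAWD) and ``trd`` (mean
    tardiness of tardy patients), plus a count-weighted ``overall`` row
    (tardy-count-weighted for ``trd``).  This is the aggregation used to
    summarize a list's initial clinical need; it operates on class-level
    numbers so that a published summary table can be fed back in directly.
    """
    if mwt_max is None:
        mwt_max = max(a.mwt for a in aggregates)
    rows = []
    for a in aggregates:
        u = a.urgency if a.urgency is not None else urgency_coefficient(a.mwt, mwt_max)
        rows.append(
            {
                "class": a.class_id,
                "mwt": a.mwt,
                "p": a.count,
                "t_p": a.tardy_count,
                "t_p/p": a.tardy_count / a.count if a.count else None,
                "wt": a.mean_wait,
                "wwt": None if a.mean_wait is None else a.mean_wait * u,
                "trd": a.mean_tardiness,
            }
        )
    n = sum(a.count for a in aggregates)
    n_t = sum(a.tardy_count for a in aggregates)
    overall = {
        "class": "overall",
        "mwt": None,
        "p": n,
        "t_p": n_t,
        "t_p/p": n_t / n if n else None,
        "wt": _wmean([r["wt"] for r in rows], [r["p"] for r in rows]),
        "wwt": _wmean([r["wwt"] for r in rows], [r["p"] for r in rows]),
        "trd": _wmean([r["trd"] for r in rows], [r["t_p"] for r in rows]),
    }
    return pd.DataFrame(rows + [overall])


def _wmean(values: Sequence[float | None], weights: Sequence[float]) -> float | None:
    """Weighted mean ignoring absent values (classes without the quantity)."""
    num = den = 0.0
    for v, w in zip(values, weights):
        if v is not None and w:
            num += v * w
            den += w
    return num / den if den else None


def initial_list_summary(instance: Instance) -> pd.DataFrame:
    """Initial-situation summary of a waiting list (before scheduling)."""
    classes = sorted(
        {p.urgency_class for p in instance.patients}, key=lambda c: c.class_id
    )
    aggs = []
    for c in classes:
        members = [p for p in instance.patients if p.urgency_class == c]
        tardy = [p for p in members if p.tardy_at_start]
        aggs.append(
            ClassAggregate(
                class_id=c.class_id,
                mwt=c.mwt,
                count=len(members),
                tardy_count=len(tardy),
                mean_wait=_mean([p.waited for p in members]),
                mean_tardiness=_mean([p.waited - c.mwt for p in tardy]),
                urgency=c.urgency,
            )
        )
    return summarize_class_aggregates(aggs)


@dataclass
class MetricsReport:
    """Schedule-outcome metrics per urgency class plus an overall row.

    ``frame`` columns: op, sw, op_t, sw_t, t_p/p, wt_op, wt_sw, wwt_op,
    wwt_sw, trd_op, trd_sw.  Absent quantities (no operated patients in a
    class, no tardy patients, ...) are ``NaN`` in the frame and rendered
    ``-`` by :meth:`to_csv`.
    """

    frame: pd.DataFrame

    def row(self, class_id) -> pd.Series:
        return self.frame.set_index("class").loc[class_id]

    @property
    def overall(self) -> pd.Series:
        return self.row("overall")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, na_rep="-")

    def __str__(self) -> str:
        return self.frame.to_string(index=False, na_rep="-", float_format="%.2f")


def compute_metrics(instance: Instance, assignment: Assignment) -> MetricsReport:
    """Per-class operated / still-waiting metrics of a schedule.

    For each class: counts (``op``, ``sw``), tardy counts (``op_t`` tardy at
    surgery, ``sw_t`` tardy at horizon end), waiting times (``wt_op`` mean of
    ``w + d``, ``wt_sw`` mean of ``w + D + 1``), their NAWD versions
    (``wwt_* = mean of wt * u``) and mean tardiness of tardy patients
    (``trd_op``, ``trd_sw``).  The overall row weights class rows by the
    relevant patient counts.
    """
    D = instance.horizon
    block_of = instance._block_index
    classes = sorted(
        {p.urgency_class for p in instance.patients}, key=lambda c: c.class_id
    )
    rows = []
    for c in classes:
        members = [p for p in instance.patients if p.urgency_class == c]
        wt_op, wt_sw, trd_op, trd_sw = [], [], [], []
        n_op = n_sw = 0
        for p in members:
            bid = assignment.schedule.get(p.patient_id)
            if bid is not None:
                d = block_of[bid].day
                n_op += 1
                wt_op.append(p.waited + d)
                t = p.waited + d - c.mwt
                if t > 0:
                    trd_op.append(t)
            else:
                n_sw += 1
                wt_sw.append(p.waited + D + 1)
                t = p.waited + D + 1 - c.mwt
                if t > 0:
                    trd_sw.append(t)
        rows.append(
            {
                "class": c.class_id,
                "mwt": c.mwt,
                "op": n_op,
                "sw": n_sw,
                "op_t": len(trd_op),
                "sw_t": len(trd_sw),
                "t_p/p": (len(trd_op) + len(trd_sw)) / len(members)
                if members
                else None,
                "wt_op": _mean(wt_op),
                "wt_sw": _mean(wt_sw),
                "wwt_op": None if not wt_op else _mean(wt_op) * c.urgency,
                "wwt_sw": None if not wt_sw else _mean(wt_sw) * c.urgency,
                "trd_op": _mean(trd_op),
                "trd_sw": _mean(trd_sw),
            }
        )
    op_w = [r["op"] for r in rows]
    sw_w = [r["sw"] for r in rows]
    overall = {
        "class": "overall",
        "mwt": None,
        "op": sum(op_w),
        "sw": sum(sw_w),
        "op_t": sum(r["op_t"] for r in rows),
        "sw_t": sum(r["sw_t"] for r in rows),
        "t_p/p": (
            (sum(r["op_t"] for r in rows) + sum(r["sw_t"] for r in rows))
            / len(instance.patients)
            if instance.patients
            else None
        ),
        "wt_op": _wmean([r["wt_op"] for r in rows], op_w),
        "wt_sw": _wmean([r["wt_sw"] for r in rows], sw_w),
        "wwt_op": _wmean([r["wwt_op"] for r in rows], op_w),
        "wwt_sw": _wmean([r["wwt_sw"] for r in rows], sw_w),
        "trd_op": _wmean([r["trd_op"] for r in rows], [r["op_t"] for r in rows]),
        "trd_sw": _wmean([r["trd_sw"] for r in rows], [r["sw_t"] for r in rows]),
    }
    return MetricsReport(frame=pd.DataFrame(rows + [overall]))
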