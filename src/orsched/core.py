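"""Domain types and penalty arithmetic for waiting-list surgery scheduling.

The unit of analysis is an :class:`Instance`: a waiting list of elective
patients, each belonging to an urgency class with a mandated Maximum Waiting
Time (MWT), plus a set of operating-room (OR) blocks available within a short
planning horizon (one week by default).  The advance-scheduling models select
a subset of patients and assign each to a block; everything downstream
(optimization, simulation, metrics) consumes these types.

Conventions
-----------
* Durations and block capacities are in **minutes** (a 6-hour block is 360).
* Waiting times, the horizon ``D`` and block days are in **days**.
* The urgency coefficient ``u`` of a class is the ratio of the least urgent
  class's MWT to the class's own MWT, so the least urgent class has ``u = 1``
  and one waiting day for a class counts as ``u`` "need-adjusted" days
  (NAWD — Need-Adjusted Waiting Days).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "UrgencyClass",
    "Patient",
    "ORBlock",
    "Instance",
    "RobustConfig",
    "Assignment",
    "UNSCHEDULED",
    "urgency_coefficient",
    "scheduled_penalty",
    "unscheduled_penalty",
    "total_objective",
    "standard_urgency_classes",
    "STANDARD_MWTS",
]

#: Maximum waiting times (days) of the five-class urgency system, from the
#: most urgent (class 0) to the least urgent (class 4).
STANDARD_MWTS = (8, 30, 60, 180, 360)

#: Marker for a patient left off the schedule.
UNSCHEDULED = None


def urgency_coefficient(mwt: float, mwt_max: float) -> float:
    """Urgency coefficient of a class: ``mwt_max / mwt``.

    ``mwt_max`` is the MWT of the least urgent class, so the least urgent
    class has coefficient exactly 1 and more urgent classes accrue clinical
    need proportionally faster (class with MWT 8 against 360 → 45).

    Raises
    ------
    ValueError
        If ``mwt <= 0`` or ``mwt_max < mwt``.
    """
    if mwt <= 0:
        raise ValueError(f"maximum waiting time must be positive, got {mwt}")
    if mwt_max < mwt:
        raise ValueError(
            f"mwt_max ({mwt_max}) must be at least the class mwt ({mwt})"
        )
    return mwt_max / mwt


@dataclass(frozen=True)
class UrgencyClass:
    """An urgency class: identifier, MWT (days) and urgency coefficient."""

    class_id: int
    mwt: float
    urgency: float

    def __post_init__(self) -> None:
        if self.mwt <= 0:
            raise ValueError("mwt must be positive")
        if self.urgency < 1:
            raise ValueError("urgency coefficient must be >= 1")


def standard_urgency_classes(mwts: Iterable[float] = STANDARD_MWTS) -> list[UrgencyClass]:
    """Build urgency classes from a list of MWTs (most urgent first)."""
    mwts = list(mwts)
    mwt_max = max(mwts)
    return [
        UrgencyClass(class_id=i, mwt=m, urgency=urgency_coefficient(m, mwt_max))
        for i, m in enumerate(mwts)
    ]


@dataclass(frozen=True)
class Patient:
    """A waiting-list entry.

    ``mean_duration``/``sd_duration`` describe the surgery-duration
    distribution in minutes; ``mean_duration`` may be ``None`` for a list
    whose surgery types have not been assigned yet (the optimization and
    simulation layers require it).
    """

    patient_id: str
    waited: int
    urgency_class: UrgencyClass
    mean_duration: float | None = None
    sd_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.waited < 0:
            raise ValueError("waited days must be >= 0")
        if self.mean_duration is not None and self.mean_duration <= 0:
            raise ValueError("mean_duration must be positive")
        if self.sd_duration < 0:
            raise ValueError("sd_duration must be >= 0")

    @property
    def mwt(self) -> float:
        return self.urgency_class.mwt

    @property
    def urgency(self) -> float:
        return self.urgency_class.urgency

    @property
    def tardy_at_start(self) -> bool:
        """Whether the patient already exceeded their MWT (strict: ``w > l``)."""
        return self.waited > self.mwt


@dataclass(frozen=True)
class ORBlock:
    """An operating-room block: capacity in minutes and its day in the horizon."""

    block_id: str
    capacity: float
    day: int

    def __post_init__(self) -> None:
        if self.capacity < 0:
            raise ValueError("capacity must be >= 0")
        if self.day < 1:
            raise ValueError("block day must be >= 1")


@dataclass
class Instance:
    """A waiting list, the available OR blocks, and the horizon length."""

    patients: list[Patient]
    blocks: list[ORBlock]
    horizon: int = 7
    name: str = ""

    def __post_init__(self) -> None:
        pids = [p.patient_id for p in self.patients]
        if len(set(pids)) != len(pids):
            raise ValueError("patient ids must be unique")
        bids = [b.block_id for b in self.blocks]
        if len(set(bids)) != len(bids):
            raise ValueError("block ids must be unique")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for b in self.blocks:
            if b.day > self.horizon:
                raise ValueError(
                    f"block {b.block_id} on day {b.day} exceeds horizon {self.horizon}"
                )

    def patient(self, patient_id: str) -> Patient:
        return self._patient_index[patient_id]

    def block(self, block_id: str) -> ORBlock:
        return self._block_index[block_id]

    @property
    def _patient_index(self) -> dict[str, Patient]:
        return {p.patient_id: p for p in self.patients}

    @property
    def _block_index(self) -> dict[str, ORBlock]:
        return {b.block_id: b for b in self.blocks}

    def require_durations(self) -> None:
        missing = [p.patient_id for p in self.patients if p.mean_duration is None]
        if missing:
            raise ValueError(
                f"patients without surgery durations: {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        classes = sorted(
            {p.urgency_class for p in self.patients}, key=lambda c: c.class_id
        )
        return {
            "name": self.name,
            "horizon": self.horizon,
            "classes": [{"id": c.class_id, "mwt": c.mwt} for c in classes],
            "patients": [
                {
                    "id": p.patient_id,
                    "waited": p.waited,
                    "class": p.urgency_class.class_id,
                    "mean_duration": p.mean_duration,
                    "sd_duration": p.sd_duration,
                }
                for p in self.patients
            ],
            "blocks": [
                {"id": b.block_id, "capacity": b.capacity, "day": b.day}
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Instance":
        mwt_max = max(c["mwt"] for c in data["classes"])
        classes = {
            c["id"]: UrgencyClass(
                class_id=c["id"],
                mwt=c["mwt"],
                urgency=urgency_coefficient(c["mwt"], mwt_max),
            )
            for c in data["classes"]
        }
        patients = [
            Patient(
                patient_id=str(p["id"]),
                waited=int(p["waited"]),
                urgency_class=classes[p["class"]],
                mean_duration=p.get("mean_duration"),
                sd_duration=float(p.get("sd_duration", 0.0)),
            )
            for p in data["patients"]
        ]
        blocks = [
            ORBlock(block_id=str(b["id"]), capacity=float(b["capacity"]), day=int(b["day"]))
            for b in data["blocks"]
        ]
        return cls(
            patients=patients,
            blocks=blocks,
            horizon=int(data.get("horizon", 7)),
            name=data.get("name", ""),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "Instance":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def patients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.patient_id for p in self.patients],
                "waited": [p.waited for p in self.patients],
                "class": [p.urgency_class.class_id for p in self.patients],
                "mwt": [p.mwt for p in self.patients],
                "urgency": [p.urgency for p in self.patients],
                "mean_duration": [p.mean_duration for p in self.patients],
                "sd_duration": [p.sd_duration for p in self.patients],
            }
        )

    def blocks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [b.block_id for b in self.blocks],
                "capacity": [b.capacity for b in self.blocks],
                "day": [b.day for b in self.blocks],
            }
        )

    def save_csv(self, directory: str | Path) -> None:
        """CSV twin of the JSON schema: patients.csv, blocks.csv, meta.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.patients_frame().to_csv(directory / "patients.csv", index=False)
        self.blocks_frame().to_csv(directory / "blocks.csv", index=False)
        (directory / "meta.json").write_text(
            json.dumps({"name": self.name, "horizon": self.horizon})
        )

    @classmethod
    def load_csv(cls, directory: str | Path) -> "Instance":
        directory = Path(directory)
        pf = pd.read_csv(directory / "patients.csv")
        bf = pd.read_csv(directory / "blocks.csv")
        meta = json.loads((directory / "meta.json").read_text())
        classes = [
            {"id": int(cid), "mwt": float(mwt)}
            for cid, mwt in pf[["class", "mwt"]].drop_duplicates().itertuples(index=False)
        ]
        data = {
            "name": meta.get("name", ""),
            "horizon": meta.get("horizon", 7),
            "classes": classes,
            "patients": [
                {
                    "id": row["id"],
                    "waited": row["waited"],
                    "class": row["class"],
                    "mean_duration": None
                    if pd.isna(row["mean_duration"])
                    else row["mean_duration"],
                    "sd_duration": row["sd_duration"],
                }
                for _, row in pf.iterrows()
            ],
            "blocks": [
                {"id": row["id"], "capacity": row["capacity"], "day": row["day"]}
                for _, row in bf.iterrows()
            ],
        }
        return cls.from_dict(data)


@dataclass(frozen=True)
class RobustConfig:
    """Robustness parameters of the cardinality-constrained model.

    ``gamma`` (Γ) is the uncertainty budget: the number of patients per block
    assumed to simultaneously require their maximum surgery time.  ``alpha``
    (α) scales each patient's maximum deviation: ``t_hat = alpha * sd``.
    ``gamma = 0`` or ``alpha = 0`` collapses the robust model onto the
    deterministic one.
    """

    gamma: int = 0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0 or int(self.gamma) != self.gamma:
            raise ValueError("gamma must be a nonnegative integer")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def deviation(self, patient: Patient) -> float:
        """Maximum duration deviation ``t_hat = alpha * sd`` (minutes)."""
        return self.alpha * patient.sd_duration


# ---------------------------------------------------------------------------
# Penalty arithmetic
# ---------------------------------------------------------------------------

def scheduled_penalty(patient: Patient, block: ORBlock) -> float:
    """Penalty of operating ``patient`` in ``block``.

    ``p = [d + (w + d - l)+] * u``: the days waited within the horizon plus
    the tardiness at surgery, both weighted by the urgency coefficient.
    """
    d, w, l, u = block.day, patient.waited, patient.mwt, patient.urgency
    return (d + max(w + d - l, 0.0)) * u


def unscheduled_penalty(patient: Patient, horizon: int) -> float:
    """Penalty of leaving ``patient`` off the schedule.

    The earliest an unscheduled patient can be operated is day ``D + 1``, so
    ``q = [(w + D + 1) + (w + D + 1 - l)+] * u`` — a lower bound on their
    eventual weighted waiting plus tardiness.  Note the full waited time
    enters here (unlike ``p``, which charges only in-horizon days), which
    keeps long-waiting patients from being deferred indefinitely.
    """
    w, l, u = patient.waited, patient.mwt, patient.urgency
    e = w + horizon + 1
    return (e + max(e - l, 0.0)) * u


@dataclass
class Assignment:
    """A schedule: each patient mapped to a block id or ``None`` (unscheduled).

    Carries the solver-reported objective, status and relative MIP gap, plus
    (for robust solves) the dual auxiliaries ``zeta`` (per block) and ``pi``
    (per patient-block pair) of the linearized worst-case capacity terms.
    """

    schedule: dict[str, str | None]
    objective: float = float("nan")
    status: str = "optimal"
    gap: float | None = None
    zeta: dict[str, float] | None = None
    pi: dict[tuple[str, str], float] | None = None

    def operated_ids(self) -> list[str]:
        return [pid for pid, bid in self.schedule.items() if bid is not None]

    def unscheduled_ids(self) -> list[str]:
        return [pid for pid, bid in self.schedule.items() if bid is None]

    def block_patients(self, instance: Instance) -> dict[str, list[str]]:
        """Patient ids per block (blocks with nobody scheduled included)."""
        out: dict[str, list[str]] = {b.block_id: [] for b in instance.blocks}
        for pid, bid in self.schedule.items():
            if bid is not None:
                if bid not in out:
                    raise ValueError(f"assignment references unknown block {bid!r}")
                out[bid].append(pid)
        return out

    def to_dict(self) -> dict:
        return {
            "schedule": self.schedule,
            "objective": self.objective,
            "status": self.status,
            "gap": self.gap,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "Assignment":
        d = json.loads(Path(path).read_text())
        return cls(
            schedule=dict(d["schedule"]),
            objective=d.get("objective", float("nan")),
            status=d.get("status", "optimal"),
            gap=d.get("gap"),
        )


def total_objective(instance: Instance, assignment: Assignment) -> float:
    """Recompute the penalty objective of a schedule from first principles.

    Sum of ``scheduled_penalty`` over operated patients plus
    ``unscheduled_penalty`` over the rest.  Used to audit solver output
    against the model's own arithmetic.

    Raises
    ------
    ValueError
        If the assignment references an unknown patient or block, or a
        patient of the instance is missing from the schedule.
    """
    blocks = instance._block_index
    total = 0.0
    for p in instance.patients:
        if p.patient_id not in assignment.schedule:
            raise ValueError(f"patient {p.patient_id!r} missing from assignment")
        bid = assignment.schedule[p.patient_id]
        if bid is None:
            total += unscheduled_penalty(p, instance.horizon)
        else:
            if bid not in blocks:
                raise ValueError(f"assignment references unknown block {bid!r}")
            total += scheduled_penalty(p, blocks[bid])
    unknown = set(assignment.schedule) - set(instance._patient_index)
    if unknown:
        raise ValueError(f"assignment references unknown patients {sorted(unknown)[:5]}")
    return total
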