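"""Synthetic waiting lists and surgery-time sets.

Real elective waiting lists carry only aggregate descriptions in published
summaries: per urgency class, the patient count, the number already tardy,
and the average waited time.  The generator reproduces exactly that
structure: tardy counts are matched exactly (a tardy patient has waited
strictly more than the class MWT) and the class mean waited time is matched
to the nearest achievable integer total, via a two-piece uniform draw
(non-tardy mass on ``[0, mwt]``, tardy mass above it) followed by bounded
integer adjustments.

Surgery-time sets mirror the usual description of a case mix: a handful of
surgery types, each with a mean duration, a standard deviation and a
frequency.  Eight bundled synthetic sets span coefficients of variation from
0.1 to 0.6 and mean case lengths from ~70 to ~115 minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .core import (
    Instance,
    ORBlock,
    Patient,
    UrgencyClass,
    standard_urgency_classes,
)

__all__ = [
    "SurgeryType",
    "SurgeryTimeSet",
    "ClassProfile",
    "ListProfile",
    "InfeasibleProfileError",
    "generate_waiting_list",
    "assign_surgery_times",
    "benchmark_suite",
    "default_time_sets",
    "PROFILE_20",
    "PROFILE_40",
]


class InfeasibleProfileError(ValueError):
    """The requested class aggregates cannot be realized with integer waits."""


@dataclass(frozen=True)
class SurgeryType:
    mean_duration: float
    sd_duration: float
    frequency: float


@dataclass(frozen=True)
class SurgeryTimeSet:
    """A case mix: surgery types with mean/SD durations and frequencies."""

    name: str
    types: tuple[SurgeryType, ...]

    def __post_init__(self) -> None:
        if not self.types:
            raise ValueError("a surgery-time set needs at least one type")
        tot = sum(t.frequency for t in self.types)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"type frequencies must sum to 1, got {tot}")
        for t in self.types:
            if t.mean_duration <= 0 or t.sd_duration < 0 or t.frequency < 0:
                raise ValueError("invalid surgery type parameters")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "types": [
                {"mean": t.mean_duration, "sd": t.sd_duration, "frequency": t.frequency}
                for t in self.types
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurgeryTimeSet":
        return cls(
            name=d.get("name", ""),
            types=tuple(
                SurgeryType(t["mean"], t["sd"], t["frequency"]) for t in d["types"]
            ),
        )


@dataclass(frozen=True)
class ClassProfile:
    """Aggregate description of one urgency class of a waiting list."""

    urgency_class: UrgencyClass
    count: int
    tardy_count: int
    mean_waited: float

    def __post_init__(self) -> None:
        if self.count < 0 or self.tardy_count < 0 or self.tardy_count > self.count:
            raise ValueError("need 0 <= tardy_count <= count")
        if self.count and self.mean_waited < 0:
            raise ValueError("mean_waited must be >= 0")


@dataclass(frozen=True)
class ListProfile:
    """Aggregate description of a full waiting list plus the block setup."""

    classes: tuple[ClassProfile, ...]
    horizon: int = 7
    n_blocks: int = 2
    block_capacity: float = 360.0
    name: str = ""

    @property
    def n_patients(self) -> int:
        return sum(c.count for c in self.classes)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon": self.horizon,
            "n_blocks": self.n_blocks,
            "block_capacity": self.block_capacity,
            "classes": [
                {
                    "id": c.urgency_class.class_id,
                    "mwt": c.urgency_class.mwt,
                    "count": c.count,
                    "tardy_count": c.tardy_count,
                    "mean_waited": c.mean_waited,
                }
                for c in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ListProfile":
        mwts = [c["mwt"] for c in d["classes"]]
        ucs = standard_urgency_classes(mwts)
        return cls(
            name=d.get("name", ""),
            horizon=int(d.get("horizon", 7)),
            n_blocks=int(d.get("n_blocks", 2)),
            block_capacity=float(d.get("block_capacity", 360.0)),
            classes=tuple(
                ClassProfile(
                    urgency_class=uc,
                    count=int(c["count"]),
                    tardy_count=int(c["tardy_count"]),
                    mean_waited=float(c["mean_waited"]),
                )
                for uc, c in zip(ucs, d["classes"])
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ListProfile":
        """Load from a YAML or JSON profile config."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


def _waits_for_class(cp: ClassProfile, rng: np.random.Generator) -> np.ndarray:
    """Integer waited days matching the tardy count exactly and the mean closely."""
    n, k, mwt = cp.count, cp.tardy_count, int(cp.urgency_class.mwt)
    if n == 0:
        return np.zeros(0, dtype=int)
    target_sum = int(round(n * cp.mean_waited))
    lo = np.concatenate([np.zeros(n - k, dtype=int), np.full(k, mwt + 1, dtype=int)])
    # generous upper bound for tardy waits so large targets stay reachable
    hi_t = max(mwt + 1, 2 * mwt, target_sum)
    hi = np.concatenate([np.full(n - k, mwt, dtype=int), np.full(k, hi_t, dtype=int)])
    if not (lo.sum() <= target_sum <= hi.sum()):
        raise InfeasibleProfileError(
            f"class {cp.urgency_class.class_id}: mean {cp.mean_waited} with "
            f"{k}/{n} tardy is unreachable (sum bounds [{lo.sum()}, {hi.sum()}])"
        )
    w = rng.integers(lo, hi + 1)
    delta = target_sum - int(w.sum())
    order = rng.permutation(n)
    for idx in order:
        if delta == 0:
            break
        if delta > 0:
            step = min(delta, int(hi[idx] - w[idx]))
            w[idx] += step
            delta -= step
        else:
            step = min(-delta, int(w[idx] - lo[idx]))
            w[idx] -= step
            delta += step
    if delta != 0:  # bounds were checked, so this cannot trigger
        raise InfeasibleProfileError("could not match the class mean")
    return np.asarray(w, dtype=int)


def generate_waiting_list(profile: ListProfile, seed: int) -> Instance:
    """Generate a waiting list (durations unassigned) from class aggregates.

    Tardy counts are matched exactly; each class's realized mean waited time
    equals the target up to integer rounding of the class total (well inside
    10%).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    patients: list[Patient] = []
    for cp in profile.classes:
        waits = _waits_for_class(cp, rng)
        cid = cp.urgency_class.class_id
        for k, w in enumerate(waits):
            patients.append(
                Patient(
                    patient_id=f"c{cid}p{k}",
                    waited=int(w),
                    urgency_class=cp.urgency_class,
                )
            )
    blocks = [
        ORBlock(block_id=f"b{j + 1}", capacity=profile.block_capacity, day=j + 1)
        for j in range(profile.n_blocks)
    ]
    return Instance(
        patients=patients, blocks=blocks, horizon=profile.horizon, name=profile.name
    )


def assign_surgery_times(
    instance: Instance, time_set: SurgeryTimeSet, seed: int
) -> Instance:
    """Draw a surgery type per patient with the set's frequencies."""
    rng = np.random.default_rng(seed)
    freqs = np.array([t.frequency for t in time_set.types])
    picks = rng.choice(len(time_set.types), size=len(instance.patients), p=freqs)
    patients = [
        Patient(
            patient_id=p.patient_id,
            waited=p.waited,
            urgency_class=p.urgency_class,
            mean_duration=time_set.types[k].mean_duration,
            sd_duration=time_set.types[k].sd_duration,
        )
        for p, k in zip(instance.patients, picks)
    ]
    name = f"{instance.name}-{time_set.name}" if instance.name else time_set.name
    return Instance(
        patients=patients, blocks=list(instance.blocks), horizon=instance.horizon, name=name
    )


# ---------------------------------------------------------------------------
# Bundled study-like profiles and case mixes
# ---------------------------------------------------------------------------

def _profile(name, n_blocks, rows) -> ListProfile:
    ucs = standard_urgency_classes()
    return ListProfile(
        name=name,
        horizon=7,
        n_blocks=n_blocks,
        block_capacity=360.0,
        classes=tuple(
            ClassProfile(uc, count=c, tardy_count=t, mean_waited=m)
            for uc, (c, t, m) in zip(ucs, rows)
        ),
    )


#: 20-patient list, two 6-hour blocks per week: per class (count, tardy, mean wait).
PROFILE_20 = _profile(
    "20",
    2,
    [(1, 0, 6.0), (6, 3, 34.0), (8, 3, 66.75), (4, 2, 173.75), (1, 0, 338.0)],
)

#: 40-patient list, three 6-hour blocks per week.
PROFILE_40 = _profile(
    "40",
    3,
    [(1, 1, 12.0), (8, 4, 38.88), (26, 4, 44.04), (3, 1, 158.33), (2, 0, 334.5)],
)

#: Large-list profiles for scalability runs (counts scaled from the 40-patient mix).
LARGE_PROFILES = {
    (n, b): _profile(
        str(n),
        b,
        [
            (max(1, round(n * 0.025)), 1, 12.0),
            (round(n * 0.2), round(n * 0.1), 38.88),
            (round(n * 0.65), round(n * 0.1), 44.04),
            (round(n * 0.075), 1, 158.33),
            (round(n * 0.05), 0, 334.5),
        ],
    )
    for n in (80, 120, 140)
    for b in (3, 5)
}


def default_time_sets() -> list[SurgeryTimeSet]:
    """Eight bundled synthetic case mixes.

    Set ``s`` (1..8) scales four base case types (50/80/120/180 minutes at
    frequencies 0.30/0.35/0.25/0.10) by a factor rising from 0.75 to 1.25 and
    uses a coefficient of variation rising from 0.1 to 0.6, so the suite
    spans both light/heavy case loads and low/high duration variability.
    """
    base = [(50.0, 0.30), (80.0, 0.35), (120.0, 0.25), (180.0, 0.10)]
    sets = []
    for s in range(1, 9):
        f = 0.75 + 0.5 * (s - 1) / 7.0
        cv = 0.1 + 0.5 * (s - 1) / 7.0
        sets.append(
            SurgeryTimeSet(
                name=str(s),
                types=tuple(
                    SurgeryType(
                        mean_duration=round(f * m, 1),
                        sd_duration=round(cv * f * m, 1),
                        frequency=fr,
                    )
                    for m, fr in base
                ),
            )
        )
    return sets


def benchmark_suite(seed: int = 0, large: bool = False) -> list[Instance]:
    """The synthetic benchmark suite: ``n-s`` instances.

    Two waiting lists (20 patients / 2 blocks and 40 patients / 3 blocks,
    7-day horizon, 360-minute blocks) each combined with the eight bundled
    surgery-time sets — 16 instances named ``20-1`` .. ``40-8``.  With
    ``large=True``, adds 80/120/140-patient lists with 3 and 5 blocks.
    """
    profiles = [PROFILE_20, PROFILE_40]
    if large:
        profiles += list(LARGE_PROFILES.values())
    sets = default_time_sets()
    out = []
    for k, prof in enumerate(profiles):
        base = generate_waiting_list(prof, seed=seed + k)
        for s, ts in enumerate(sets):
            inst = assign_surgery_times(base, ts, seed=seed + 1000 + 100 * k + s)
            if prof not in (PROFILE_20, PROFILE_40):
                inst.name = f"{prof.name}b{prof.n_blocks}-{ts.name}"
            out.append(inst)
    return out
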