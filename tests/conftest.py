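import numpy as np
import pytest

from orsched.core import (
    Instance,
    ORBlock,
    Patient,
    UrgencyClass,
    standard_urgency_classes,
    urgency_coefficient,
)

CLASSES = {c.class_id: c for c in standard_urgency_classes()}


def make_patient(pid, waited, class_id, mean=None, sd=0.0):
    return Patient(
        patient_id=pid,
        waited=waited,
        urgency_class=CLASSES[class_id],
        mean_duration=mean,
        sd_duration=sd,
    )


def make_class(mwt, mwt_max=360):
    return UrgencyClass(class_id=0, mwt=mwt, urgency=urgency_coefficient(mwt, mwt_max))


@pytest.fixture
def classes():
    return CLASSES


@pytest.fixture
def tiny_instance():
    """Two patients competing for one block that fits only one of them."""
    return Instance(
        patients=[
            make_patient("a", waited=10, class_id=2, mean=200.0, sd=20.0),
            make_patient("b", waited=10, class_id=2, mean=200.0, sd=20.0),
        ],
        blocks=[ORBlock("b1", capacity=360.0, day=1)],
        horizon=7,
    )


def random_instance(rng, n_patients=None, n_blocks=2, capacity=360.0, with_sd=True):
    """A small random instance for oracle-equivalence runs."""
    n = n_patients or int(rng.integers(3, 9))
    patients = []
    for i in range(n):
        cid = int(rng.integers(0, 5))
        mwt = CLASSES[cid].mwt
        waited = int(rng.integers(0, int(1.5 * mwt) + 1))
        mean = float(rng.integers(60, 260))
        sd = float(rng.integers(0, 80)) if with_sd else 0.0
        patients.append(make_patient(f"p{i}", waited, cid, mean=mean, sd=sd))
    blocks = [
        ORBlock(f"b{j}", capacity=capacity, day=j + 1) for j in range(n_blocks)
    ]
    return Instance(patients=patients, blocks=blocks, horizon=7)
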