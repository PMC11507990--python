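"""Urgency arithmetic, penalty formulas and instance serialization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orsched.core import (
    Assignment,
    Instance,
    ORBlock,
    RobustConfig,
    scheduled_penalty,
    standard_urgency_classes,
    total_objective,
    unscheduled_penalty,
    urgency_coefficient,
)

from conftest import make_patient


class TestUrgencyCoefficient:
    @pytest.mark.parametrize(
        "mwt,mwt_max,expected",
        [(8, 360, 45.0), (30, 360, 12.0), (60, 360, 6.0), (180, 360, 2.0), (360, 360, 1.0)],
    )
    def test_five_class_system(self, mwt, mwt_max, expected):
        assert urgency_coefficient(mwt, mwt_max) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            urgency_coefficient(0, 360)
        with pytest.raises(ValueError):
            urgency_coefficient(-5, 360)
        with pytest.raises(ValueError):
            urgency_coefficient(400, 360)

    def test_least_urgent_is_one_and_nonincreasing_in_mwt(self):
        classes = standard_urgency_classes()
        assert classes[-1].urgency == 1.0
        urgencies = [c.urgency for c in classes]
        assert urgencies == sorted(urgencies, reverse=True)


class TestPenalties:
    def test_scheduled_penalty_tardy(self):
        # (d + (w + d - l)+) * u = (3 + 7) * 12
        p = make_patient("x", waited=34, class_id=1)
        b = ORBlock("b", capacity=360, day=3)
        assert scheduled_penalty(p, b) == 120.0

    def test_scheduled_penalty_not_tardy(self):
        p = make_patient("x", waited=0, class_id=2)
        b = ORBlock("b", capacity=360, day=2)
        assert scheduled_penalty(p, b) == 12.0

    def test_scheduled_penalty_boundary(self):
        # w + d == l exactly: tardiness term vanishes
        p = make_patient("x", waited=27, class_id=1)
        b = ORBlock("b", capacity=360, day=3)
        assert scheduled_penalty(p, b) == 3 * 12.0

    @pytest.mark.parametrize(
        "waited,class_id,expected",
        [(34, 1, 648.0), (0, 4, 8.0), (6, 0, 900.0)],
    )
    def test_unscheduled_penalty(self, waited, class_id, expected):
        p = make_patient("x", waited=waited, class_id=class_id)
        assert unscheduled_penalty(p, horizon=7) == expected

    @given(
        waited=st.integers(0, 500),
        day=st.integers(1, 7),
        class_id=st.integers(0, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_scheduled_at_least_day_times_urgency(self, waited, day, class_id):
        """p >= d*u, equality exactly when the patient is not tardy at surgery."""
        p = make_patient("x", waited=waited, class_id=class_id)
        b = ORBlock("b", capacity=360, day=day)
        pen = scheduled_penalty(p, b)
        assert pen >= day * p.urgency - 1e-12
        if waited + day <= p.mwt:
            assert pen == day * p.urgency
        else:
            assert pen > day * p.urgency

    @given(waited=st.integers(0, 500), day=st.integers(1, 7), class_id=st.integers(0, 4))
    @settings(max_examples=200, deadline=None)
    def test_being_scheduled_never_costs_more_than_waiting(self, waited, day, class_id):
        """q > p for any in-horizon block: scheduling a patient always helps."""
        p = make_patient("x", waited=waited, class_id=class_id)
        b = ORBlock("b", capacity=360, day=day)
        assert unscheduled_penalty(p, horizon=7) > scheduled_penalty(p, b)


class TestTotalObjective:
    def test_empty_schedule_sums_q(self):
        pats = [make_patient(f"p{i}", waited=10 * i, class_id=i, mean=60.0) for i in range(5)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360, 1)], horizon=7)
        asg = Assignment(schedule={p.patient_id: None for p in pats})
        expected = sum(unscheduled_penalty(p, 7) for p in pats)
        assert total_objective(inst, asg) == expected

    def test_single_scheduled_decomposition(self):
        pats = [make_patient(f"p{i}", waited=20, class_id=2, mean=60.0) for i in range(3)]
        b = ORBlock("b", 360, 2)
        inst = Instance(patients=pats, blocks=[b], horizon=7)
        asg = Assignment(schedule={"p0": "b", "p1": None, "p2": None})
        q_sum = sum(unscheduled_penalty(p, 7) for p in pats)
        expected = q_sum - unscheduled_penalty(pats[0], 7) + scheduled_penalty(pats[0], b)
        assert math.isclose(total_objective(inst, asg), expected)

    def test_unknown_block_raises(self):
        pats = [make_patient("p0", waited=0, class_id=2, mean=60.0)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360, 1)], horizon=7)
        with pytest.raises(ValueError, match="unknown block"):
            total_objective(inst, Assignment(schedule={"p0": "nope"}))

    def test_missing_patient_raises(self):
        pats = [make_patient("p0", waited=0, class_id=2, mean=60.0)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360, 1)], horizon=7)
        with pytest.raises(ValueError, match="missing"):
            total_objective(inst, Assignment(schedule={}))


class TestInstanceValidation:
    def test_duplicate_patient_ids(self):
        pats = [make_patient("p", 0, 2, mean=60.0), make_patient("p", 1, 2, mean=60.0)]
        with pytest.raises(ValueError, match="unique"):
            Instance(patients=pats, blocks=[ORBlock("b", 360, 1)])

    def test_block_day_beyond_horizon(self):
        with pytest.raises(ValueError, match="horizon"):
            Instance(patients=[], blocks=[ORBlock("b", 360, 9)], horizon=7)

    def test_robust_config_validation(self):
        with pytest.raises(ValueError):
            RobustConfig(gamma=-1)
        with pytest.raises(ValueError):
            RobustConfig(gamma=1, alpha=-0.5)
        cfg = RobustConfig(gamma=2, alpha=1.5)
        assert cfg.deviation(make_patient("x", 0, 2, mean=60.0, sd=10.0)) == 15.0


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        pats = [
            make_patient("p0", 5, 0, mean=100.0, sd=10.0),
            make_patient("p1", 40, 1, mean=80.0, sd=5.0),
        ]
        inst = Instance(
            patients=pats,
            blocks=[ORBlock("b1", 360, 1), ORBlock("b2", 360, 3)],
            horizon=7,
            name="demo",
        )
        path = tmp_path / "inst.json"
        inst.save_json(path)
        back = Instance.load_json(path)
        assert back.name == "demo"
        assert back.to_dict() == inst.to_dict()

    def test_csv_round_trip(self, tmp_path):
        pats = [make_patient("p0", 5, 0, mean=100.0, sd=10.0)]
        inst = Instance(patients=pats, blocks=[ORBlock("b1", 360, 2)], horizon=7, name="d")
        inst.save_csv(tmp_path)
        back = Instance.load_csv(tmp_path)
        assert back.to_dict() == inst.to_dict()

    def test_assignment_round_trip(self, tmp_path):
        asg = Assignment(schedule={"p0": "b1", "p1": None}, objective=12.5, status="optimal", gap=0.0)
        path = tmp_path / "asg.json"
        asg.save_json(path)
        back = Assignment.load_json(path)
        assert back.schedule == asg.schedule
        assert back.objective == 12.5
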