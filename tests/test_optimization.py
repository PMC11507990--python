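"""DAS/RAS solves against the brute-force oracle, robust auditing, bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orsched.core import Assignment, Instance, ORBlock, RobustConfig, total_objective
from orsched.model import (
    AdvanceSchedulingModel,
    duality_gap_check,
    max_operated_bound,
    robust_worst_case_load,
    solve_das,
    solve_ras,
    verify_robust_feasibility,
)

from conftest import make_patient, random_instance
from _oracle import oracle_optimum, oracle_worst_case_enum


class TestWorstCaseLoad:
    def test_example(self):
        pts = [(60, 10), (50, 20), (40, 5)]
        assert robust_worst_case_load(pts, 2) == 180.0

    def test_gamma_zero_is_mean_load(self):
        pts = [(60, 10), (50, 20)]
        assert robust_worst_case_load(pts, 0) == 110.0

    def test_gamma_at_least_n_adds_all_deviations(self):
        pts = [(60, 10), (50, 20), (40, 5)]
        assert robust_worst_case_load(pts, 7) == 150.0 + 35.0

    @given(
        pairs=st.lists(
            st.tuples(st.floats(1, 300), st.floats(0, 100)), min_size=0, max_size=6
        ),
        gamma=st.integers(0, 6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_subset_enumeration(self, pairs, gamma):
        closed = robust_worst_case_load(pairs, gamma)
        brute = oracle_worst_case_enum(pairs, gamma)
        assert closed == pytest.approx(brute)


class TestDualityGapCheck:
    def test_closed_form_example(self):
        # deviations (10, 20, 5), gamma 2 -> inner optimum 30
        assert duality_gap_check([10.0, 20.0, 5.0], gamma=2, zeta=10.0, pi=[0.0, 10.0, 0.0])

    def test_all_zero_deviations(self):
        assert duality_gap_check([0.0, 0.0], gamma=1, zeta=0.0, pi=[0.0, 0.0])

    def test_gamma_equals_n(self):
        that = [7.0, 3.0, 11.0]
        assert duality_gap_check(that, gamma=3, zeta=0.0, pi=that)

    def test_infeasible_duals_raise(self):
        with pytest.raises(ValueError, match="violated"):
            duality_gap_check([10.0], gamma=1, zeta=2.0, pi=[1.0])
        with pytest.raises(ValueError, match="nonnegative"):
            duality_gap_check([10.0], gamma=1, zeta=-1.0, pi=[11.0])


class TestDeterministicSolve:
    def test_capacity_admits_exactly_one(self, tiny_instance):
        res = solve_das(tiny_instance)
        assert res.n_operated == 1
        assert res.status == "optimal"

    def test_zero_capacity_blocks_leave_all_unscheduled(self):
        pats = [make_patient(f"p{i}", 10, 2, mean=60.0) for i in range(3)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 0.0, 1)], horizon=7)
        res = solve_das(inst)
        assert res.n_operated == 0
        empty = Assignment(schedule={p.patient_id: None for p in pats})
        assert res.objective == pytest.approx(total_objective(inst, empty))

    def test_objective_matches_recompute(self, tiny_instance):
        res = solve_das(tiny_instance)
        assert res.objective == pytest.approx(
            total_objective(tiny_instance, res.assignment), rel=1e-6
        )

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            inst = random_instance(rng, n_patients=int(rng.integers(3, 7)))
            res = solve_das(inst)
            opt, _ = oracle_optimum(inst, gamma=0)
            assert res.objective == pytest.approx(opt, rel=1e-9, abs=1e-6)


class TestRobustSolve:
    def test_gamma_zero_equals_das(self, tiny_instance):
        das = solve_das(tiny_instance)
        ras = solve_ras(tiny_instance, RobustConfig(gamma=0, alpha=1.0))
        assert ras.objective == pytest.approx(das.objective)

    def test_alpha_zero_equals_das(self, tiny_instance):
        das = solve_das(tiny_instance)
        ras = solve_ras(tiny_instance, RobustConfig(gamma=3, alpha=0.0))
        assert ras.objective == pytest.approx(das.objective)

    def test_matches_bruteforce_with_oracle_feasibility(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            inst = random_instance(rng, n_patients=int(rng.integers(3, 7)))
            gamma = int(rng.integers(1, 4))
            res = solve_ras(inst, RobustConfig(gamma=gamma, alpha=1.0))
            opt, _ = oracle_optimum(inst, gamma=gamma, alpha=1.0)
            assert res.objective == pytest.approx(opt, rel=1e-9, abs=1e-6)

    def test_solution_passes_own_feasibility_audit(self):
        rng = np.random.default_rng(3)
        inst = random_instance(rng, n_patients=8)
        cfg = RobustConfig(gamma=2, alpha=1.5)
        res = solve_ras(inst, cfg)
        audit = verify_robust_feasibility(inst, res.assignment, cfg)
        assert all(ok for ok, _ in audit.values())

    def test_das_solution_fails_robust_audit_on_tight_instance(self):
        # block packed exactly at mean capacity, positive deviations
        pats = [make_patient(f"p{i}", 50, 1, mean=120.0, sd=30.0) for i in range(3)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360.0, 1)], horizon=7)
        das = solve_das(inst)
        assert das.n_operated == 3
        audit = verify_robust_feasibility(inst, das.assignment, RobustConfig(gamma=2, alpha=1.0))
        ok, slack = audit["b"]
        assert not ok and slack == pytest.approx(-60.0)

    def test_empty_schedule_feasible_with_full_slack(self):
        pats = [make_patient("p", 10, 2, mean=60.0, sd=10.0)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360.0, 1)], horizon=7)
        audit = verify_robust_feasibility(
            inst, Assignment(schedule={"p": None}), RobustConfig(gamma=2, alpha=1.0)
        )
        assert audit["b"] == (True, 360.0)

    def test_objective_monotone_in_gamma_and_alpha(self):
        rng = np.random.default_rng(11)
        inst = random_instance(rng, n_patients=8, n_blocks=2)
        for alpha in (0.5, 1.0, 2.0):
            objs = [
                solve_ras(inst, RobustConfig(gamma=g, alpha=alpha)).objective
                for g in range(0, 5)
            ]
            assert all(b >= a - 1e-6 for a, b in zip(objs, objs[1:]))
        for gamma in (1, 2):
            objs = [
                solve_ras(inst, RobustConfig(gamma=gamma, alpha=a)).objective
                for a in (0.0, 0.5, 1.0, 2.0)
            ]
            assert all(b >= a - 1e-6 for a, b in zip(objs, objs[1:]))

    def test_saturation_after_max_block_count(self):
        """Once gamma >= patients per block, growing it changes nothing."""
        pats = [make_patient(f"p{i}", 20, 2, mean=100.0, sd=25.0) for i in range(6)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360.0, 1)], horizon=7)
        objs = {
            g: solve_ras(inst, RobustConfig(gamma=g, alpha=1.0)).objective
            for g in range(0, 7)
        }
        # at most 3 patients fit a block even deterministically
        assert objs[4] == pytest.approx(objs[3])
        assert objs[6] == pytest.approx(objs[3])


class TestMaxOperatedBound:
    def test_single_block_floor(self):
        pats = [make_patient(f"p{i}", 0, 2, mean=100.0) for i in range(4)]
        inst = Instance(patients=pats, blocks=[ORBlock("b", 360.0, 1)], horizon=7)
        assert max_operated_bound(inst) == 3

    def test_two_blocks_two_hundreds(self):
        pats = [make_patient(f"p{i}", 0, 2, mean=200.0) for i in range(4)]
        inst = Instance(
            patients=pats,
            blocks=[ORBlock("b1", 360.0, 1), ORBlock("b2", 360.0, 2)],
            horizon=7,
        )
        assert max_operated_bound(inst) == 2

    def test_matches_enumeration_and_bounds_solutions(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            inst = random_instance(rng, n_patients=int(rng.integers(4, 9)))
            bound = max_operated_bound(inst)
            # enumeration maximum
            best = 0
            import itertools

            nJ = len(inst.blocks)
            for choice in itertools.product(range(nJ + 1), repeat=len(inst.patients)):
                loads = [0.0] * nJ
                ok = True
                for i, c in enumerate(choice):
                    if c < nJ:
                        loads[c] += inst.patients[i].mean_duration
                if all(l <= b.capacity + 1e-9 for l, b in zip(loads, inst.blocks)):
                    best = max(best, sum(1 for c in choice if c < nJ))
            assert bound == best
            assert solve_das(inst).n_operated <= bound
            assert (
                solve_ras(inst, RobustConfig(gamma=2, alpha=1.0)).n_operated <= bound
            )


class TestResultsObject:
    def test_summary_contains_key_facts(self, tiny_instance):
        res = AdvanceSchedulingModel(tiny_instance, robust=RobustConfig(2, 1.0)).fit()
        text = res.summary()
        assert "robust (RAS)" in text
        assert "objective" in text
        assert "gamma" in text

    def test_duals_present_for_robust(self, tiny_instance):
        res = solve_ras(tiny_instance, RobustConfig(gamma=1, alpha=1.0))
        assert res.assignment.zeta is not None
        assert res.assignment.pi is not None
        # duals certify the worst-case term on each block
        for b in tiny_instance.blocks:
            pids = res.assignment.block_patients(tiny_instance)[b.block_id]
            that = [1.0 * tiny_instance.patient(p).sd_duration for p in pids]
            pi = [res.assignment.pi[(p, b.block_id)] for p in pids]
            assert duality_gap_check(that, 1, res.assignment.zeta[b.block_id], pi)
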