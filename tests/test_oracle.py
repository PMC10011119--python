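import dataclasses

import numpy as np
import pytest

from careloc import (CarelocError, GeometryConfig, generate_instance,
                     enumerate_stage1, enumerate_stage2, solve_stage1,
                     solve_stage2, validate)

from conftest import make_instance


class TestValidator:
    def test_exact_output_is_feasible(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        s2 = solve_stage2(tiny_instance, s1)
        rep = validate(tiny_instance, s1, s2)
        assert rep.feasible
        assert rep.stage1_objective == pytest.approx(s1.objective, abs=1e-6)
        assert rep.stage2_objective == pytest.approx(s2.objective, abs=1e-5)

    def test_planted_shortage_fault_is_caught(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        s2 = solve_stage2(tiny_instance, s1)
        # lower one positive shortage below its floor
        idx = np.unravel_index(np.argmax(s2.shortage), s2.shortage.shape)
        assert s2.shortage[idx] > 1.0
        s2.shortage[idx] -= 1.0
        s2.objective = None  # keep the probe to the planted constraint fault
        rep = validate(tiny_instance, s1, s2)
        fams = {v["family"] for v in rep.violations}
        assert "shortage_floor" in fams
        hits = [v for v in rep.violations if v["family"] == "shortage_floor"]
        assert [tuple(h["index"]) for h in hits] == [tuple(int(i) for i in idx)]

    def test_equity_violation_reports_slack(self, equity_example):
        s1 = solve_stage1(equity_example)
        s2 = solve_stage2(equity_example, s1)  # ratios {0.1, 0.5}
        tight = dataclasses.replace(equity_example, alpha_max=np.array([0.3]))
        s2.objective = None
        rep = validate(tight, s1, s2)
        hits = [v for v in rep.violations if v["family"] == "equity_cap"]
        assert len(hits) == 1
        assert hits[0]["slack"] == pytest.approx(-0.1, abs=1e-9)

    def test_idempotence(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        s2 = solve_stage2(tiny_instance, s1)
        a = validate(tiny_instance, s1, s2)
        b = validate(tiny_instance, s1, s2)
        assert a.to_dict() == b.to_dict()

    def test_shape_mismatch_rejected(self, tiny_instance):
        other = make_instance(n_nodes=2)
        s1 = solve_stage1(other)
        with pytest.raises(CarelocError):
            validate(tiny_instance, s1)

    def test_objective_recompute_mismatch_is_flagged(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        s1.objective = s1.objective + 1.0
        rep = validate(tiny_instance, s1)
        assert any(v["family"] == "stage1_objective_recompute"
                   for v in rep.violations)


class TestEnumerateStage1:
    def test_two_node_hand_optimum(self):
        inst = make_instance(
            n_nodes=2,
            hlhcc_fixed=np.array([10.0, 20.0]),
            llhcc_fixed=np.array([3.0, 5.0]),
            capacity_cost=np.array([[7.0], [9.0]]),
        )
        sol = enumerate_stage1(inst)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(22.0)

    def test_no_floors_zero_objective(self):
        sol = enumerate_stage1(make_instance(n_nodes=3, H=0, V=0))
        assert sol.objective == 0.0

    def test_size_guard(self):
        inst = generate_instance(GeometryConfig(n_nodes=7, seed=0))
        with pytest.raises(CarelocError, match="6 nodes"):
            enumerate_stage1(inst)

    def test_infeasible_detected(self):
        sol = enumerate_stage1(make_instance(n_nodes=2, H=5))
        assert sol.status == "infeasible"


class TestEnumerateStage2:
    def test_zero_demand_zero_everything(self):
        inst = make_instance(n_nodes=2, demand=0.0)
        s1 = solve_stage1(inst)
        sol = enumerate_stage2(inst, s1)
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0)
        assert np.allclose(sol.llhcc_transfer, 0) and np.allclose(sol.shortage, 0)

    def test_prohibitive_link_cost_closes_links(self):
        inst = generate_instance(GeometryConfig(
            n_nodes=4, seed=77, n_services=1, n_periods=1,
            link_cost_range=(10_000, 10_001),
            transfer_cost_range=(9_000, 9_001)))
        s1 = solve_stage1(inst)
        sol = enumerate_stage2(inst, s1)
        assert sol.status == "optimal"
        assert np.allclose(sol.link_open, 0)

    def test_size_guard(self):
        inst = generate_instance(GeometryConfig(n_nodes=5, seed=0))
        s1 = solve_stage1(inst)
        with pytest.raises(CarelocError, match="limited to"):
            enumerate_stage2(inst, s1)

    def test_agrees_with_milp(self):
        for seed in (50, 51):
            inst = generate_instance(GeometryConfig(
                n_nodes=4, seed=seed, n_services=2, n_periods=2,
                alpha_max=0.3))
            s1 = solve_stage1(inst)
            a = solve_stage2(inst, s1)
            b = enumerate_stage2(inst, s1)
            assert a.objective == pytest.approx(b.objective, rel=1e-5)
            rep = validate(inst, s1, b)
            assert rep.feasible, rep.violations
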