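import dataclasses

import numpy as np
import pytest

from careloc import (CarelocError, GeometryConfig, generate_instance,
                     enumerate_stage2, equity_gaps, solve_stage1,
                     solve_stage2, total_cost, validate)

from conftest import make_instance


def _solved_pair(seed, **kw):
    inst = generate_instance(GeometryConfig(n_nodes=4, seed=seed,
                                            n_services=2, n_periods=2, **kw))
    s1 = solve_stage1(inst)
    assert s1.status == "optimal"
    return inst, s1


class TestStage2Exact:
    def test_ample_capacity_zero_shortage(self):
        # capacity >> demand, full coverage, penalty dominant
        inst = make_instance(n_nodes=3, n_periods=2, capacity_menu=((1000.0,),),
                             demand=10.0, penalty=500.0)
        s1 = solve_stage1(inst)
        s2 = solve_stage2(inst, s1)
        assert s2.status == "optimal"
        assert np.allclose(s2.shortage, 0.0, atol=1e-7)
        assert np.allclose(s2.equity_gap, 0.0, atol=1e-7)

    def test_equity_cap_shapes_shortage_split(self, equity_example):
        """Capacity 14 against 2x10 demand with a 0.4 gap cap forces the
        cheap-penalty node to keep shortage 5 and the dear one exactly 1."""
        s1 = solve_stage1(equity_example)
        s2 = solve_stage2(equity_example, s1)
        assert s2.status == "optimal"
        assert s2.shortage[:, 0, 0] == pytest.approx([1.0, 5.0], abs=1e-6)
        gap = equity_gaps(equity_example, s2.shortage)[0, 0]
        assert gap == pytest.approx(0.4, abs=1e-6)
        assert s2.objective == pytest.approx(105.0, abs=1e-6)

    def test_exclusive_service_blocks_referral(self):
        inst = make_instance(n_nodes=3, n_services=1, exclusive=1,
                             capacity_menu=((100.0,),))
        s1 = solve_stage1(inst)
        s2 = solve_stage2(inst, s1)
        assert s2.status == "optimal"
        assert np.allclose(s2.referral, 0.0)
        # LLHCCs hold no stock of their own, so they dispense nothing either
        assert np.allclose(s2.llhcc_direct, 0.0)

    def test_vacuous_cap_equals_no_equity(self):
        inst, s1 = _solved_pair(21, alpha_max=1.0)
        with_eq = solve_stage2(inst, s1, include_equity=True)
        without = solve_stage2(inst, s1, include_equity=False)
        assert with_eq.objective == pytest.approx(without.objective, rel=1e-9)

    def test_tightening_cap_weakly_increases_cost(self):
        objs = []
        for cap in (1.0, 0.5, 0.25):
            inst, s1 = _solved_pair(22, alpha_max=cap)
            s2 = solve_stage2(inst, s1)
            assert s2.status == "optimal"
            objs.append(s2.objective)
        assert objs[0] <= objs[1] + 1e-9 and objs[1] <= objs[2] + 1e-9

    def test_linearization_matches_nonlinear_recomputation(self):
        for seed, cap in ((30, 1.0), (31, 0.3), (32, 0.25)):
            inst, s1 = _solved_pair(seed, alpha_max=cap)
            s2 = solve_stage2(inst, s1)
            assert s2.status == "optimal"
            gaps = equity_gaps(inst, s2.shortage)
            assert np.abs((s2.max_ratio - s2.min_ratio) - gaps).max() < 1e-6
            assert (gaps <= inst.alpha_max[:, None] + 1e-6).all()

    def test_printed_sign_variant_is_infeasible(self, equity_example):
        """With two demand-positive nodes one min-side selector is off, and
        the sign-swapped product rows then demand gamma'' >= B + M and
        gamma'' <= B - M at once."""
        s1 = solve_stage1(equity_example)
        bad = solve_stage2(equity_example, s1, equity_sign_mode="printed")
        assert bad.status == "infeasible"
        good = solve_stage2(equity_example, s1, equity_sign_mode="corrected")
        assert good.status == "optimal"

    def test_zero_cap_forces_shortage_padding(self, equity_example):
        """The reported shortage may exceed its floor, so a zero gap cap is
        met by padding the cheap node's shortage up: with capacity 14 and
        demand 2x10, equal ratios force B = (3, 3), cost 100*3 + 1*3."""
        inst = dataclasses.replace(equity_example, alpha_max=np.array([0.0]))
        s1 = solve_stage1(inst)
        s2 = solve_stage2(inst, s1)
        assert s2.status == "optimal"
        assert s2.shortage[:, 0, 0] == pytest.approx([3.0, 3.0], abs=1e-6)
        assert s2.objective == pytest.approx(303.0, abs=1e-6)

    def test_oracle_agreement_battery(self):
        for seed in (40, 41, 42):
            inst, s1 = _solved_pair(seed, alpha_max=0.3)
            a = solve_stage2(inst, s1)
            b = enumerate_stage2(inst, s1)
            assert a.status == b.status == "optimal"
            assert a.objective == pytest.approx(b.objective, rel=1e-5)

    def test_relaxing_equity_never_increases_cost(self):
        inst, s1 = _solved_pair(43, alpha_max=0.25)
        capped = solve_stage2(inst, s1)
        free = solve_stage2(inst, s1, include_equity=False)
        assert free.objective <= capped.objective + 1e-6

    def test_shortage_never_exceeds_demand(self):
        inst, s1 = _solved_pair(44, alpha_max=0.4)
        s2 = solve_stage2(inst, s1)
        assert (s2.shortage <= inst.demand + 1e-7).all()

    def test_integer_flow_mode(self):
        inst = make_instance(n_nodes=3, capacity_menu=((25.0,),), demand=10.0)
        s1 = solve_stage1(inst)
        cont = solve_stage2(inst, s1)
        integ = solve_stage2(inst, s1, integer_flows=True)
        assert integ.status == "optimal"
        assert integ.objective >= cont.objective - 1e-6
        flows = np.concatenate([integ.hlhcc_direct.ravel(),
                                integ.llhcc_direct.ravel(),
                                integ.referral.ravel()])
        assert np.allclose(flows, np.round(flows), atol=1e-6)

    def test_validator_passes_on_exact_output(self):
        inst, s1 = _solved_pair(45, alpha_max=0.35)
        s2 = solve_stage2(inst, s1)
        rep = validate(inst, s1, s2)
        assert rep.feasible, rep.violations
        assert rep.stage2_objective == pytest.approx(s2.objective, abs=1e-5)


class TestTotalCost:
    def test_sum_matches_independent_recomputation(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        s2 = solve_stage2(tiny_instance, s1)
        c1, c2, tot = total_cost(s1, s2)
        rep = validate(tiny_instance, s1, s2)
        assert tot == pytest.approx(rep.stage1_objective + rep.stage2_objective,
                                    abs=1e-5)
        assert c1 >= 0 and c2 >= 0

    def test_zero_demand_gives_zero_allocation_cost(self):
        inst = make_instance(n_nodes=2, demand=0.0)
        s1 = solve_stage1(inst)
        s2 = solve_stage2(inst, s1)
        assert s2.status == "optimal"
        assert s2.objective == pytest.approx(0.0, abs=1e-9)

    def test_rejects_mismatched_solutions(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        other = make_instance(n_nodes=2)
        o1 = solve_stage1(other)
        o2 = solve_stage2(other, o1)
        with pytest.raises(CarelocError):
            total_cost(s1, o2)
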