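import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from careloc import (GeometryConfig, generate_instance, solve_stage1,
                     solve_stage2, validate)
from careloc.ga import (Chromosome, GAConfig, decode_stage1,
                        gaussian_mutation, roulette_select, run_stage1_ga,
                        run_stage2_ga, sqp_warm_start, uniform_mask_crossover)

from conftest import make_instance


def _pop(fitnesses):
    return [Chromosome(genes=np.zeros(2), fitness=f) for f in fitnesses]


class TestOperators:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), length=st.integers(1, 40))
    def test_crossover_conserves_componentwise_sum(self, seed, length):
        rng = np.random.default_rng(seed)
        p1, p2 = rng.uniform(size=length), rng.uniform(size=length)
        c1, c2 = uniform_mask_crossover(p1, p2, rng)
        np.testing.assert_allclose(c1 + c2, p1 + p2, atol=1e-12)
        assert ((0 <= c1) & (c1 <= 1)).all() and ((0 <= c2) & (c2 <= 1)).all()

    def test_crossover_identical_parents(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=10)
        c1, c2 = uniform_mask_crossover(p, p.copy(), rng)
        np.testing.assert_allclose(c1, p)
        np.testing.assert_allclose(c2, p)

    def test_crossover_rejects_length_mismatch(self):
        with pytest.raises(Exception):
            uniform_mask_crossover(np.zeros(3), np.zeros(4),
                                   np.random.default_rng(0))

    def test_mutation_disabled_leaves_genes(self):
        cfg = GAConfig(seed=0, mutation_rate=0.0)
        g = np.random.default_rng(1).uniform(size=50)
        np.testing.assert_array_equal(gaussian_mutation(g, cfg, np.random.default_rng(2)), g)

    def test_mutation_tiny_sigma_barely_moves(self):
        cfg = GAConfig(seed=0, mutation_rate=1.0, mutation_sigma=1e-12)
        g = np.full(100, 0.5)
        out = gaussian_mutation(g, cfg, np.random.default_rng(3))
        np.testing.assert_allclose(out, g, atol=1e-9)

    def test_mutation_rate_calibration(self):
        """Fraction of mutated genes matches the gate rate within 3 sigma."""
        cfg = GAConfig(seed=0, mutation_rate=0.1, mutation_sigma=0.1)
        rng = np.random.default_rng(42)
        n = 10_000
        g = np.full(n, 0.5)  # interior, so clipping cannot mask a mutation
        out = gaussian_mutation(g, cfg, rng)
        changed = (out != g).sum()
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(changed - 0.1 * n) <= 3 * sigma

    def test_roulette_degenerate_mass(self):
        pop = _pop([5.0, 1.0, 3.0])
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = roulette_select(pop, rng, weights=np.array([0.0, 1.0, 0.0]))
            assert a is pop[1] and b is pop[1]

    def test_roulette_uniform_within_3_sigma(self):
        pop = _pop([1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        n_draws = 10_000
        for _ in range(n_draws // 2):
            a, b = roulette_select(pop, rng, weights=np.ones(4))
            counts[next(i for i, c in enumerate(pop) if c is a)] += 1
            counts[next(i for i, c in enumerate(pop) if c is b)] += 1
        p = 1 / 4
        sigma = np.sqrt(n_draws * p * (1 - p))
        assert (np.abs(counts - n_draws * p) <= 3 * sigma).all()

    def test_roulette_prefers_better_fitness(self):
        pop = _pop([100.0, 1.0])  # minimization: the second is better
        rng = np.random.default_rng(11)
        wins = sum(roulette_select(pop, rng)[0] is pop[1] for _ in range(3000))
        assert wins > 1700  # rank weights 2:1

    def test_roulette_empty_population_rejected(self):
        with pytest.raises(Exception):
            roulette_select([], np.random.default_rng(0))


class TestDecodeStage1:
    def test_all_closed_penalty_counts_missing_coverage(self):
        inst = make_instance(n_nodes=3, n_services=2, H=1, V=1)
        genes = np.zeros(3 * 3 + 2)
        sol, pen = decode_stage1(genes, inst, penalty_weight=1.0)
        assert sol.hlhcc_open.sum() == 0
        assert pen == pytest.approx(3 * 2 * (1 + 1))  # (H+V) per (node, service)

    def test_feasible_decode_matches_validator_objective(self, tiny_instance):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sol, pen = decode_stage1(rng.uniform(size=3 * 4 + 2), tiny_instance)
            if pen == 0:
                rep = validate(tiny_instance, sol)
                assert rep.feasible
                assert rep.stage1_objective == pytest.approx(sol.objective)
                break
        else:
            pytest.fail("no feasible decode found in 20 random draws")

    def test_decode_is_deterministic(self, tiny_instance):
        g = np.random.default_rng(9).uniform(size=3 * 4 + 2)
        a, pa = decode_stage1(g, tiny_instance)
        b, pb = decode_stage1(g, tiny_instance)
        assert pa == pb and a.to_dict() == b.to_dict()


class TestStage1GA:
    def test_trace_monotone_and_reproducible(self, tiny_instance):
        cfg = GAConfig(seed=123, population_size=30, n_generations=20)
        sol_a, hist_a = run_stage1_ga(tiny_instance, cfg)
        sol_b, hist_b = run_stage1_ga(tiny_instance, cfg)
        assert (np.diff(hist_a["best_fitness"]) <= 1e-12).all()
        assert hist_a.equals(hist_b)
        assert sol_a.to_dict() == sol_b.to_dict()

    def test_near_exact_on_small_instances(self):
        hits = 0
        for s in range(5):
            inst = generate_instance(GeometryConfig(n_nodes=6, seed=800 + s,
                                                    n_services=2))
            exact = solve_stage1(inst)
            cfg = GAConfig(seed=s, population_size=60, n_generations=60)
            ga, _ = run_stage1_ga(inst, cfg)
            assert ga.ga_feasible
            assert ga.objective >= exact.objective - 1e-9
            rep = validate(inst, ga)
            assert rep.feasible
            hits += (ga.objective - exact.objective) / exact.objective <= 0.05
        assert hits >= 4

    def test_infeasible_battery_is_flagged(self):
        inst = make_instance(n_nodes=2, H=5)  # cannot be covered
        cfg = GAConfig(seed=0, population_size=10, n_generations=5)
        sol, _ = run_stage1_ga(inst, cfg)
        assert sol.ga_feasible is False


class TestStage2GA:
    def test_warm_start_is_lower_bound(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        exact = solve_stage2(tiny_instance, s1)
        ws = sqp_warm_start(tiny_instance, s1)
        assert ws.objective <= exact.objective + 1e-5 * max(1, exact.objective)

    def test_ample_capacity_relaxation_reaches_zero_shortage(self):
        inst = make_instance(n_nodes=3, capacity_menu=((1000.0,),),
                             demand=10.0, penalty=500.0)
        s1 = solve_stage1(inst)
        exact = solve_stage2(inst, s1)
        ws = sqp_warm_start(inst, s1)
        assert np.isclose(ws.objective, exact.objective, rtol=1e-6)

    def test_ga_never_beats_exact_and_validates(self):
        inst = generate_instance(GeometryConfig(n_nodes=5, seed=900,
                                                n_services=2, n_periods=2,
                                                alpha_max=0.5))
        s1 = solve_stage1(inst)
        exact = solve_stage2(inst, s1)
        cfg = GAConfig(seed=1, population_size=20, n_generations=15)
        ga, hist = run_stage2_ga(inst, s1, cfg)
        assert ga.ga_feasible
        assert ga.objective >= exact.objective - 1e-6
        assert validate(inst, s1, ga).feasible
        assert (np.diff(hist["best_fitness"]) <= 1e-12).all()

    def test_reproducible_under_fixed_seed(self, tiny_instance):
        s1 = solve_stage1(tiny_instance)
        cfg = GAConfig(seed=5, population_size=15, n_generations=10)
        a, ha = run_stage2_ga(tiny_instance, s1, cfg)
        b, hb = run_stage2_ga(tiny_instance, s1, cfg)
        assert ha.equals(hb)
        assert a.objective == b.objective
        assert np.array_equal(a.link_open, b.link_open)

    def test_prohibitive_transfer_cost_yields_no_links(self):
        inst = generate_instance(GeometryConfig(
            n_nodes=4, seed=77, n_services=1, n_periods=1,
            link_cost_range=(10_000, 10_001),
            transfer_cost_range=(9_000, 9_001)))
        s1 = solve_stage1(inst)
        exact = solve_stage2(inst, s1)
        cfg = GAConfig(seed=2, population_size=20, n_generations=15)
        ga, _ = run_stage2_ga(inst, s1, cfg)
        assert np.allclose(ga.link_open, 0)
        assert np.allclose(exact.link_open, 0)
        assert ga.objective == pytest.approx(exact.objective, rel=1e-6)

    def test_warm_start_never_worse(self):
        """The SQP seed cannot hurt: same final objective or better, reached
        no later (the memetic completion usually makes both optimal at the
        initial population already)."""
        for s in range(3):
            inst = generate_instance(GeometryConfig(
                n_nodes=5, seed=950 + s, n_services=2, n_periods=2,
                alpha_max=0.5))
            s1 = solve_stage1(inst)
            cfg = GAConfig(seed=s, population_size=15, n_generations=10)
            warm, hw = run_stage2_ga(inst, s1, cfg, warm_start=True)
            cold, hc = run_stage2_ga(inst, s1, cfg, warm_start=False)
            assert warm.objective <= cold.objective + 1e-9

            def first_hit(h):
                best = h["best_fitness"].iloc[-1]
                return int(h.loc[h["best_fitness"] <= best + 1e-9,
                                 "generation"].min())
            assert first_hit(hw) <= first_hit(hc)
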