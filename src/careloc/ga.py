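"""Hybrid metaheuristic: real-coded GA with an SQP-seeded allocation stage.

Both stages use a random-key encoding — a chromosome is a vector in
[0, 1]^L decoded deterministically into discrete decisions — because the
continuous convex-combination crossover requires real genes. Constraint
handling mixes constructive repair (assignment, one-facility-per-node,
capacity-level counts are satisfied by construction) with a static penalty
on the coverage floors / equity cap, weighted so any infeasible decode is
dominated by any feasible one.

Stage 1 searches node roles, assignments and capacity levels directly.
Stage 2 searches only the transfer-link pattern; each decode is completed
by solving the residual allocation exactly (an LP when the equity cap turns
out slack, a small selector MILP otherwise), so every chromosome is
flow-feasible. The stage-2 population is seeded from a sequential quadratic
programming (SLSQP) solve of the continuous relaxation, whose objective is
also a valid lower bound on the allocation optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .instance import CarelocError, Instance
from .stage1 import Stage1Solution
from .stage2 import (Stage2Solution, build_stage2_model, equity_gaps,
                     solve_stage2)
from .oracle import _fill_equity

__all__ = [
    "GAConfig",
    "Chromosome",
    "decode_stage1",
    "roulette_select",
    "uniform_mask_crossover",
    "gaussian_mutation",
    "run_stage1_ga",
    "sqp_warm_start",
    "run_stage2_ga",
    "WarmStart",
]


@dataclass(frozen=True)
class GAConfig:
    """Metaheuristic parameters.

    ``penalty_weight="auto"`` scales to 10x an upper bound on the
    unpenalized objective range so feasibility always dominates.
    """

    seed: int
    population_size: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sigma: float = 0.3
    elite_count: int = 2
    n_generations: int = 150
    penalty_weight: float | str = "auto"

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CarelocError(f"{name} must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise CarelocError("elite_count must be smaller than population_size")

    @staticmethod
    def from_dict(d: dict) -> "GAConfig":
        return GAConfig(**d)


@dataclass
class Chromosome:
    genes: np.ndarray
    fitness: float = np.inf
    penalty: float = 0.0
    decoded: Any = None


# --- operators --------------------------------------------------------------

def roulette_select(population: list[Chromosome], rng: np.random.Generator,
                    weights: np.ndarray | None = None
                    ) -> tuple[Chromosome, Chromosome]:
    """Draw a parent pair, probability proportional to desirability.

    On a minimization problem raw 1/cost weighting is scale-sensitive, so
    the default desirability is reverse-rank: the worst chromosome gets
    weight 1, the best gets ``len(population)``. An explicit nonnegative
    ``weights`` vector overrides this.
    """
    if not population:
        raise CarelocError("cannot select from an empty population")
    if weights is None:
        fit = np.array([c.fitness for c in population])
        if not np.isfinite(fit).all():
            raise CarelocError("all fitness values must be finite for selection")
        order = np.argsort(-fit, kind="stable")  # worst first
        weights = np.empty(len(population))
        weights[order] = np.arange(1, len(population) + 1)
    else:
        weights = np.asarray(weights, float)
        if (weights < 0).any() or weights.sum() <= 0:
            raise CarelocError("selection weights must be nonnegative, not all zero")
    p = weights / weights.sum()
    i, j = rng.choice(len(population), size=2, p=p)
    return population[i], population[j]


def uniform_mask_crossover(p1: np.ndarray, p2: np.ndarray,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous uniform crossover with a fresh uniform [0,1] mask per gene.

    ``child1 = p1*mask + p2*(1-mask)`` and ``child2 = p1*(1-mask) + p2*mask``;
    being convex combinations the children stay in [0, 1] and their
    componentwise sum equals the parents'.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if p1.shape != p2.shape:
        raise CarelocError("parents must have equal length")
    mask = rng.uniform(size=p1.shape)
    return p1 * mask + p2 * (1.0 - mask), p1 * (1.0 - mask) + p2 * mask


def gaussian_mutation(genes: np.ndarray, config: GAConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform per-gene gating + additive Gaussian perturbation, clipped.

    Each gene independently mutates with probability ``mutation_rate``;
    a mutating gene receives N(0, mutation_sigma) noise and is clipped back
    into [0, 1].
    """
    genes = np.asarray(genes, float).copy()
    gate = rng.uniform(size=genes.shape) < config.mutation_rate
    noise = rng.normal(0.0, config.mutation_sigma, size=genes.shape)
    genes[gate] = np.clip(genes[gate] + noise[gate], 0.0, 1.0)
    return genes


# --- stage-1 decoding -------------------------------------------------------

def _stage1_penalty_weight(inst: Instance) -> float:
    ub = float(inst.hlhcc_fixed_cost.sum() + inst.llhcc_fixed_cost.sum())
    for n in range(inst.n_services):
        ub += float(inst.capacity_level_cost[n].max(axis=1).sum())
    return 10.0 * max(ub, 1.0)


def decode_stage1(genes: np.ndarray, inst: Instance,
                  penalty_weight: float | str = "auto"
                  ) -> tuple[Stage1Solution, float]:
    """Deterministically decode a random-key chromosome into a design.

    Layout: ``[HLHCC keys (I) | LLHCC keys (I) | assignment keys (I) |
    capacity keys (N)]``. Keys above 0.5 open a facility; a node keyed open
    at both tiers keeps the tier with the larger key (HLHCC on ties). Each
    open LLHCC is attached to the within-coverage open HLHCC picked by its
    quantized assignment key, or closed when no such HLHCC exists.
    Capacity keys quantize to one level per service, shared across sites.
    Coverage-floor shortfalls accrue penalty = weight x missing coverage
    units; everything else is feasible by construction.
    """
    I, N = inst.n_nodes, inst.n_services
    genes = np.asarray(genes, float)
    if genes.shape != (3 * I + N,):
        raise CarelocError(f"stage-1 chromosome must have length {3 * I + N}")
    w = _stage1_penalty_weight(inst) if penalty_weight == "auto" else float(penalty_weight)
    hk, lk, ak, ck = genes[:I], genes[I:2 * I], genes[2 * I:3 * I], genes[3 * I:]
    X = (hk > 0.5).astype(float)
    y = (lk > 0.5).astype(float)
    both = (X > 0.5) & (y > 0.5)
    y[both & (hk >= lk)] = 0.0
    X[both & (hk < lk)] = 0.0

    b = inst.hlhcc_coverage
    assignment = np.zeros((I, I))
    for j in range(I):
        if y[j] < 0.5:
            continue
        cands = [k for k in range(I)
                 if k != j and X[k] > 0.5 and b[j, k, :].sum() >= 1]
        if not cands:
            y[j] = 0.0
            continue
        pick = min(int(ak[j] * len(cands)), len(cands) - 1)
        assignment[j, cands[pick]] = 1.0

    z = tuple(np.zeros((I, inst.n_levels[n])) for n in range(N))
    obj = float((inst.hlhcc_fixed_cost * X).sum() + (inst.llhcc_fixed_cost * y).sum())
    for n in range(N):
        lvl = min(int(ck[n] * inst.n_levels[n]), inst.n_levels[n] - 1)
        for k in range(I):
            if X[k] > 0.5:
                z[n][k, lvl] = 1.0
                obj += float(inst.capacity_level_cost[n][k, lvl])

    cov_h = (b * X[None, :, None]).sum(axis=1)           # (I, N)
    cov_l = (inst.llhcc_coverage * y[None, :, None]).sum(axis=1)
    shortfall = (np.maximum(0, inst.min_hlhcc_cover - cov_h).sum()
                 + np.maximum(0, inst.min_llhcc_cover - cov_l).sum())
    penalty = w * float(shortfall)
    sol = Stage1Solution(
        hlhcc_open=X, llhcc_open=y, assignment=assignment, capacity_choice=z,
        objective=obj, status="heuristic", ga_feasible=(penalty == 0.0),
    )
    return sol, penalty


# --- generic generational loop ----------------------------------------------

def _evolve(eval_fn: Callable[[np.ndarray], tuple[Any, float, float]],
            length: int, config: GAConfig, rng: np.random.Generator,
            seeds: list[np.ndarray] | None = None
            ) -> tuple[Chromosome, pd.DataFrame]:
    """Run the generational scheme shared by both stages.

    Elitism copies the best ``elite_count`` unchanged each generation, so
    the best-fitness trajectory is monotone nonincreasing.
    """

    def make(genes):
        decoded, raw, pen = eval_fn(genes)
        return Chromosome(genes=genes, fitness=raw + pen, penalty=pen,
                          decoded=decoded)

    pop = [make(g) for g in (seeds or [])]
    while len(pop) < config.population_size:
        pop.append(make(rng.uniform(size=length)))
    pop = pop[:config.population_size]

    history = []
    best = min(pop, key=lambda c: c.fitness)
    for gen in range(config.n_generations):
        pop.sort(key=lambda c: c.fitness)
        history.append({
            "generation": gen,
            "best_fitness": pop[0].fitness,
            "mean_fitness": float(np.mean([c.fitness for c in pop])),
            "penalty_share": float(np.mean([c.penalty > 0 for c in pop])),
        })
        nxt = [Chromosome(c.genes.copy(), c.fitness, c.penalty, c.decoded)
               for c in pop[:config.elite_count]]
        while len(nxt) < config.population_size:
            pa, pb = roulette_select(pop, rng)
            if rng.uniform() < config.crossover_rate:
                g1, g2 = uniform_mask_crossover(pa.genes, pb.genes, rng)
            else:
                g1, g2 = pa.genes.copy(), pb.genes.copy()
            for g in (g1, g2):
                if len(nxt) < config.population_size:
                    nxt.append(make(gaussian_mutation(g, config, rng)))
        pop = nxt
        cand = min(pop, key=lambda c: c.fitness)
        if cand.fitness < best.fitness:
            best = cand
    pop.sort(key=lambda c: c.fitness)
    history.append({
        "generation": config.n_generations,
        "best_fitness": pop[0].fitness,
        "mean_fitness": float(np.mean([c.fitness for c in pop])),
        "penalty_share": float(np.mean([c.penalty > 0 for c in pop])),
    })
    if pop[0].fitness < best.fitness:
        best = pop[0]
    return best, pd.DataFrame(history)


def run_stage1_ga(inst: Instance, config: GAConfig
                  ) -> tuple[Stage1Solution, pd.DataFrame]:
    """Evolve a location design; returns the best decode and the trace.

    The result is flagged ``ga_feasible=False`` (never silently returned as
    feasible) when no penalty-free decode was found.
    """
    rng = np.random.default_rng(config.seed)
    L = 3 * inst.n_nodes + inst.n_services
    w = (_stage1_penalty_weight(inst) if config.penalty_weight == "auto"
         else float(config.penalty_weight))

    def eval_fn(genes):
        sol, pen = decode_stage1(genes, inst, penalty_weight=w)
        return sol, sol.objective, pen

    best, history = _evolve(eval_fn, L, config, rng)
    sol: Stage1Solution = best.decoded
    sol.ga_feasible = best.penalty == 0.0
    return sol, history


# --- stage-2: SQP warm start + GA over link patterns ------------------------

@dataclass
class WarmStart:
    """Continuous-relaxation seed for the allocation GA."""

    link_relaxed: np.ndarray     # (I, I, T) in [0, 1]
    objective: float             # valid lower bound on the allocation optimum
    method: str                  # "slsqp" or "lp"


def sqp_warm_start(inst: Instance, s1: Stage1Solution,
                   max_slsqp_vars: int = 800) -> WarmStart:
    """Solve the continuous relaxation of the allocation stage.

    All binaries (links and equity selectors) are relaxed to [0, 1] and the
    resulting linear program is solved with SLSQP from a fixed interior
    start; its solution seeds the GA population. The reported relaxed
    objective is certified by an LP solve of the same relaxation, so it is
    always a valid lower bound on the allocation MILP optimum. Models too
    large for a dense SQP solve (or an SLSQP run that fails its
    convergence/feasibility test; exit status 8 — termination at a
    degenerate boundary — counts as converged) fall back to the LP solution
    for the seed as well.
    """
    model, ix, const = build_stage2_model(inst, s1)
    if model.n_vars == 0:
        return WarmStart(np.zeros((inst.n_nodes, inst.n_nodes, inst.n_periods)),
                         const, "lp")
    c, A, lo, hi = model.matrices()
    lb = np.array(model.lb)
    ub = np.array(model.ub)
    A = A.toarray() if model.n_vars <= max_slsqp_vars else A

    xsol = None
    method = "lp"
    if model.n_vars <= max_slsqp_vars:
        eq = lo == hi
        fin_hi = np.isfinite(hi) & ~eq
        fin_lo = np.isfinite(lo) & ~eq
        cons = []
        if eq.any():
            Ae, be = A[eq], lo[eq]
            cons.append({"type": "eq", "fun": lambda v, Ae=Ae, be=be: Ae @ v - be,
                         "jac": lambda v, Ae=Ae: Ae})
        if fin_hi.any():
            Ah, bh = A[fin_hi], hi[fin_hi]
            cons.append({"type": "ineq", "fun": lambda v, Ah=Ah, bh=bh: bh - Ah @ v,
                         "jac": lambda v, Ah=Ah: -Ah})
        if fin_lo.any():
            Al, bl = A[fin_lo], lo[fin_lo]
            cons.append({"type": "ineq", "fun": lambda v, Al=Al, bl=bl: Al @ v - bl,
                         "jac": lambda v, Al=Al: Al})
        ubf = np.where(np.isfinite(ub), ub, lb + 2.0 * inst.demand.sum())
        x0 = lb + 0.5 * (ubf - lb)
        res = minimize(
            lambda v: float(c @ v), x0, jac=lambda v: c, method="SLSQP",
            bounds=list(zip(lb, ubf)), constraints=cons,
            options={"maxiter": 300, "ftol": 1e-10},
        )
        if res.success or res.status == 8:
            viol = 0.0
            if eq.any():
                viol = max(viol, float(np.abs(A[eq] @ res.x - lo[eq]).max()))
            if fin_hi.any():
                viol = max(viol, float(np.maximum(A[fin_hi] @ res.x - hi[fin_hi], 0).max()))
            if fin_lo.any():
                viol = max(viol, float(np.maximum(lo[fin_lo] - A[fin_lo] @ res.x, 0).max()))
            if viol <= 1e-5:
                xsol = np.asarray(res.x)
                method = "slsqp"

    lp = _lp_fallback(c, A, lo, hi, lb, ub)
    if lp is None:
        raise CarelocError(
            "allocation relaxation is infeasible; the allocation MILP "
            "is infeasible too")
    obj = lp[0]  # certified bound, regardless of which x seeds the GA
    if xsol is None:
        xsol = lp[1]

    links = np.zeros((inst.n_nodes, inst.n_nodes, inst.n_periods))
    for (j, j2, t), v in ix["x"].items():
        links[j, j2, t] = float(np.clip(xsol[v], 0.0, 1.0))
    return WarmStart(links, float(obj) + const, method)


def _lp_fallback(c, A, lo, hi, lb, ub):
    import scipy.sparse as sp
    A = sp.csr_matrix(A)
    rows_ub, rhs_ub, rows_eq, rhs_eq = [], [], [], []
    for r in range(A.shape[0]):
        if lo[r] == hi[r]:
            rows_eq.append(r)
            rhs_eq.append(lo[r])
        else:
            if np.isfinite(hi[r]):
                rows_ub.append((r, 1.0, hi[r]))
            if np.isfinite(lo[r]):
                rows_ub.append((r, -1.0, -lo[r]))
    A_ub = (sp.vstack([s * A.getrow(r) for r, s, _ in rows_ub])
            if rows_ub else None)
    b_ub = np.array([b for *_, b in rows_ub]) if rows_ub else None
    A_eq = A[rows_eq] if rows_eq else None
    b_eq = np.array(rhs_eq) if rows_eq else None
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return None
    return float(res.fun), np.asarray(res.x)


def _stage2_penalty_weight(inst: Instance) -> float:
    ub = float((inst.shortage_penalty[:, :, None] * inst.demand).sum())
    ub += float(inst.link_fixed_cost.sum()) * inst.n_periods
    return 10.0 * max(ub, 1.0)


def _complete_links(inst: Instance, s1: Stage1Solution, links: np.ndarray,
                    weight: float) -> tuple[Stage2Solution, float, float]:
    """Exact residual completion for a fixed link pattern.

    Solves the residual LP without the equity cap first; only when the
    achieved nonlinear gap violates the cap is the residual re-solved as a
    small MILP over the equity selectors. Returns
    ``(solution, raw_objective, penalty)``.
    """
    relaxed = solve_stage2(inst, s1, fixed_links=links, include_equity=False)
    if relaxed.status != "optimal":  # pragma: no cover - LP always feasible
        return relaxed, np.inf, weight
    gaps = equity_gaps(inst, relaxed.shortage)
    viol = float(np.maximum(gaps - inst.alpha_max[:, None], 0.0).sum())
    if viol <= 1e-9:
        _fill_equity(inst, relaxed)
        relaxed.ga_feasible = True
        return relaxed, float(relaxed.objective), 0.0
    capped = solve_stage2(inst, s1, fixed_links=links, include_equity=True)
    if capped.status == "optimal":
        capped.ga_feasible = True
        return capped, float(capped.objective), 0.0
    # equity cannot be met under this link pattern
    relaxed.ga_feasible = False
    return relaxed, float(relaxed.objective), weight * viol


def run_stage2_ga(inst: Instance, s1: Stage1Solution, config: GAConfig,
                  warm_start: bool = True
                  ) -> tuple[Stage2Solution, pd.DataFrame]:
    """Evolve the transfer-link pattern; allocations are completed exactly.

    Chromosome layout: ``I*I*T`` link keys (thresholded at 0.5, restricted
    to ordered pairs of open LLHCCs) followed by ``I`` allocation-priority
    keys (inert under the exact completion; kept for layout stability).
    With ``warm_start`` the initial population contains a chromosome built
    from the SLSQP relaxation's link values.
    """
    if s1.status != "optimal" and not s1.ga_feasible:
        raise CarelocError("stage-2 GA requires an optimal or GA-feasible "
                           "stage-1 solution")
    I, T = inst.n_nodes, inst.n_periods
    rng = np.random.default_rng(config.seed)
    L = I * I * T + I
    weight = (_stage2_penalty_weight(inst) if config.penalty_weight == "auto"
              else float(config.penalty_weight))
    open_l = s1.llhcc_open > 0.5
    pair_mask = open_l[:, None] & open_l[None, :]
    np.fill_diagonal(pair_mask, False)

    cache: dict[bytes, tuple[Stage2Solution, float, float]] = {}

    def decode(genes: np.ndarray) -> tuple[Stage2Solution, float, float]:
        keys = genes[:I * I * T].reshape(I, I, T)
        links = ((keys > 0.5) & pair_mask[:, :, None]).astype(float)
        key = links.astype(np.int8).tobytes()
        if key not in cache:
            cache[key] = _complete_links(inst, s1, links, weight)
        return cache[key]

    seeds = []
    if warm_start:
        ws = sqp_warm_start(inst, s1)
        g = rng.uniform(size=L) * 0.0 + 0.5
        g[:I * I * T] = (0.25 + 0.5 * ws.link_relaxed).reshape(-1)
        seeds.append(np.clip(g, 0.0, 1.0))

    best, history = _evolve(decode, L, config, rng, seeds=seeds)
    sol: Stage2Solution = best.decoded
    sol.ga_feasible = best.penalty == 0.0
    sol.status = "heuristic"
    return sol, history
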