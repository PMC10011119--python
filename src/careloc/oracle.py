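"""Independent verification and brute-force exact oracles.

The validator re-checks every constraint family by direct arithmetic on the
dense solution tensors — it never touches solver artifacts, and it checks
the equity cap in its original nonlinear max-min form (not through the
linearization variables), so linearization bugs are catchable.

The enumeration oracles exhaustively search tiny instances: the location
stage over all node-role patterns, the allocation stage over all transfer
link patterns (with extremal-node selector enumeration when the equity cap
binds), solving each residual continuous program with
:func:`scipy.optimize.linprog`. They share no model-building code with the
MILP path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .instance import CarelocError, Instance
from .stage1 import Stage1Solution
from .stage2 import Stage2Solution, equity_gaps

__all__ = ["ViolationReport", "validate", "enumerate_stage1", "enumerate_stage2"]

TOL = 1e-6


@dataclass
class ViolationReport:
    """Outcome of independent constraint checking.

    Each violation records the constraint family, the index tuple, both
    sides of the comparison and the slack (negative means violated).
    """

    violations: list[dict] = field(default_factory=list)
    stage1_objective: float | None = None
    stage2_objective: float | None = None

    @property
    def feasible(self) -> bool:
        return len(self.violations) == 0

    def add(self, family: str, index: tuple, lhs: float, rhs: float,
            sense: str) -> None:
        """Record ``lhs (sense) rhs`` if violated beyond tolerance.

        ``sense`` is one of ``<=``, ``>=``, ``==``; slack is ``rhs - lhs``
        for ``<=``, ``lhs - rhs`` for ``>=`` and ``-|lhs - rhs|`` for ``==``.
        """
        if sense == "<=":
            slack = rhs - lhs
        elif sense == ">=":
            slack = lhs - rhs
        else:
            slack = -abs(lhs - rhs)
        if slack < -TOL:
            self.violations.append({
                "family": family, "index": tuple(int(v) for v in index),
                "lhs": float(lhs), "rhs": float(rhs), "slack": float(slack),
            })

    def to_frame(self) -> pd.DataFrame:
        cols = ["family", "index", "lhs", "rhs", "slack"]
        return pd.DataFrame(self.violations, columns=cols)

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "stage1_objective": self.stage1_objective,
            "stage2_objective": self.stage2_objective,
            "violations": [
                {**v, "index": list(v["index"])} for v in self.violations
            ],
        }


def _check_stage1(inst: Instance, s1: Stage1Solution, rep: ViolationReport) -> None:
    I, N = inst.n_nodes, inst.n_services
    X, y, XA = s1.hlhcc_open, s1.llhcc_open, s1.assignment
    b, a = inst.hlhcc_coverage, inst.llhcc_coverage
    for arr, fam in ((X, "hlhcc_open_binary"), (y, "llhcc_open_binary"),
                     (XA, "assignment_binary")):
        for idx in np.ndindex(arr.shape):
            v = arr[idx]
            rep.add(fam, idx, min(abs(v), abs(v - 1.0)), 0.0, "==")
    for j in range(I):
        for k in range(I):
            if j == k:
                continue
            rep.add("assignment_requires_open_hlhcc", (j, k), XA[j, k], X[k], "<=")
            rep.add("assignment_within_coverage", (j, k),
                    XA[j, k], min(1.0, float(b[j, k, :].sum())), "<=")
        rep.add("one_assignment_per_llhcc", (j,),
                float(sum(XA[j, k] for k in range(I) if k != j)), y[j], "==")
    for n in range(N):
        for k in range(I):
            rep.add("one_capacity_level_per_service", (k, n),
                    float(s1.capacity_choice[n][k, :].sum()), X[k], "==")
    for i in range(I):
        rep.add("one_tier_per_node", (i,), X[i] + y[i], 1.0, "<=")
    for i in range(I):
        for n in range(N):
            rep.add("hlhcc_cover_floor", (i, n),
                    float((b[i, :, n] * X).sum()), inst.min_hlhcc_cover, ">=")
            rep.add("llhcc_cover_floor", (i, n),
                    float((a[i, :, n] * y).sum()), inst.min_llhcc_cover, ">=")
    obj = float((inst.hlhcc_fixed_cost * X).sum() + (inst.llhcc_fixed_cost * y).sum())
    for n in range(N):
        obj += float((inst.capacity_level_cost[n] * s1.capacity_choice[n]).sum())
    rep.stage1_objective = obj
    if s1.objective is not None:
        rep.add("stage1_objective_recompute", (), float(s1.objective), obj, "==")


def _check_stage2(inst: Instance, s1: Stage1Solution, s2: Stage2Solution,
                  rep: ViolationReport) -> None:
    I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
    X, y, XA = s1.hlhcc_open, s1.llhcc_open, s1.assignment
    b, a, D = inst.hlhcc_coverage, inst.llhcc_coverage, inst.demand
    x, h = s2.link_open, s2.llhcc_transfer
    u, e, w, B = s2.hlhcc_direct, s2.llhcc_direct, s2.referral, s2.shortage
    cap = s1.installed_capacity(inst)

    for name, arr in (("transfer", h), ("hlhcc_direct", u),
                      ("llhcc_direct", e), ("referral", w), ("shortage", B)):
        neg = arr.min()
        rep.add(f"{name}_nonnegative", (), float(neg), 0.0, ">=")

    for j in range(I):
        for j2 in range(I):
            for t in range(T):
                v = x[j, j2, t]
                rep.add("link_binary", (j, j2, t), min(abs(v), abs(v - 1.0)),
                        0.0, "==")
                if v > 0.5:
                    rep.add("link_endpoints_open", (j, j2, t),
                            2.0 * v, y[j] + y[j2], "<=")
                    if j == j2:
                        rep.add("link_no_self_loop", (j, j2, t), v, 0.0, "<=")
                for n in range(N):
                    if h[j, j2, n, t] > TOL and v < 0.5:
                        rep.add("transfer_requires_link", (j, j2, n, t),
                                h[j, j2, n, t], 0.0, "<=")
    for k in range(I):
        for n in range(N):
            for t in range(T):
                load = float(w[k, :, n, t].sum() + u[k, :, n, t].sum())
                rep.add("hlhcc_capacity", (k, n, t), load,
                        float(cap[k, n]) if X[k] > 0.5 else 0.0, "<=")
    for k in range(I):
        for j in range(I):
            for n in range(N):
                for t in range(T):
                    if w[k, j, n, t] > TOL:
                        gate = (XA[j, k] > 0.5 and b[j, k, n] > 0.5
                                and X[k] > 0.5 and y[j] > 0.5
                                and inst.hlhcc_exclusive[n] < 0.5)
                        if not gate:
                            rep.add("referral_gating", (k, j, n, t),
                                    w[k, j, n, t], 0.0, "<=")
    for j in range(I):
        for i in range(I):
            for n in range(N):
                for t in range(T):
                    if e[j, i, n, t] > TOL and not (a[i, j, n] > 0.5 and y[j] > 0.5):
                        rep.add("llhcc_service_gating", (j, i, n, t),
                                e[j, i, n, t], 0.0, "<=")
    for k in range(I):
        for i in range(I):
            for n in range(N):
                for t in range(T):
                    if u[k, i, n, t] > TOL and not (b[i, k, n] > 0.5 and X[k] > 0.5):
                        rep.add("hlhcc_service_gating", (k, i, n, t),
                                u[k, i, n, t], 0.0, "<=")
    for j in range(I):
        for n in range(N):
            for t in range(T):
                inflow = float(w[:, j, n, t].sum() + h[:, j, n, t].sum())
                outflow = float(e[j, :, n, t].sum() + h[j, :, n, t].sum())
                rep.add("llhcc_flow_balance", (j, n, t), inflow, outflow, ">=")
    for i in range(I):
        for n in range(N):
            for t in range(T):
                served = float(e[:, i, n, t].sum() + u[:, i, n, t].sum())
                rep.add("shortage_floor", (i, n, t), B[i, n, t],
                        D[i, n, t] - served, ">=")
    # equity checked in its original nonlinear max-min form
    gaps = equity_gaps(inst, B)
    for n in range(N):
        for t in range(T):
            rep.add("equity_cap", (n, t), float(gaps[n, t]),
                    float(inst.alpha_max[n]), "<=")

    obj = float((inst.link_fixed_cost[:, :, None] * x).sum())
    obj += float((inst.llhcc_transfer_unit_cost[:, :, :, None] * h).sum())
    obj += float((inst.hlhcc_service_unit_cost[:, :, :, None] * u).sum())
    obj += float((inst.llhcc_service_unit_cost[:, :, :, None] * e).sum())
    obj += float((inst.referral_unit_cost[:, :, :, None] * w).sum())
    obj += float((inst.shortage_penalty[:, :, None] * B).sum())
    rep.stage2_objective = obj
    if s2.objective is not None:
        rep.add("stage2_objective_recompute", (), float(s2.objective), obj, "==")


def validate(inst: Instance, s1: Stage1Solution,
             s2: Stage2Solution | None = None) -> ViolationReport:
    """Check a solution pair by direct arithmetic; see module docstring."""
    if s1.hlhcc_open.shape != (inst.n_nodes,):
        raise CarelocError("stage-1 solution shape does not match the instance")
    if s2 is not None and s2.shortage.shape != (
            inst.n_nodes, inst.n_services, inst.n_periods):
        raise CarelocError("stage-2 solution shape does not match the instance")
    rep = ViolationReport()
    _check_stage1(inst, s1, rep)
    if s2 is not None:
        _check_stage2(inst, s1, s2, rep)
    return rep


# --- stage-1 enumeration ----------------------------------------------------

def enumerate_stage1(inst: Instance, max_nodes: int = 6) -> Stage1Solution:
    """Brute-force optimal location design for tiny instances.

    Enumerates every assignment of node roles (closed / HLHCC / LLHCC),
    checks the coverage floors and the existence of a within-coverage
    assignment for every open LLHCC, and prices each feasible pattern with
    the cheapest capacity level per (HLHCC, service) — cheaper levels always
    dominate because capacity never enters the location-stage objective.
    """
    I, N = inst.n_nodes, inst.n_services
    if I > max_nodes:
        raise CarelocError(
            f"enumeration oracle limited to {max_nodes} nodes, got {I}")
    b, a = inst.hlhcc_coverage, inst.llhcc_coverage
    cheapest_cost = np.array([
        [inst.capacity_level_cost[n][k].min() for n in range(N)]
        for k in range(I)
    ])  # (I, N)
    cheapest_level = [
        np.argmin(inst.capacity_level_cost[n], axis=1) for n in range(N)
    ]
    best_obj = np.inf
    best = None
    for roles in itertools.product((0, 1, 2), repeat=I):  # 0 closed, 1 HLHCC, 2 LLHCC
        X = np.array([1.0 if r == 1 else 0.0 for r in roles])
        y = np.array([1.0 if r == 2 else 0.0 for r in roles])
        if ((b * X[None, :, None]).sum(axis=1) < inst.min_hlhcc_cover).any():
            continue
        if ((a * y[None, :, None]).sum(axis=1) < inst.min_llhcc_cover).any():
            continue
        assignment = np.zeros((I, I))
        ok = True
        for j in range(I):
            if y[j] < 0.5:
                continue
            cands = [k for k in range(I)
                     if k != j and X[k] > 0.5 and b[j, k, :].sum() >= 1]
            if not cands:
                ok = False
                break
            assignment[j, cands[0]] = 1.0
        if not ok:
            continue
        obj = float((inst.hlhcc_fixed_cost * X).sum()
                    + (inst.llhcc_fixed_cost * y).sum()
                    + (cheapest_cost * X[:, None]).sum())
        if obj < best_obj - 1e-12:
            best_obj = obj
            best = (X, y, assignment)
    if best is None:
        return Stage1Solution(
            hlhcc_open=np.zeros(I), llhcc_open=np.zeros(I),
            assignment=np.zeros((I, I)),
            capacity_choice=tuple(np.zeros((I, inst.n_levels[n])) for n in range(N)),
            objective=None, status="infeasible",
        )
    X, y, assignment = best
    z = tuple(np.zeros((I, inst.n_levels[n])) for n in range(N))
    for n in range(N):
        for k in range(I):
            if X[k] > 0.5:
                z[n][k, cheapest_level[n][k]] = 1.0
    return Stage1Solution(
        hlhcc_open=X, llhcc_open=y, assignment=assignment,
        capacity_choice=z, objective=best_obj, status="optimal",
    )


# --- stage-2 enumeration ----------------------------------------------------

def _residual_lp(inst: Instance, s1: Stage1Solution, n: int, t: int,
                 links: frozenset, selector: tuple | None):
    """Exact residual LP for one (service, period) given open links.

    ``selector`` optionally pins ``(argmax node, argmin node)`` of the
    shortage-to-demand ratio and imposes the equity cap; ``None`` solves the
    uncapped problem. Returns ``(objective, var_values)`` or ``None`` if
    infeasible.
    """
    I = inst.n_nodes
    D = inst.demand[:, n, t]
    open_h = [k for k in range(I) if s1.hlhcc_open[k] > 0.5]
    open_l = [j for j in range(I) if s1.llhcc_open[j] > 0.5]
    cap = s1.installed_capacity(inst)

    vars_: list[tuple] = []
    bounds = []
    cost = []

    def add(kind, idx, c, ub=None):
        vars_.append((kind, idx))
        bounds.append((0.0, ub))
        cost.append(c)
        return len(vars_) - 1

    vh, vw, vu, ve, vB = {}, {}, {}, {}, {}
    for (j, j2) in links:
        vh[j, j2] = add("h", (j, j2), float(inst.llhcc_transfer_unit_cost[j, j2, n]))
    if inst.hlhcc_exclusive[n] < 0.5:
        for k in open_h:
            for j in open_l:
                if s1.assignment[j, k] > 0.5 and inst.hlhcc_coverage[j, k, n] > 0.5:
                    vw[k, j] = add("w", (k, j), float(inst.referral_unit_cost[k, j, n]))
    for k in open_h:
        for i in range(I):
            if inst.hlhcc_coverage[i, k, n] > 0.5:
                vu[k, i] = add("u", (k, i), float(inst.hlhcc_service_unit_cost[k, i, n]))
    for j in open_l:
        for i in range(I):
            if inst.llhcc_coverage[i, j, n] > 0.5:
                ve[j, i] = add("e", (j, i), float(inst.llhcc_service_unit_cost[j, i, n]))
    for i in range(I):
        vB[i] = add("B", (i,), float(inst.shortage_penalty[i, n]), ub=float(D[i]))

    nv = len(vars_)
    A_ub, b_ub = [], []

    def row(coeffs, rhs):
        r = np.zeros(nv)
        for v, c in coeffs.items():
            r[v] += c
        A_ub.append(r)
        b_ub.append(rhs)

    for k in open_h:
        coeffs = {v: 1.0 for (kk, j), v in vw.items() if kk == k}
        coeffs.update({v: 1.0 for (kk, i), v in vu.items() if kk == k})
        if coeffs:
            row(coeffs, float(cap[k, n]))
    for j in open_l:
        coeffs: dict[int, float] = {}
        for (k, jj), v in vw.items():
            if jj == j:
                coeffs[v] = coeffs.get(v, 0.0) - 1.0
        for (ja, jb), v in vh.items():
            if jb == j:
                coeffs[v] = coeffs.get(v, 0.0) - 1.0
            if ja == j:
                coeffs[v] = coeffs.get(v, 0.0) + 1.0
        for (jj, i), v in ve.items():
            if jj == j:
                coeffs[v] = coeffs.get(v, 0.0) + 1.0
        if coeffs:
            row(coeffs, 0.0)  # outflow - inflow <= 0
    for i in range(I):
        coeffs = {vB[i]: -1.0}
        for (j, ii), v in ve.items():
            if ii == i:
                coeffs[v] = coeffs.get(v, 0.0) - 1.0
        for (k, ii), v in vu.items():
            if ii == i:
                coeffs[v] = coeffs.get(v, 0.0) - 1.0
        row(coeffs, -float(D[i]))  # B + served >= D
    if selector is not None:
        i_max, i_min = selector
        for i in range(I):
            if D[i] <= 0:
                continue
            if i != i_max:
                row({vB[i]: 1.0 / D[i], vB[i_max]: -1.0 / D[i_max]}, 0.0)
            if i != i_min:
                row({vB[i_min]: 1.0 / D[i_min], vB[i]: -1.0 / D[i]}, 0.0)
        row({vB[i_max]: 1.0 / D[i_max], vB[i_min]: -1.0 / D[i_min]},
            float(inst.alpha_max[n]))

    res = linprog(np.array(cost), A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=bounds, method="highs")
    if res.status != 0:
        return None
    out = {}
    for v, (kind, idx) in enumerate(vars_):
        out[(kind, idx)] = float(res.x[v])
    return float(res.fun), out


def _block_value(inst, s1, n, t, links, cache):
    """Optimal residual value for one (service, period), equity cap enforced."""
    key = (n, t, links)
    if key in cache:
        return cache[key]
    D = inst.demand[:, n, t]
    dpos = [i for i in range(inst.n_nodes) if D[i] > 0]
    base = _residual_lp(inst, s1, n, t, links, None)
    result = None
    if base is not None:
        obj, vals = base
        B = np.array([vals[("B", (i,))] for i in range(inst.n_nodes)])
        gap = 0.0
        if dpos:
            r = np.array([B[i] / D[i] for i in dpos])
            gap = float(r.max() - r.min())
        if gap <= inst.alpha_max[n] + 1e-9 or not dpos:
            result = (obj, vals)
        else:
            best = None
            for i_max in dpos:
                for i_min in dpos:
                    sol = _residual_lp(inst, s1, n, t, links, (i_max, i_min))
                    if sol is not None and (best is None or sol[0] < best[0]):
                        best = sol
            result = best
    cache[key] = result
    return result


def enumerate_stage2(inst: Instance, s1: Stage1Solution,
                     max_nodes: int = 4, max_periods: int = 2,
                     max_link_vars: int = 12) -> Stage2Solution:
    """Brute-force optimal allocation for tiny instances.

    Enumerates all binary transfer-link patterns; with links fixed (and
    flows bounded by per-service demand) the residual splits by
    (service, period), so each block is priced by an exact LP, with
    extremal-node selector enumeration when the uncapped solution violates
    the equity cap. Equity is checked in its nonlinear form throughout.
    """
    I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
    if I > max_nodes or T > max_periods:
        raise CarelocError(
            f"enumeration oracle limited to {max_nodes} nodes / "
            f"{max_periods} periods, got {I} / {T}")
    if s1.status != "optimal" and not s1.ga_feasible:
        raise CarelocError("stage-2 oracle requires a feasible stage-1 solution")
    open_l = [j for j in range(I) if s1.llhcc_open[j] > 0.5]
    pairs = [(j, j2) for j in open_l for j2 in open_l if j != j2]
    link_vars = [(j, j2, t) for (j, j2) in pairs for t in range(T)]
    if len(link_vars) > max_link_vars:
        raise CarelocError(
            f"link pattern space too large ({len(link_vars)} link variables, "
            f"limit {max_link_vars})")

    cache: dict = {}
    best_obj = np.inf
    best_pattern = None
    best_blocks = None
    for bits in itertools.product((0, 1), repeat=len(link_vars)):
        x = np.zeros((I, I, T))
        for (j, j2, t), v in zip(link_vars, bits):
            x[j, j2, t] = float(v)
        link_cost = sum(
            inst.link_fixed_cost[j, j2] for (j, j2, t), v in zip(link_vars, bits)
            if v
        )
        total = float(link_cost)
        blocks = {}
        feasible = True
        for t in range(T):
            links_t = frozenset(
                (j, j2) for (j, j2) in pairs if x[j, j2, t] > 0.5)
            for n in range(N):
                blk = _block_value(inst, s1, n, t, links_t, cache)
                if blk is None:
                    feasible = False
                    break
                total += blk[0]
                blocks[n, t] = blk[1]
            if not feasible:
                break
        if feasible and total < best_obj - 1e-12:
            best_obj = total
            best_pattern = x
            best_blocks = blocks

    empty = Stage2Solution(
        link_open=np.zeros((I, I, T)), llhcc_transfer=np.zeros((I, I, N, T)),
        hlhcc_direct=np.zeros((I, I, N, T)), llhcc_direct=np.zeros((I, I, N, T)),
        referral=np.zeros((I, I, N, T)), shortage=np.zeros((I, N, T)),
        equity_gap=np.zeros((N, T)), max_ratio=np.zeros((N, T)),
        min_ratio=np.zeros((N, T)), max_selector=np.zeros((I, N, T)),
        min_selector=np.zeros((I, N, T)), max_product=np.zeros((I, N, T)),
        min_product=np.zeros((I, N, T)), objective=None, status="infeasible",
    )
    if best_pattern is None:
        return empty
    sol = empty
    sol.status = "optimal"
    sol.objective = float(best_obj)
    sol.link_open = best_pattern
    for (n, t), vals in best_blocks.items():
        for (kind, idx), v in vals.items():
            if kind == "h":
                sol.llhcc_transfer[idx[0], idx[1], n, t] = v
            elif kind == "w":
                sol.referral[idx[0], idx[1], n, t] = v
            elif kind == "u":
                sol.hlhcc_direct[idx[0], idx[1], n, t] = v
            elif kind == "e":
                sol.llhcc_direct[idx[0], idx[1], n, t] = v
            elif kind == "B":
                sol.shortage[idx[0], n, t] = v
    _fill_equity(inst, sol)
    return sol


def _fill_equity(inst: Instance, sol: Stage2Solution) -> None:
    """Populate the equity tensors from shortage and demand directly."""
    for n in range(inst.n_services):
        for t in range(inst.n_periods):
            d = inst.demand[:, n, t]
            pos = np.nonzero(d > 0)[0]
            if len(pos) == 0:
                continue
            r = sol.shortage[pos, n, t] / d[pos]
            i_max = pos[int(np.argmax(r))]
            i_min = pos[int(np.argmin(r))]
            sol.max_ratio[n, t] = float(r.max())
            sol.min_ratio[n, t] = float(r.min())
            sol.equity_gap[n, t] = float(r.max() - r.min())
            sol.max_selector[:, n, t] = 0.0
            sol.min_selector[:, n, t] = 0.0
            sol.max_selector[i_max, n, t] = 1.0
            sol.min_selector[i_min, n, t] = 1.0
            sol.max_product[:, n, t] = 0.0
            sol.min_product[:, n, t] = 0.0
            sol.max_product[i_max, n, t] = sol.shortage[i_max, n, t]
            sol.min_product[i_min, n, t] = sol.shortage[i_min, n, t]
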