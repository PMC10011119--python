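"""First stage: facility location MILP.

Decides which nodes host higher-level centers (HLHCCs) and which host
lower-level centers (LLHCCs), the assignment of each open LLHCC to an open
HLHCC within coverage, and one capacity level per (open HLHCC, service),
minimizing fixed opening plus capacity installation cost. Coverage-floor
constraints require every node, for every service, to be covered by at
least H open HLHCCs and V open LLHCCs.

A node may host at most one facility (never both tiers at once).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instance import CarelocError, Instance
from .milpcore import MipModel, solve

__all__ = ["Stage1Solution", "build_stage1_model", "solve_stage1", "covered_demand"]

_BTOL = 1e-6


@dataclass
class Stage1Solution:
    """Location-stage decisions.

    ``assignment[j, k] = 1`` means open LLHCC j is attached to open HLHCC k
    (referrals of capacity flow along these arcs in stage 2);
    ``capacity_choice[n][k, m] = 1`` selects level m of service n at HLHCC k.
    """

    hlhcc_open: np.ndarray                      # (I,) binary
    llhcc_open: np.ndarray                      # (I,) binary
    assignment: np.ndarray                      # (I, I) binary
    capacity_choice: tuple[np.ndarray, ...]     # per n: (I, M_n) binary
    objective: float | None
    status: str                                 # optimal | infeasible | time_limit
    infeasibility: list[dict] = field(default_factory=list)
    ga_feasible: bool | None = None             # set by the metaheuristic path

    def installed_capacity(self, inst: Instance) -> np.ndarray:
        """Installed units/period per (node, service)."""
        cap = np.zeros((inst.n_nodes, inst.n_services))
        for n in range(inst.n_services):
            cap[:, n] = self.capacity_choice[n] @ inst.capacity_levels[n]
        return cap

    def to_dict(self) -> dict:
        return {
            "hlhcc_open": self.hlhcc_open.astype(int).tolist(),
            "llhcc_open": self.llhcc_open.astype(int).tolist(),
            "assignment": self.assignment.astype(int).tolist(),
            "capacity_choice": [z.astype(int).tolist() for z in self.capacity_choice],
            "objective": self.objective,
            "status": self.status,
            "infeasibility": self.infeasibility,
        }

    @staticmethod
    def from_dict(d: dict) -> "Stage1Solution":
        return Stage1Solution(
            hlhcc_open=np.asarray(d["hlhcc_open"], float),
            llhcc_open=np.asarray(d["llhcc_open"], float),
            assignment=np.asarray(d["assignment"], float),
            capacity_choice=tuple(np.asarray(z, float) for z in d["capacity_choice"]),
            objective=d["objective"],
            status=d["status"],
            infeasibility=d.get("infeasibility", []),
        )


def build_stage1_model(inst: Instance, eq6_mode: str = "tight"):
    """Build the location MILP.

    Variables: ``X[k]`` (HLHCC at k), ``y[j]`` (LLHCC at j), ``XA[j,k]``
    (assignment, j != k), ``z[n][k,m]`` (capacity level).

    ``eq6_mode``: the assignment-within-coverage constraint. ``"tight"``
    (default) uses the equivalent XA[j,k] <= sum_n b[j,k,n]; ``"literal"``
    reproduces the big-M form XA[j,k] <= M * (sum_n b[j,k,n]) * X[k], which
    has the same integer feasible set but a weaker LP relaxation.

    Returns ``(model, index_maps)``.
    """
    if eq6_mode not in ("tight", "literal"):
        raise CarelocError("eq6_mode must be 'tight' or 'literal'")
    I, N = inst.n_nodes, inst.n_services
    b, a = inst.hlhcc_coverage, inst.llhcc_coverage
    m = MipModel()
    X = [m.add_binary(f"X_{k}") for k in range(I)]
    y = [m.add_binary(f"y_{j}") for j in range(I)]
    XA = {}
    for j in range(I):
        for k in range(I):
            if j != k:
                XA[j, k] = m.add_binary(f"XA_{j}_{k}")
    z = [
        [[m.add_binary(f"z_{k}_{n}_{lvl}") for lvl in range(inst.n_levels[n])]
         for k in range(I)]
        for n in range(N)
    ]

    obj: dict[int, float] = {}
    for k in range(I):
        obj[X[k]] = float(inst.hlhcc_fixed_cost[k])
        obj[y[k]] = float(inst.llhcc_fixed_cost[k])
    for n in range(N):
        for k in range(I):
            for lvl in range(inst.n_levels[n]):
                obj[z[n][k][lvl]] = float(inst.capacity_level_cost[n][k, lvl])
    m.set_objective(obj)

    big_m = inst.big_m if not isinstance(inst.big_m, str) else max(N, 1)
    for j in range(I):
        for k in range(I):
            if j == k:
                continue
            # assignment only to an open HLHCC
            m.add_le({XA[j, k]: 1.0, X[k]: -1.0}, 0.0, "assign_open")
            s = float(b[j, k, :].sum())
            if eq6_mode == "tight":
                m.add_le({XA[j, k]: 1.0}, min(s, 1.0), "assign_cover")
            else:
                m.add_le({XA[j, k]: 1.0, X[k]: -big_m * s}, 0.0, "assign_cover")
    for j in range(I):
        # each open LLHCC attached to exactly one HLHCC (other than itself)
        coeffs = {XA[j, k]: 1.0 for k in range(I) if k != j}
        coeffs[y[j]] = -1.0
        m.add_eq(coeffs, 0.0, "assign_count")
    for n in range(N):
        for k in range(I):
            coeffs = {z[n][k][lvl]: 1.0 for lvl in range(inst.n_levels[n])}
            coeffs[X[k]] = -1.0
            m.add_eq(coeffs, 0.0, "capacity_level_count")
    for i in range(I):
        m.add_le({X[i]: 1.0, y[i]: 1.0}, 1.0, "one_tier_per_node")
    for i in range(I):
        for n in range(N):
            m.add_ge(
                {X[k]: float(b[i, k, n]) for k in range(I) if b[i, k, n]},
                float(inst.min_hlhcc_cover), f"hlhcc_cover_floor_{i}_{n}",
            )
            m.add_ge(
                {y[j]: float(a[i, j, n]) for j in range(I) if a[i, j, n]},
                float(inst.min_llhcc_cover), f"llhcc_cover_floor_{i}_{n}",
            )
    return m, {"X": X, "y": y, "XA": XA, "z": z}


def _coverage_certificate(inst: Instance) -> list[dict]:
    """Rows (i, n) whose candidate pool cannot meet the coverage floor."""
    cert = []
    b_counts = inst.hlhcc_coverage.sum(axis=1)
    a_counts = inst.llhcc_coverage.sum(axis=1)
    for i in range(inst.n_nodes):
        for n in range(inst.n_services):
            if b_counts[i, n] < inst.min_hlhcc_cover:
                cert.append({
                    "family": "hlhcc_cover_floor", "node": i, "service": n,
                    "candidates": int(b_counts[i, n]),
                    "required": inst.min_hlhcc_cover,
                })
            if a_counts[i, n] < inst.min_llhcc_cover:
                cert.append({
                    "family": "llhcc_cover_floor", "node": i, "service": n,
                    "candidates": int(a_counts[i, n]),
                    "required": inst.min_llhcc_cover,
                })
    return cert


def solve_stage1(inst: Instance, time_limit: float | None = None,
                 backend: str = "highs", eq6_mode: str = "tight",
                 mip_gap: float | None = None,
                 lp_export_path=None) -> Stage1Solution:
    """Solve the location stage to proven optimality.

    On infeasibility the certificate lists coverage-floor rows whose
    candidate pools are too small (empty when infeasibility arises from
    constraint interplay, e.g. the one-facility-per-node rule).
    """
    model, ix = build_stage1_model(inst, eq6_mode=eq6_mode)
    if lp_export_path is not None:
        model.write_lp(lp_export_path)
    res = solve(model, backend=backend, time_limit=time_limit, mip_gap=mip_gap)
    I, N = inst.n_nodes, inst.n_services
    empty = Stage1Solution(
        hlhcc_open=np.zeros(I), llhcc_open=np.zeros(I),
        assignment=np.zeros((I, I)),
        capacity_choice=tuple(np.zeros((I, inst.n_levels[n])) for n in range(N)),
        objective=None, status=res.status,
    )
    if res.status != "optimal":
        if res.status == "infeasible":
            empty.infeasibility = _coverage_certificate(inst)
        return empty
    x = res.x
    sol = empty
    sol.status = "optimal"
    sol.objective = float(res.objective)
    sol.hlhcc_open = np.array([round(x[ix["X"][k]]) for k in range(I)], float)
    sol.llhcc_open = np.array([round(x[ix["y"][j]]) for j in range(I)], float)
    for (j, k), v in ix["XA"].items():
        sol.assignment[j, k] = round(x[v])
    for n in range(N):
        for k in range(I):
            for lvl in range(inst.n_levels[n]):
                sol.capacity_choice[n][k, lvl] = round(x[ix["z"][n][k][lvl]])
    return sol


def covered_demand(inst: Instance, sol: Stage1Solution) -> float:
    """Diagnostic: total demand within coverage of at least one open facility.

    Not part of the optimization objective; reported so coverage attained by
    a cost-minimal design can be inspected.
    """
    b, a = inst.hlhcc_coverage, inst.llhcc_coverage
    open_h = sol.hlhcc_open > 0.5
    open_l = sol.llhcc_open > 0.5
    covered = (
        (b[:, open_h, :].sum(axis=1) > 0) | (a[:, open_l, :].sum(axis=1) > 0)
    )  # (I, N)
    return float((inst.demand * covered[:, :, None]).sum())
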