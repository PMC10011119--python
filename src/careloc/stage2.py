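"""Second stage: multi-period allocation MILP with a max-min equity cap.

Given the located network, each period allocates capacitated service units:
HLHCCs serve covered demand directly (u), push referral capacity down to
their assigned LLHCCs (w), LLHCCs serve covered demand (e) and may move
units between each other over opened transfer links (x, h). Unmet demand is
a shortage (B), penalized per unit.

LLHCCs hold no intrinsic capacity: every unit an LLHCC dispenses originates
from HLHCC referral or inter-LLHCC transfer (a flow-balance constraint at
each LLHCC). This is the literal model and tends to surprise users.

Equity: per service and period, the spread alpha between the largest and
smallest node-level shortage-to-demand ratios is capped by alpha_max. The
max/min is nonlinear; it is linearized with binary selector variables
(beta', gamma') picking the extremal nodes and product variables
(beta'', gamma'') standing in for selector-times-shortage, via big-M rows.
Nodes with zero demand in a period are excluded from the selector sets
(their ratio is undefined).

Shortage variables are bounded above by demand. The bound is always
admissible (the shortage lower bound never exceeds demand) and gives the
equity big-M rows a finite valid constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instance import CarelocError, Instance
from .milpcore import MipModel, solve
from .stage1 import Stage1Solution

__all__ = [
    "Stage2Solution",
    "build_stage2_model",
    "solve_stage2",
    "total_cost",
    "equity_gaps",
]

_TOL = 1e-6


@dataclass
class Stage2Solution:
    """Allocation-stage decisions (dense tensors; closed facilities hold zeros)."""

    link_open: np.ndarray        # (I, I, T) binary, x[j, j', t]
    llhcc_transfer: np.ndarray   # (I, I, N, T), h[j, j', n, t]
    hlhcc_direct: np.ndarray     # (I, I, N, T), u[k, i, n, t]
    llhcc_direct: np.ndarray     # (I, I, N, T), e[j, i, n, t]
    referral: np.ndarray         # (I, I, N, T), w[k, j, n, t]
    shortage: np.ndarray         # (I, N, T), B
    equity_gap: np.ndarray       # (N, T), alpha
    max_ratio: np.ndarray        # (N, T), beta
    min_ratio: np.ndarray        # (N, T), gamma
    max_selector: np.ndarray     # (I, N, T) binary, beta'
    min_selector: np.ndarray     # (I, N, T) binary, gamma'
    max_product: np.ndarray      # (I, N, T), beta''
    min_product: np.ndarray      # (I, N, T), gamma''
    objective: float | None
    status: str
    infeasibility: list[dict] = field(default_factory=list)
    ga_feasible: bool | None = None

    def to_dict(self) -> dict:
        d = {}
        for name in ("link_open", "llhcc_transfer", "hlhcc_direct", "llhcc_direct",
                     "referral", "shortage", "equity_gap", "max_ratio", "min_ratio",
                     "max_selector", "min_selector", "max_product", "min_product"):
            d[name] = getattr(self, name).tolist()
        d["objective"] = self.objective
        d["status"] = self.status
        d["infeasibility"] = self.infeasibility
        return d

    @staticmethod
    def from_dict(d: dict) -> "Stage2Solution":
        kw = {
            name: np.asarray(d[name], float)
            for name in ("link_open", "llhcc_transfer", "hlhcc_direct",
                         "llhcc_direct", "referral", "shortage", "equity_gap",
                         "max_ratio", "min_ratio", "max_selector", "min_selector",
                         "max_product", "min_product")
        }
        return Stage2Solution(objective=d["objective"], status=d["status"],
                              infeasibility=d.get("infeasibility", []), **kw)

    def nonzero_flows(self) -> pd.DataFrame:
        """Long-format table of all nonzero flow entries."""
        rows = []
        for name, arr, labels in (
            ("transfer", self.llhcc_transfer, ("j", "j2", "n", "t")),
            ("hlhcc_direct", self.hlhcc_direct, ("k", "i", "n", "t")),
            ("llhcc_direct", self.llhcc_direct, ("j", "i", "n", "t")),
            ("referral", self.referral, ("k", "j", "n", "t")),
        ):
            for idx in zip(*np.nonzero(arr > _TOL)):
                rows.append((name, *map(int, idx), float(arr[idx])))
        return pd.DataFrame(rows, columns=["flow", "a", "b", "n", "t", "units"])

    def equity_report(self, inst: Instance) -> pd.DataFrame:
        """Per (service, period): max ratio, min ratio, gap, cap, binding flag."""
        rows = []
        for n in range(inst.n_services):
            for t in range(inst.n_periods):
                cap = float(inst.alpha_max[n])
                gap = float(self.equity_gap[n, t])
                rows.append({
                    "service": n, "period": t,
                    "max_ratio": float(self.max_ratio[n, t]),
                    "min_ratio": float(self.min_ratio[n, t]),
                    "equity_gap": gap, "cap": cap,
                    "binding": abs(gap - cap) <= 1e-6,
                })
        return pd.DataFrame(rows)


def equity_gaps(inst: Instance, shortage: np.ndarray) -> np.ndarray:
    """Nonlinear equity gap per (service, period) from shortage and demand.

    Spread between the largest and smallest shortage-to-demand ratio across
    nodes with positive demand; 0 when fewer than one such node exists.
    """
    N, T = inst.n_services, inst.n_periods
    out = np.zeros((N, T))
    for n in range(N):
        for t in range(T):
            d = inst.demand[:, n, t]
            pos = d > 0
            if pos.sum() == 0:
                continue
            r = shortage[pos, n, t] / d[pos]
            out[n, t] = float(r.max() - r.min())
    return out


def _flow_big_m(inst: Instance) -> np.ndarray:
    """Per-service valid flow bound: total demand of the service."""
    return inst.demand.sum(axis=(0, 2))  # (N,)


def build_stage2_model(
    inst: Instance,
    s1: Stage1Solution,
    equity_sign_mode: str = "corrected",
    include_equity: bool = True,
    integer_flows: bool = False,
    fixed_links: np.ndarray | None = None,
):
    """Build the allocation MILP given a located network.

    Parameters
    ----------
    equity_sign_mode
        ``"corrected"`` (default) uses the symmetric product linearization
        for the min-ratio side, mirroring the max-ratio side. ``"printed"``
        reproduces a sign-swapped variant whose min-side rows are jointly
        infeasible whenever a selector is off and the big-M is positive;
        kept only to demonstrate that defect.
    include_equity
        When False, all equity variables and rows are omitted (used for
        relaxation-ordering checks and infeasibility diagnosis).
    fixed_links
        Optional (I, I, T) binary tensor fixing the transfer-link pattern;
        link variables are then not created and their fixed cost enters the
        objective as a constant.

    Returns ``(model, index_maps, objective_constant)``.
    """
    if s1.status not in ("optimal",) and not s1.ga_feasible:
        raise CarelocError("stage-2 model requires an optimal or GA-feasible stage-1 solution")
    if equity_sign_mode not in ("corrected", "printed"):
        raise CarelocError("equity_sign_mode must be 'corrected' or 'printed'")
    I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
    D = inst.demand
    open_h = [k for k in range(I) if s1.hlhcc_open[k] > 0.5]
    open_l = [j for j in range(I) if s1.llhcc_open[j] > 0.5]
    cap_inst = s1.installed_capacity(inst)   # (I, N)

    auto = isinstance(inst.big_m, str)
    M_flow = _flow_big_m(inst) if auto else np.full(N, float(inst.big_m))
    M_link = float(M_flow.sum()) if auto else float(inst.big_m)
    # shortage is bounded by demand, so the per-service peak demand is a
    # valid constant for the equity product rows
    M_eq = D.max(axis=(0, 2)) if auto else np.full(N, float(inst.big_m))
    M_eq = np.maximum(M_eq, 1.0)

    m = MipModel()
    ix: dict[str, dict] = {k: {} for k in
                           ("x", "h", "w", "u", "e", "B",
                            "alpha", "beta", "gamma",
                            "beta_sel", "gamma_sel", "beta_prod", "gamma_prod")}
    const = 0.0
    obj: dict[int, float] = {}

    pairs = [(j, j2) for j in open_l for j2 in open_l if j != j2]
    for (j, j2) in pairs:
        for t in range(T):
            if fixed_links is None:
                v = m.add_binary(f"x_{j}_{j2}_{t}")
                ix["x"][j, j2, t] = v
                obj[v] = float(inst.link_fixed_cost[j, j2])
            elif fixed_links[j, j2, t] > 0.5:
                const += float(inst.link_fixed_cost[j, j2])

    for (j, j2) in pairs:
        for n in range(N):
            for t in range(T):
                if fixed_links is not None and fixed_links[j, j2, t] < 0.5:
                    continue  # closed link carries no transfer
                v = m.add_var(f"h_{j}_{j2}_{n}_{t}", 0.0, float(M_flow[n]),
                              integer=integer_flows)
                ix["h"][j, j2, n, t] = v
                obj[v] = float(inst.llhcc_transfer_unit_cost[j, j2, n])

    for k in open_h:
        for n in range(N):
            if inst.hlhcc_exclusive[n] > 0.5:
                continue  # exclusive services are never referred down
            for j in open_l:
                if s1.assignment[j, k] > 0.5 and inst.hlhcc_coverage[j, k, n] > 0.5:
                    for t in range(T):
                        v = m.add_var(f"w_{k}_{j}_{n}_{t}", 0.0, float(M_flow[n]),
                                      integer=integer_flows)
                        ix["w"][k, j, n, t] = v
                        obj[v] = float(inst.referral_unit_cost[k, j, n])

    for k in open_h:
        for i in range(I):
            for n in range(N):
                if inst.hlhcc_coverage[i, k, n] > 0.5:
                    for t in range(T):
                        v = m.add_var(f"u_{k}_{i}_{n}_{t}", 0.0, float(M_flow[n]),
                                      integer=integer_flows)
                        ix["u"][k, i, n, t] = v
                        obj[v] = float(inst.hlhcc_service_unit_cost[k, i, n])

    for j in open_l:
        for i in range(I):
            for n in range(N):
                if inst.llhcc_coverage[i, j, n] > 0.5:
                    for t in range(T):
                        v = m.add_var(f"e_{j}_{i}_{n}_{t}", 0.0, float(M_flow[n]),
                                      integer=integer_flows)
                        ix["e"][j, i, n, t] = v
                        obj[v] = float(inst.llhcc_service_unit_cost[j, i, n])

    for i in range(I):
        for n in range(N):
            for t in range(T):
                v = m.add_var(f"B_{i}_{n}_{t}", 0.0, float(D[i, n, t]))
                ix["B"][i, n, t] = v
                obj[v] = float(inst.shortage_penalty[i, n])

    # capacity at each open HLHCC, per service and period
    for k in open_h:
        for n in range(N):
            for t in range(T):
                coeffs = {}
                for j in open_l:
                    v = ix["w"].get((k, j, n, t))
                    if v is not None:
                        coeffs[v] = 1.0
                for i in range(I):
                    v = ix["u"].get((k, i, n, t))
                    if v is not None:
                        coeffs[v] = 1.0
                if coeffs:
                    m.add_le(coeffs, float(cap_inst[k, n]), "hlhcc_capacity")

    # transfers only over opened links
    if fixed_links is None:
        for (j, j2) in pairs:
            for t in range(T):
                coeffs = {ix["h"][j, j2, n, t]: 1.0 for n in range(N)
                          if (j, j2, n, t) in ix["h"]}
                if coeffs:
                    coeffs[ix["x"][j, j2, t]] = -M_link
                    m.add_le(coeffs, 0.0, "transfer_needs_link")

    # LLHCC flow balance: inflow (referral + transfer) covers outflow
    for j in open_l:
        for n in range(N):
            for t in range(T):
                coeffs: dict[int, float] = {}
                for k in open_h:
                    v = ix["w"].get((k, j, n, t))
                    if v is not None:
                        coeffs[v] = 1.0
                for j2 in open_l:
                    v = ix["h"].get((j2, j, n, t))
                    if v is not None:
                        coeffs[v] = coeffs.get(v, 0.0) + 1.0
                    v = ix["h"].get((j, j2, n, t))
                    if v is not None:
                        coeffs[v] = coeffs.get(v, 0.0) - 1.0
                for i in range(I):
                    v = ix["e"].get((j, i, n, t))
                    if v is not None:
                        coeffs[v] = coeffs.get(v, 0.0) - 1.0
                if coeffs:
                    m.add_ge(coeffs, 0.0, "llhcc_balance")

    # shortage definition
    for i in range(I):
        for n in range(N):
            for t in range(T):
                coeffs = {ix["B"][i, n, t]: 1.0}
                for j in open_l:
                    v = ix["e"].get((j, i, n, t))
                    if v is not None:
                        coeffs[v] = 1.0
                for k in open_h:
                    v = ix["u"].get((k, i, n, t))
                    if v is not None:
                        coeffs[v] = 1.0
                m.add_ge(coeffs, float(D[i, n, t]), "shortage_floor")

    if include_equity:
        for n in range(N):
            Mn = float(M_eq[n])
            for t in range(T):
                dpos = [i for i in range(I) if D[i, n, t] > 0]
                if not dpos:
                    continue
                va = m.add_var(f"alpha_{n}_{t}", 0.0, np.inf)
                vb = m.add_var(f"beta_{n}_{t}", 0.0, np.inf)
                vg = m.add_var(f"gamma_{n}_{t}", 0.0, np.inf)
                ix["alpha"][n, t] = va
                ix["beta"][n, t] = vb
                ix["gamma"][n, t] = vg
                m.add_eq({va: 1.0, vb: -1.0, vg: 1.0}, 0.0, "equity_gap_def")
                m.add_le({va: 1.0}, float(inst.alpha_max[n]), f"equity_cap_{n}_{t}")
                beta_sum: dict[int, float] = {vb: -1.0}
                gamma_sum: dict[int, float] = {vg: -1.0}
                sel_b: dict[int, float] = {}
                sel_g: dict[int, float] = {}
                for i in dpos:
                    d_i = float(D[i, n, t])
                    Bv = ix["B"][i, n, t]
                    bs = m.add_binary(f"bsel_{i}_{n}_{t}")
                    gs = m.add_binary(f"gsel_{i}_{n}_{t}")
                    bp = m.add_var(f"bprod_{i}_{n}_{t}", 0.0, Mn)
                    gp = m.add_var(f"gprod_{i}_{n}_{t}", 0.0, Mn)
                    ix["beta_sel"][i, n, t] = bs
                    ix["gamma_sel"][i, n, t] = gs
                    ix["beta_prod"][i, n, t] = bp
                    ix["gamma_prod"][i, n, t] = gp
                    sel_b[bs] = 1.0
                    sel_g[gs] = 1.0
                    beta_sum[bp] = 1.0 / d_i
                    gamma_sum[gp] = 1.0 / d_i
                    # beta'' tracks B on the selected node, 0 elsewhere
                    m.add_ge({bp: 1.0, Bv: -1.0, bs: -Mn}, -Mn, "max_prod_lo")
                    m.add_le({bp: 1.0, Bv: -1.0, bs: Mn}, Mn, "max_prod_hi")
                    m.add_le({bp: 1.0, bs: -Mn}, 0.0, "max_prod_gate")
                    if equity_sign_mode == "corrected":
                        m.add_ge({gp: 1.0, Bv: -1.0, gs: -Mn}, -Mn, "min_prod_lo")
                        m.add_le({gp: 1.0, Bv: -1.0, gs: Mn}, Mn, "min_prod_hi")
                    else:
                        # printed variant: plus/minus swapped on the min side
                        m.add_ge({gp: 1.0, Bv: -1.0, gs: Mn}, Mn, "min_prod_lo_printed")
                        m.add_le({gp: 1.0, Bv: -1.0, gs: -Mn}, -Mn, "min_prod_hi_printed")
                    m.add_le({gp: 1.0, gs: -Mn}, 0.0, "min_prod_gate")
                    m.add_ge({vb: 1.0, Bv: -1.0 / d_i}, 0.0, "max_ratio_bound")
                    m.add_le({vg: 1.0, Bv: -1.0 / d_i}, 0.0, "min_ratio_bound")
                m.add_eq(sel_b, 1.0, "one_max_selector")
                m.add_eq(sel_g, 1.0, "one_min_selector")
                m.add_eq(beta_sum, 0.0, "max_ratio_def")
                m.add_eq(gamma_sum, 0.0, "min_ratio_def")

    m.set_objective(obj)
    return m, ix, const


def _extract(inst: Instance, s1: Stage1Solution, ix, x: np.ndarray,
             objective: float, status: str,
             fixed_links: np.ndarray | None) -> Stage2Solution:
    I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
    sol = Stage2Solution(
        link_open=np.zeros((I, I, T)),
        llhcc_transfer=np.zeros((I, I, N, T)),
        hlhcc_direct=np.zeros((I, I, N, T)),
        llhcc_direct=np.zeros((I, I, N, T)),
        referral=np.zeros((I, I, N, T)),
        shortage=np.zeros((I, N, T)),
        equity_gap=np.zeros((N, T)),
        max_ratio=np.zeros((N, T)),
        min_ratio=np.zeros((N, T)),
        max_selector=np.zeros((I, N, T)),
        min_selector=np.zeros((I, N, T)),
        max_product=np.zeros((I, N, T)),
        min_product=np.zeros((I, N, T)),
        objective=objective, status=status,
    )
    if fixed_links is not None:
        sol.link_open = np.asarray(fixed_links, float).copy()
        # zero out pairs that are not both open (defensive)
        mask = (s1.llhcc_open[:, None] > 0.5) & (s1.llhcc_open[None, :] > 0.5)
        np.fill_diagonal(mask, False)
        sol.link_open *= mask[:, :, None]
    for (j, j2, t), v in ix["x"].items():
        sol.link_open[j, j2, t] = round(x[v])
    for (j, j2, n, t), v in ix["h"].items():
        sol.llhcc_transfer[j, j2, n, t] = max(0.0, x[v])
    for (k, i, n, t), v in ix["u"].items():
        sol.hlhcc_direct[k, i, n, t] = max(0.0, x[v])
    for (j, i, n, t), v in ix["e"].items():
        sol.llhcc_direct[j, i, n, t] = max(0.0, x[v])
    for (k, j, n, t), v in ix["w"].items():
        sol.referral[k, j, n, t] = max(0.0, x[v])
    for (i, n, t), v in ix["B"].items():
        sol.shortage[i, n, t] = max(0.0, x[v])
    for (n, t), v in ix["alpha"].items():
        sol.equity_gap[n, t] = x[v]
    for (n, t), v in ix["beta"].items():
        sol.max_ratio[n, t] = x[v]
    for (n, t), v in ix["gamma"].items():
        sol.min_ratio[n, t] = x[v]
    for (i, n, t), v in ix["beta_sel"].items():
        sol.max_selector[i, n, t] = round(x[v])
    for (i, n, t), v in ix["gamma_sel"].items():
        sol.min_selector[i, n, t] = round(x[v])
    for (i, n, t), v in ix["beta_prod"].items():
        sol.max_product[i, n, t] = max(0.0, x[v])
    for (i, n, t), v in ix["gamma_prod"].items():
        sol.min_product[i, n, t] = max(0.0, x[v])
    return sol


def _equity_certificate(inst: Instance, s1: Stage1Solution, backend,
                        time_limit) -> list[dict]:
    """Name the (service, period) rows whose equity cap forces infeasibility."""
    try:
        relaxed = solve_stage2(inst, s1, time_limit=time_limit, backend=backend,
                               include_equity=False)
    except CarelocError:
        return []
    if relaxed.status != "optimal":
        return []
    gaps = equity_gaps(inst, relaxed.shortage)
    cert = []
    for n in range(inst.n_services):
        for t in range(inst.n_periods):
            if gaps[n, t] > inst.alpha_max[n] + _TOL:
                cert.append({
                    "family": "equity_cap", "service": n, "period": t,
                    "uncapped_gap": float(gaps[n, t]),
                    "cap": float(inst.alpha_max[n]),
                })
    return cert


def solve_stage2(
    inst: Instance,
    s1: Stage1Solution,
    time_limit: float | None = None,
    backend: str = "highs",
    equity_sign_mode: str = "corrected",
    include_equity: bool = True,
    integer_flows: bool = False,
    fixed_links: np.ndarray | None = None,
    mip_gap: float | None = None,
    lp_export_path=None,
) -> Stage2Solution:
    """Solve the allocation stage.

    On success the linearized extremal ratios are re-verified post hoc
    against the direct nonlinear recomputation from shortage and demand.
    On infeasibility the certificate names the (service, period) rows whose
    equity cap binds below the uncapped optimum's gap.
    """
    model, ix, const = build_stage2_model(
        inst, s1, equity_sign_mode=equity_sign_mode,
        include_equity=include_equity, integer_flows=integer_flows,
        fixed_links=fixed_links,
    )
    if lp_export_path is not None:
        model.write_lp(lp_export_path)
    if model.n_vars == 0:
        # degenerate instance: nothing to decide
        sol = _extract(inst, s1, ix, np.zeros(0), const, "optimal", fixed_links)
        return sol
    res = solve(model, backend=backend, time_limit=time_limit, mip_gap=mip_gap)
    if res.status != "optimal":
        I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
        sol = _extract(inst, s1, ix, np.zeros(model.n_vars), None,
                       res.status, fixed_links)
        if res.status == "infeasible" and include_equity:
            sol.infeasibility = _equity_certificate(inst, s1, backend, time_limit)
        return sol
    sol = _extract(inst, s1, ix, res.x, float(res.objective) + const,
                   "optimal", fixed_links)
    if include_equity:
        _verify_equity(inst, sol)
    else:
        # report the achieved (unconstrained) equity figures
        sol.equity_gap = equity_gaps(inst, sol.shortage)
    return sol


def _verify_equity(inst: Instance, sol: Stage2Solution, tol: float = 1e-5) -> None:
    """Check beta/gamma against direct max/min recomputation from B and D."""
    for n in range(inst.n_services):
        for t in range(inst.n_periods):
            d = inst.demand[:, n, t]
            pos = d > 0
            if pos.sum() == 0:
                continue
            r = sol.shortage[pos, n, t] / d[pos]
            if abs(sol.max_ratio[n, t] - r.max()) > tol or \
               abs(sol.min_ratio[n, t] - r.min()) > tol:
                raise CarelocError(
                    "equity linearization mismatch at "
                    f"(service={n}, period={t}): beta={sol.max_ratio[n, t]:.8f} "
                    f"vs max={r.max():.8f}, gamma={sol.min_ratio[n, t]:.8f} "
                    f"vs min={r.min():.8f}"
                )


def total_cost(s1: Stage1Solution, s2: Stage2Solution) -> tuple[float, float, float]:
    """Return (location cost, allocation cost, combined total).

    The two stages are solved sequentially; the combined figure is reported
    for convenience, it is never jointly optimized.
    """
    if s1.status != "optimal" and not s1.ga_feasible:
        raise CarelocError("stage-1 solution is not optimal/feasible")
    if s2.status != "optimal" and not s2.ga_feasible:
        raise CarelocError("stage-2 solution is not optimal/feasible")
    if s1.hlhcc_open.shape[0] != s2.shortage.shape[0]:
        raise CarelocError("solutions belong to different instances")
    return (float(s1.objective), float(s2.objective),
            float(s1.objective) + float(s2.objective))
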