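"""Minimal mixed-integer linear model container with pluggable backends.

Two backends are provided:

``highs``
    scipy's bundled HiGHS branch-and-cut (:func:`scipy.optimize.milp`).
``bnb``
    A self-contained best-bound branch-and-bound over LP relaxations solved
    with :func:`scipy.optimize.linprog`. Intended for small models and for
    cross-checking the primary backend, not for production-size instances.

Models are built once and handed to :func:`solve`; rows are stored sparsely
as ``(indices, coefficients, lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = ["MipModel", "MipResult", "solve", "BACKENDS"]

BACKENDS = ("highs", "bnb")

_INT_TOL = 1e-6


@dataclass
class MipResult:
    status: str                 # optimal | infeasible | time_limit | unbounded
    x: np.ndarray | None
    objective: float | None


@dataclass
class MipModel:
    """A linear model: minimize c.x subject to lo <= A x <= hi, bounds, integrality."""

    names: list[str] = field(default_factory=list)
    lb: list[float] = field(default_factory=list)
    ub: list[float] = field(default_factory=list)
    integer: list[bool] = field(default_factory=list)
    obj: dict[int, float] = field(default_factory=dict)
    rows: list[tuple[list[int], list[float], float, float, str]] = field(
        default_factory=list
    )

    @property
    def n_vars(self) -> int:
        return len(self.names)

    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf,
                integer: bool = False) -> int:
        self.names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)
        self.integer.append(integer)
        return len(self.names) - 1

    def add_binary(self, name: str) -> int:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def add_constr(self, coeffs: dict[int, float], lo: float, hi: float,
                   name: str = "") -> None:
        idx = list(coeffs.keys())
        val = [float(coeffs[i]) for i in idx]
        self.rows.append((idx, val, float(lo), float(hi), name))

    def add_le(self, coeffs, rhs, name=""):
        self.add_constr(coeffs, -np.inf, rhs, name)

    def add_ge(self, coeffs, rhs, name=""):
        self.add_constr(coeffs, rhs, np.inf, name)

    def add_eq(self, coeffs, rhs, name=""):
        self.add_constr(coeffs, rhs, rhs, name)

    def set_objective(self, coeffs: dict[int, float]) -> None:
        self.obj = {int(k): float(v) for k, v in coeffs.items()}

    def matrices(self):
        c = np.zeros(self.n_vars)
        for i, v in self.obj.items():
            c[i] = v
        if self.rows:
            data, ri, ci = [], [], []
            lo = np.empty(len(self.rows))
            hi = np.empty(len(self.rows))
            for r, (idx, val, l, h, _) in enumerate(self.rows):
                ri.extend([r] * len(idx))
                ci.extend(idx)
                data.extend(val)
                lo[r], hi[r] = l, h
            A = sparse.csr_matrix(
                (data, (ri, ci)), shape=(len(self.rows), self.n_vars)
            )
        else:
            A = sparse.csr_matrix((0, self.n_vars))
            lo = np.zeros(0)
            hi = np.zeros(0)
        return c, A, lo, hi

    def write_lp(self, path) -> None:
        """Export in CPLEX LP text format (for debugging)."""
        c, A, lo, hi = self.matrices()
        A = A.tocsr()

        def term(coef, j, first):
            s = "" if (first and coef >= 0) else ("+ " if coef >= 0 else "- ")
            return f"{s}{abs(coef):.12g} {self.names[j]}"

        lines = ["Minimize", " obj: " + (" ".join(
            term(c[j], j, k == 0) for k, j in enumerate(np.nonzero(c)[0])
        ) or "0 " + (self.names[0] if self.names else "x0"))]
        lines.append("Subject To")
        rcount = 0
        for r in range(A.shape[0]):
            row = A.getrow(r)
            expr = " ".join(
                term(v, j, k == 0)
                for k, (j, v) in enumerate(zip(row.indices, row.data))
            ) or "0 " + self.names[0]
            rname = self.rows[r][4] or f"c{r}"
            if lo[r] == hi[r]:
                lines.append(f" {rname}_{rcount}: {expr} = {lo[r]:.12g}")
            else:
                if np.isfinite(hi[r]):
                    lines.append(f" {rname}_{rcount}u: {expr} <= {hi[r]:.12g}")
                if np.isfinite(lo[r]):
                    lines.append(f" {rname}_{rcount}l: {expr} >= {lo[r]:.12g}")
            rcount += 1
        lines.append("Bounds")
        for j in range(self.n_vars):
            l, u = self.lb[j], self.ub[j]
            uu = f"{u:.12g}" if np.isfinite(u) else "+inf"
            lines.append(f" {l:.12g} <= {self.names[j]} <= {uu}")
        ints = [self.names[j] for j in range(self.n_vars) if self.integer[j]]
        if ints:
            lines.append("General")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# --- backends ---------------------------------------------------------------

def _solve_highs(model: MipModel, time_limit, mip_gap) -> MipResult:
    c, A, lo, hi = model.matrices()
    integrality = np.array(model.integer, dtype=int)
    bounds = Bounds(np.array(model.lb), np.array(model.ub))
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    if mip_gap is not None:
        options["mip_rel_gap"] = float(mip_gap)
    cons = LinearConstraint(A, lo, hi) if A.shape[0] else None
    res = milp(
        c,
        constraints=cons,
        integrality=integrality,
        bounds=bounds,
        options=options or None,
    )
    if res.status == 0:
        return MipResult("optimal", np.asarray(res.x), float(res.fun))
    if res.status == 2:
        return MipResult("infeasible", None, None)
    if res.status == 3:
        return MipResult("unbounded", None, None)
    # iteration/time limit or numerical trouble
    x = np.asarray(res.x) if res.x is not None else None
    f = float(res.fun) if res.fun is not None else None
    return MipResult("time_limit", x, f)


def _lp_relax(model: MipModel, lb, ub):
    c, A, lo, hi = model.matrices()
    ub_rows, ub_rhs, eq_rows, eq_rhs = [], [], [], []
    A = A.tocsr()
    for r in range(A.shape[0]):
        if lo[r] == hi[r]:
            eq_rows.append(r)
            eq_rhs.append(lo[r])
        else:
            if np.isfinite(hi[r]):
                ub_rows.append((r, 1.0, hi[r]))
            if np.isfinite(lo[r]):
                ub_rows.append((r, -1.0, -lo[r]))
    if ub_rows:
        A_ub = sparse.vstack([s * A.getrow(r) for r, s, _ in ub_rows]).tocsr()
        b_ub = np.array([b for _, _, b in ub_rows])
    else:
        A_ub, b_ub = None, None
    A_eq = A[eq_rows] if eq_rows else None
    b_eq = np.array(eq_rhs) if eq_rows else None
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=list(zip(lb, ub)), method="highs",
    )
    return res


def _solve_bnb(model: MipModel, time_limit, mip_gap, node_limit=100_000) -> MipResult:
    """Best-first branch-and-bound over LP relaxations (small models only)."""
    import heapq
    import time as _time

    t0 = _time.monotonic()
    int_idx = [j for j, isint in enumerate(model.integer) if isint]
    lb0 = list(model.lb)
    ub0 = list(model.ub)

    incumbent: np.ndarray | None = None
    inc_obj = np.inf
    timed_out = False

    root = _lp_relax(model, lb0, ub0)
    if root.status == 2:
        return MipResult("infeasible", None, None)
    if root.status == 3:
        return MipResult("unbounded", None, None)
    heap = [(root.fun, 0, lb0, ub0, root)]
    counter = 1
    nodes = 0
    while heap:
        bound, _, lb, ub, res = heapq.heappop(heap)
        if bound >= inc_obj - 1e-9:
            continue
        nodes += 1
        if nodes > node_limit or (
            time_limit is not None and _time.monotonic() - t0 > time_limit
        ):
            timed_out = True
            break
        x = np.asarray(res.x)
        frac = [(abs(x[j] - round(x[j])), j) for j in int_idx]
        worst = max(frac, default=(0.0, -1))
        if worst[0] <= _INT_TOL:
            xr = x.copy()
            for j in int_idx:
                xr[j] = round(xr[j])
            if res.fun < inc_obj - 1e-9:
                inc_obj = res.fun
                incumbent = xr
            continue
        j = worst[1]
        floor_v = np.floor(x[j])
        for new_lb, new_ub in (
            (lb, [*ub[:j], floor_v, *ub[j + 1:]]),
            ([*lb[:j], floor_v + 1, *lb[j + 1:]], ub),
        ):
            child = _lp_relax(model, new_lb, new_ub)
            if child.status == 0 and child.fun < inc_obj - 1e-9:
                heapq.heappush(heap, (child.fun, counter, new_lb, new_ub, child))
                counter += 1
    if incumbent is None:
        return MipResult("time_limit" if timed_out else "infeasible", None, None)
    return MipResult(
        "time_limit" if timed_out else "optimal", incumbent, float(inc_obj)
    )


def solve(model: MipModel, backend: str = "highs", time_limit: float | None = None,
          mip_gap: float | None = None) -> MipResult:
    """Solve a model with the named backend."""
    if backend == "highs":
        return _solve_highs(model, time_limit, mip_gap)
    if backend == "bnb":
        return _solve_bnb(model, time_limit, mip_gap)
    raise ValueError(f"unknown backend '{backend}'; choose from {BACKENDS}")
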