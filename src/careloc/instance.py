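"""Problem data model for the two-stage hierarchical healthcare network.

A problem instance lives on a set of nodes that are simultaneously demand
points and candidate sites for both facility tiers: higher-level healthcare
centers (HLHCCs, which hold all service capacity) and lower-level healthcare
centers (LLHCCs, which dispense services received by referral or transfer).
Coverage is binary: a facility may serve a node for a service only if the
node lies within that facility's per-service coverage radius.

This module defines the immutable :class:`Instance` record, a seeded
synthetic-instance generator, and JSON/CSV readers and writers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CarelocError",
    "SchemaError",
    "Instance",
    "GeometryConfig",
    "coverage_from_distances",
    "generate_instance",
    "read_instance",
    "write_instance",
    "instance_to_long_csv",
]


class CarelocError(Exception):
    """Base error for this package."""


class SchemaError(CarelocError):
    """Raised when an instance file violates the documented schema.

    The message always names the offending field.
    """


# --- core data record -------------------------------------------------------

#: JSON keys required in an instance file, in schema order.
_REQUIRED_FIELDS = (
    "n_nodes",
    "n_services",
    "n_periods",
    "capacity_levels",
    "hlhcc_fixed_cost",
    "llhcc_fixed_cost",
    "capacity_level_cost",
    "hlhcc_coverage",
    "llhcc_coverage",
    "demand",
    "link_fixed_cost",
    "llhcc_transfer_unit_cost",
    "hlhcc_service_unit_cost",
    "llhcc_service_unit_cost",
    "referral_unit_cost",
    "shortage_penalty",
    "hlhcc_exclusive",
    "min_hlhcc_cover",
    "min_llhcc_cover",
    "alpha_max",
    "big_m",
)


@dataclass(frozen=True)
class Instance:
    """Immutable problem data for the two-stage location-allocation model.

    Index conventions (0-based): nodes ``i, j, j', k`` in ``range(n_nodes)``,
    services ``n`` in ``range(n_services)``, periods ``t`` in
    ``range(n_periods)``, capacity levels ``m`` per service.

    Parameters
    ----------
    capacity_levels
        Per service, the ordered menu of installable capacities
        (units/period); strictly increasing within a service.
    capacity_level_cost
        ``G[k][n][m]`` — cost of installing level ``m`` of service ``n`` at
        HLHCC site ``k``; a list over services of ``(n_nodes, M_n)`` arrays.
    hlhcc_coverage, llhcc_coverage
        Binary tensors ``b[x, k, n]`` / ``a[i, j, n]``: node ``x`` (``i``)
        lies within site ``k``'s (``j``'s) coverage radius for service ``n``.
        Diagonals are 1 — a site always covers its own node.
    demand
        ``D[i, n, t]`` patients per period.
    hlhcc_exclusive
        ``A[n] = 1`` marks services that may never be referred down to
        LLHCCs (e.g. emergency care).
    min_hlhcc_cover, min_llhcc_cover
        Access-equity floors H and V: every node must be covered by at
        least H open HLHCCs and V open LLHCCs for every service.
    alpha_max
        Per-service cap on the spread between the largest and smallest
        node-level shortage-to-demand ratios in any period.
    big_m
        Either the string ``"auto"`` (tight per-constraint-family bounds)
        or a single positive number used literally everywhere.
    """

    n_nodes: int
    n_services: int
    n_periods: int
    capacity_levels: tuple[np.ndarray, ...]          # per n: (M_n,)
    hlhcc_fixed_cost: np.ndarray                     # (I,)
    llhcc_fixed_cost: np.ndarray                     # (I,)
    capacity_level_cost: tuple[np.ndarray, ...]      # per n: (I, M_n)
    hlhcc_coverage: np.ndarray                       # (I, I, N) binary, b[x,k,n]
    llhcc_coverage: np.ndarray                       # (I, I, N) binary, a[i,j,n]
    demand: np.ndarray                               # (I, N, T)
    link_fixed_cost: np.ndarray                      # (I, I)
    llhcc_transfer_unit_cost: np.ndarray             # (I, I, N)  c'[j,j',n]
    hlhcc_service_unit_cost: np.ndarray              # (I, I, N)  q'[k,i,n]
    llhcc_service_unit_cost: np.ndarray              # (I, I, N)  q[j,i,n]
    referral_unit_cost: np.ndarray                   # (I, I, N)  c''[k,j,n]
    shortage_penalty: np.ndarray                     # (I, N)
    hlhcc_exclusive: np.ndarray                      # (N,) binary
    min_hlhcc_cover: int
    min_llhcc_cover: int
    alpha_max: np.ndarray                            # (N,)
    big_m: float | str = "auto"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _validate_instance(self)

    # number of capacity levels per service
    @property
    def n_levels(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.capacity_levels)

    @property
    def coverage_warning(self) -> bool:
        """True if some node cannot reach H HLHCC / V LLHCC candidates.

        A flagged instance may be stage-1 infeasible; the exact solver then
        reports infeasibility with a certificate.
        """
        b_counts = self.hlhcc_coverage.sum(axis=1)   # (I, N)
        a_counts = self.llhcc_coverage.sum(axis=1)
        return bool(
            (b_counts < self.min_hlhcc_cover).any()
            or (a_counts < self.min_llhcc_cover).any()
        )

    def equals(self, other: "Instance") -> bool:
        """Field-by-field equality (exact, including dtypes' values)."""
        if not isinstance(other, Instance):
            return False
        for f in dataclasses.fields(self):
            if f.name == "meta":
                continue
            va, vb = getattr(self, f.name), getattr(other, f.name)
            if isinstance(va, tuple):
                if len(va) != len(vb) or any(
                    not np.array_equal(x, y) for x, y in zip(va, vb)
                ):
                    return False
            elif isinstance(va, np.ndarray):
                if not np.array_equal(va, vb):
                    return False
            elif va != vb:
                return False
        return True


def _as_array(x, shape, name, binary=False, nonneg=True) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != tuple(shape):
        raise SchemaError(
            f"field '{name}': expected shape {tuple(shape)}, got {arr.shape}"
        )
    if nonneg and (arr < 0).any():
        raise SchemaError(f"field '{name}': negative entries are not allowed")
    if binary and not np.isin(arr, (0.0, 1.0)).all():
        raise SchemaError(f"field '{name}': entries must be 0 or 1")
    arr.setflags(write=False)
    return arr


def _validate_instance(inst: Instance) -> None:
    I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
    if I < 1 or N < 1 or T < 1:
        raise SchemaError("field 'n_nodes'/'n_services'/'n_periods': must be positive")
    if len(inst.capacity_levels) != N:
        raise SchemaError("field 'capacity_levels': one level menu per service required")
    for n, (cap, cost) in enumerate(zip(inst.capacity_levels, inst.capacity_level_cost)):
        if cap.ndim != 1 or len(cap) < 1:
            raise SchemaError(f"field 'capacity_levels'[{n}]: nonempty 1-D menu required")
        if cost.shape != (I, len(cap)):
            raise SchemaError(
                f"field 'capacity_level_cost'[{n}]: expected shape {(I, len(cap))}"
            )
    for name, cov in (("hlhcc_coverage", inst.hlhcc_coverage),
                      ("llhcc_coverage", inst.llhcc_coverage)):
        if not np.isin(cov, (0.0, 1.0)).all():
            raise SchemaError(f"field '{name}': entries must be 0 or 1")
        diag = cov[np.arange(I), np.arange(I), :]
        if not (diag == 1).all():
            raise SchemaError(f"field '{name}': a site must cover its own node")
    if (inst.demand < 0).any():
        raise SchemaError("field 'demand': negative demand")
    if inst.min_hlhcc_cover < 0 or inst.min_llhcc_cover < 0:
        raise SchemaError("field 'min_hlhcc_cover'/'min_llhcc_cover': must be >= 0")
    if ((inst.alpha_max < 0) | (inst.alpha_max > 1)).any():
        raise SchemaError("field 'alpha_max': entries must lie in [0, 1]")
    if isinstance(inst.big_m, str):
        if inst.big_m != "auto":
            raise SchemaError("field 'big_m': must be a positive number or 'auto'")
    elif inst.big_m <= 0:
        raise SchemaError("field 'big_m': must be a positive number or 'auto'")


# --- coverage ---------------------------------------------------------------

def coverage_from_distances(dist: np.ndarray, radius: Sequence[float]) -> np.ndarray:
    """Threshold a distance matrix into a binary coverage tensor.

    ``out[i, j, n] = 1`` iff ``dist[i, j] <= radius[n]`` (closed ball: a node
    exactly on the boundary counts as covered).

    Parameters
    ----------
    dist
        Symmetric nonnegative matrix with zero diagonal.
    radius
        One coverage radius per service.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise CarelocError("distance matrix must be square")
    if (dist < 0).any():
        raise CarelocError("distances must be nonnegative")
    if not np.allclose(dist, dist.T):
        raise CarelocError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise CarelocError("distance matrix must have a zero diagonal")
    radius = np.asarray(radius, dtype=float)
    if (radius <= 0).any():
        raise CarelocError("coverage radii must be strictly positive")
    return (dist[:, :, None] <= radius[None, None, :]).astype(np.int8)


# --- synthetic instance generator -------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Configuration for the seeded synthetic-instance generator.

    Nodes are placed uniformly at random in a square of the given side
    length; coverage tensors are derived by thresholding Euclidean distances
    against per-tier, per-service radii. The HLHCC radius must dominate the
    LLHCC radius for the same service (nested hierarchy). Costs and demand
    are drawn as integers so tiny instances admit exact integer arithmetic.
    """

    n_nodes: int
    seed: int
    n_services: int = 2
    n_periods: int = 2
    n_levels: int = 2
    side: float = 100.0
    llhcc_radius: float | Sequence[float] = 80.0
    hlhcc_radius: float | Sequence[float] = 120.0
    demand_range: tuple[int, int] = (5, 50)
    hlhcc_fixed_range: tuple[int, int] = (800, 1200)
    llhcc_fixed_range: tuple[int, int] = (300, 600)
    capacity_cost_range: tuple[int, int] = (50, 150)
    capacity_step_range: tuple[int, int] = (40, 120)
    link_cost_range: tuple[int, int] = (20, 60)
    transfer_cost_range: tuple[int, int] = (2, 8)
    service_cost_range: tuple[int, int] = (1, 6)
    shortage_penalty_range: tuple[int, int] = (50, 150)
    min_hlhcc_cover: int = 1
    min_llhcc_cover: int = 1
    alpha_max: float = 1.0
    p_exclusive: float = 0.0
    big_m: float | str = "auto"

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise CarelocError("n_nodes must be >= 2")
        r_l = np.broadcast_to(np.asarray(self.llhcc_radius, float), (self.n_services,))
        r_h = np.broadcast_to(np.asarray(self.hlhcc_radius, float), (self.n_services,))
        if (r_l <= 0).any() or (r_h <= 0).any():
            raise CarelocError("coverage radii must be strictly positive")
        if (r_h < r_l).any():
            raise CarelocError(
                "HLHCC radius must be >= LLHCC radius for every service "
                "(nested hierarchy)"
            )


def _rint(rng, lo_hi, size):
    lo, hi = lo_hi
    return rng.integers(lo, hi + 1, size=size).astype(float)


def generate_instance(config: GeometryConfig) -> Instance:
    """Generate a random instance; bit-identical for identical configs.

    Demand is drawn from a strictly positive range so the shortage-to-demand
    equity ratio is always defined. Capacity-level menus and their costs are
    strictly increasing in the level index.
    """
    rng = np.random.default_rng(config.seed)
    I, N, T = config.n_nodes, config.n_services, config.n_periods
    pts = rng.uniform(0.0, config.side, size=(I, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(dist, 0.0)

    r_l = np.broadcast_to(np.asarray(config.llhcc_radius, float), (N,))
    r_h = np.broadcast_to(np.asarray(config.hlhcc_radius, float), (N,))
    a = coverage_from_distances(dist, r_l)
    b = coverage_from_distances(dist, r_h)

    demand = _rint(rng, config.demand_range, (I, N, T))
    F = _rint(rng, config.hlhcc_fixed_range, I)
    f = _rint(rng, config.llhcc_fixed_range, I)

    caps, G = [], []
    for n in range(N):
        step = int(rng.integers(*config.capacity_step_range))
        caps.append(np.array([step * (m + 1) for m in range(config.n_levels)], float))
        base = _rint(rng, config.capacity_cost_range, I)
        slope = _rint(rng, config.capacity_cost_range, I)
        g = base[:, None] + slope[:, None] * np.arange(1, config.n_levels + 1)
        G.append(g.astype(float))

    C = _rint(rng, config.link_cost_range, (I, I))
    np.fill_diagonal(C, 0.0)
    # unit costs grow mildly with distance (rounded to keep integers)
    dist_fee = np.round(0.05 * dist)
    c_prime = _rint(rng, config.transfer_cost_range, (I, I, N)) + dist_fee[:, :, None]
    q = _rint(rng, config.service_cost_range, (I, I, N)) + dist_fee[:, :, None]
    q_prime = q + 2.0 + _rint(rng, (0, 2), (I, I, N))   # HLHCC care costs a bit more
    c_dprime = _rint(rng, config.transfer_cost_range, (I, I, N)) + dist_fee[:, :, None]
    P = _rint(rng, config.shortage_penalty_range, (I, N))
    A = (rng.uniform(size=N) < config.p_exclusive).astype(float)

    inst = Instance(
        n_nodes=I,
        n_services=N,
        n_periods=T,
        capacity_levels=tuple(caps),
        hlhcc_fixed_cost=F,
        llhcc_fixed_cost=f,
        capacity_level_cost=tuple(G),
        hlhcc_coverage=b.astype(float),
        llhcc_coverage=a.astype(float),
        demand=demand,
        link_fixed_cost=C,
        llhcc_transfer_unit_cost=c_prime,
        hlhcc_service_unit_cost=q_prime,
        llhcc_service_unit_cost=q,
        referral_unit_cost=c_dprime,
        shortage_penalty=P,
        hlhcc_exclusive=A,
        min_hlhcc_cover=config.min_hlhcc_cover,
        min_llhcc_cover=config.min_llhcc_cover,
        alpha_max=np.full(N, float(config.alpha_max)),
        big_m=config.big_m,
        meta={
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "points": pts.tolist(),
        },
    )
    return inst


# --- serialization ----------------------------------------------------------

def _instance_to_dict(inst: Instance) -> dict[str, Any]:
    d: dict[str, Any] = {
        "n_nodes": inst.n_nodes,
        "n_services": inst.n_services,
        "n_periods": inst.n_periods,
        "capacity_levels": [c.tolist() for c in inst.capacity_levels],
        "hlhcc_fixed_cost": inst.hlhcc_fixed_cost.tolist(),
        "llhcc_fixed_cost": inst.llhcc_fixed_cost.tolist(),
        # G serialized in [k][n][m] order per the schema
        "capacity_level_cost": [
            [inst.capacity_level_cost[n][k].tolist() for n in range(inst.n_services)]
            for k in range(inst.n_nodes)
        ],
        "hlhcc_coverage": inst.hlhcc_coverage.astype(int).tolist(),
        "llhcc_coverage": inst.llhcc_coverage.astype(int).tolist(),
        "demand": inst.demand.tolist(),
        "link_fixed_cost": inst.link_fixed_cost.tolist(),
        "llhcc_transfer_unit_cost": inst.llhcc_transfer_unit_cost.tolist(),
        "hlhcc_service_unit_cost": inst.hlhcc_service_unit_cost.tolist(),
        "llhcc_service_unit_cost": inst.llhcc_service_unit_cost.tolist(),
        "referral_unit_cost": inst.referral_unit_cost.tolist(),
        "shortage_penalty": inst.shortage_penalty.tolist(),
        "hlhcc_exclusive": inst.hlhcc_exclusive.astype(int).tolist(),
        "min_hlhcc_cover": inst.min_hlhcc_cover,
        "min_llhcc_cover": inst.min_llhcc_cover,
        "alpha_max": inst.alpha_max.tolist(),
        "big_m": inst.big_m,
        "meta": inst.meta,
    }
    return d


def write_instance(inst: Instance, path) -> None:
    """Write an instance as JSON (documented schema; see README)."""
    with open(path, "w") as fh:
        json.dump(_instance_to_dict(inst), fh, indent=1)


def instance_from_dict(d: dict[str, Any]) -> Instance:
    for key in _REQUIRED_FIELDS:
        if key not in d:
            raise SchemaError(f"missing required field '{key}'")
    I, N, T = int(d["n_nodes"]), int(d["n_services"]), int(d["n_periods"])
    caps = tuple(np.asarray(c, float) for c in d["capacity_levels"])
    G_knm = d["capacity_level_cost"]
    if len(G_knm) != I:
        raise SchemaError("field 'capacity_level_cost': one row per node required")
    G = tuple(
        np.asarray([G_knm[k][n] for k in range(I)], float) for n in range(N)
    )
    return Instance(
        n_nodes=I,
        n_services=N,
        n_periods=T,
        capacity_levels=caps,
        hlhcc_fixed_cost=_as_array(d["hlhcc_fixed_cost"], (I,), "hlhcc_fixed_cost"),
        llhcc_fixed_cost=_as_array(d["llhcc_fixed_cost"], (I,), "llhcc_fixed_cost"),
        capacity_level_cost=G,
        hlhcc_coverage=_as_array(d["hlhcc_coverage"], (I, I, N), "hlhcc_coverage", binary=True),
        llhcc_coverage=_as_array(d["llhcc_coverage"], (I, I, N), "llhcc_coverage", binary=True),
        demand=_as_array(d["demand"], (I, N, T), "demand"),
        link_fixed_cost=_as_array(d["link_fixed_cost"], (I, I), "link_fixed_cost"),
        llhcc_transfer_unit_cost=_as_array(
            d["llhcc_transfer_unit_cost"], (I, I, N), "llhcc_transfer_unit_cost"),
        hlhcc_service_unit_cost=_as_array(
            d["hlhcc_service_unit_cost"], (I, I, N), "hlhcc_service_unit_cost"),
        llhcc_service_unit_cost=_as_array(
            d["llhcc_service_unit_cost"], (I, I, N), "llhcc_service_unit_cost"),
        referral_unit_cost=_as_array(
            d["referral_unit_cost"], (I, I, N), "referral_unit_cost"),
        shortage_penalty=_as_array(d["shortage_penalty"], (I, N), "shortage_penalty"),
        hlhcc_exclusive=_as_array(d["hlhcc_exclusive"], (N,), "hlhcc_exclusive", binary=True),
        min_hlhcc_cover=int(d["min_hlhcc_cover"]),
        min_llhcc_cover=int(d["min_llhcc_cover"]),
        alpha_max=_as_array(d["alpha_max"], (N,), "alpha_max"),
        big_m=d["big_m"] if isinstance(d["big_m"], str) else float(d["big_m"]),
        meta=d.get("meta", {}),
    )


def read_instance(path) -> Instance:
    """Read an instance from its JSON file; errors name the offending field."""
    with open(path) as fh:
        d = json.load(fh)
    if not isinstance(d, dict):
        raise SchemaError("instance file must contain a JSON object")
    return instance_from_dict(d)


def instance_checksum(inst: Instance) -> str:
    """Stable content hash of the serialized instance (for manifests)."""
    blob = json.dumps(_instance_to_dict(inst), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def instance_to_long_csv(inst: Instance, path) -> None:
    """Flattened long-format CSV export, for human inspection only."""
    rows = []
    I, N, T = inst.n_nodes, inst.n_services, inst.n_periods
    for i in range(I):
        for n in range(N):
            for t in range(T):
                rows.append(("demand", i, -1, n, t, inst.demand[i, n, t]))
    for x in range(I):
        for k in range(I):
            for n in range(N):
                rows.append(("hlhcc_coverage", x, k, n, -1, inst.hlhcc_coverage[x, k, n]))
                rows.append(("llhcc_coverage", x, k, n, -1, inst.llhcc_coverage[x, k, n]))
    df = pd.DataFrame(rows, columns=["tensor", "i", "j", "n", "t", "value"])
    df.to_csv(path, index=False)
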