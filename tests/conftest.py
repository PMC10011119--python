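import numpy as np
import pytest

from careloc import GeometryConfig, Instance, generate_instance


def make_instance(
    n_nodes,
    n_services=1,
    n_periods=1,
    hlhcc_fixed=100.0,
    llhcc_fixed=30.0,
    capacity_menu=((10.0,),),
    capacity_cost=50.0,
    demand=20.0,
    full_coverage=True,
    link_cost=5.0,
    transfer_cost=2.0,
    hlhcc_unit=3.0,
    llhcc_unit=1.0,
    referral_cost=1.0,
    penalty=100.0,
    H=1,
    V=1,
    alpha_max=1.0,
    exclusive=0,
    **overrides,
):
    """Hand-buildable dense instance with scalar-or-array parameters."""
    I, N, T = n_nodes, n_services, n_periods
    cov = np.ones((I, I, N)) if full_coverage else np.eye(I)[:, :, None] * np.ones(N)
    fields = dict(
        n_nodes=I, n_services=N, n_periods=T,
        capacity_levels=tuple(np.asarray(capacity_menu[n % len(capacity_menu)], float)
                              for n in range(N)),
        hlhcc_fixed_cost=np.broadcast_to(np.asarray(hlhcc_fixed, float), (I,)).copy(),
        llhcc_fixed_cost=np.broadcast_to(np.asarray(llhcc_fixed, float), (I,)).copy(),
        capacity_level_cost=tuple(
            np.broadcast_to(np.asarray(capacity_cost, float),
                            (I, len(capacity_menu[n % len(capacity_menu)]))).copy()
            for n in range(N)),
        hlhcc_coverage=cov.copy(),
        llhcc_coverage=cov.copy(),
        demand=np.broadcast_to(np.asarray(demand, float), (I, N, T)).copy(),
        link_fixed_cost=np.full((I, I), float(link_cost)),
        llhcc_transfer_unit_cost=np.full((I, I, N), float(transfer_cost)),
        hlhcc_service_unit_cost=np.broadcast_to(
            np.asarray(hlhcc_unit, float), (I, I, N)).copy(),
        llhcc_service_unit_cost=np.full((I, I, N), float(llhcc_unit)),
        referral_unit_cost=np.full((I, I, N), float(referral_cost)),
        shortage_penalty=np.broadcast_to(np.asarray(penalty, float), (I, N)).copy(),
        hlhcc_exclusive=np.broadcast_to(np.asarray(exclusive, float), (N,)).copy(),
        min_hlhcc_cover=H,
        min_llhcc_cover=V,
        alpha_max=np.broadcast_to(np.asarray(alpha_max, float), (N,)).copy(),
        big_m="auto",
    )
    fields.update(overrides)
    return Instance(**fields)


@pytest.fixture
def tiny_instance():
    """4-node generated instance, both stages exactly solvable in a blink."""
    return generate_instance(
        GeometryConfig(n_nodes=4, seed=7, n_services=2, n_periods=2))


@pytest.fixture
def equity_example():
    """2 nodes, one HLHCC, capacity 14 vs demand 2x10, skewed penalties.

    With the equity cap at 0.4 the unique optimum is shortage (1, 5):
    ratios {0.1, 0.5}, gap exactly 0.4, cost 100*1 + 1*5 = 105.
    """
    return make_instance(
        n_nodes=2, capacity_menu=((14.0,),), demand=10.0,
        hlhcc_unit=0.0, penalty=np.array([[100.0], [1.0]]),
        H=1, V=0, alpha_max=0.4,
    )
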