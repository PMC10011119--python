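# careloc

Two-stage capacitated hierarchical healthcare facility location-allocation:
exact mixed-integer programming solvers, a hybrid GA-SQP metaheuristic, a
seeded synthetic-instance generator, an independent constraint validator
and brute-force oracles.

## The problem

Health planners must decide where to open two tiers of facilities over a
set of population centers — higher-level healthcare centers (**HLHCCs**,
which hold all installable service capacity) and lower-level healthcare
centers (**LLHCCs**, which dispense services close to home) — and then,
period by period, how to allocate capacitated services to demand. Every
node is simultaneously a demand point and a candidate site for either tier.
Coverage is binary: facility *k* may serve node *i* for service *n* only if
*i* lies inside *k*'s per-service coverage radius (tensors `b` for HLHCCs,
`a` for LLHCCs).

**Stage 1 (strategic).** Choose HLHCC sites `X_kk`, LLHCC sites `y_j`, an
assignment `X_jk` of each open LLHCC to a covering open HLHCC, and one
capacity level `z_knm` per (HLHCC, service), minimizing fixed opening plus
installation cost, subject to: a node hosts at most one facility; every
node is covered by at least **H** open HLHCCs and **V** open LLHCCs for
every service (the access-equity floor).

**Stage 2 (operational).** Per period, HLHCCs serve covered demand
directly (`u`), push referral capacity to their assigned LLHCCs (`w`),
LLHCCs serve covered demand (`e`) and move units over opened transfer
links (`x`, `h`). Unmet demand is shortage `B`, penalized per unit.
LLHCCs hold no intrinsic capacity: everything they dispense arrives by
referral or transfer. Per service and period, the *equity gap*

    alpha_nt = max_i B_int / D_int  -  min_i B_int / D_int

(the spread of node-level shortage-to-demand ratios) is capped by
`alpha_max`. The max/min is linearized exactly with binary extremal-node
selectors and big-M product variables, so both stages are mixed-integer
*linear* programs, solved to proven optimality with HiGHS (an in-repo
branch-and-bound backend is available for cross-checks).

**GA-SQP.** For instances beyond exact reach, a real-coded genetic
algorithm with random-key encoding (roulette selection, continuous
uniform-mask crossover, gated Gaussian mutation, elitism, penalty-based
constraint handling) searches stage-1 designs; for stage 2 the GA searches
transfer-link patterns, each decode completed by an exact residual solve,
with the population seeded from an SLSQP solve of the continuous
relaxation (whose value is also a certified lower bound).

## Worked example

```python
from careloc import (GeometryConfig, generate_instance, solve_stage1,
                     solve_stage2, total_cost, validate)

inst = generate_instance(GeometryConfig(n_nodes=4, seed=7,
                                        n_services=2, n_periods=2))
s1 = solve_stage1(inst)
s2 = solve_stage2(inst, s1)
print(s1.status, s1.objective)     # optimal 2033.0
print(s2.status, s2.objective)     # optimal 18472.0
print(total_cost(s1, s2))          # (2033.0, 18472.0, 20505.0)
print(validate(inst, s1, s2).feasible)  # True
```

The location stage opens the cheapest facility pattern meeting the H = V = 1
coverage floors for 2033 money units; the allocation stage then costs
18472, dominated by shortage penalties where installed capacity runs out.
The validator recomputes every constraint family and both objectives by
independent arithmetic — including the equity cap in its original
nonlinear max-min form.

The same pipeline is scriptable from the shell:

```
careloc generate --config config.json --out inst.json
careloc solve inst.json --method exact --stage both --out-dir run/
careloc solve inst.json --method ga-sqp --seed 3 --out-dir run-ga/
careloc benchmark --config bench.json --out bench.csv
careloc sensitivity inst.json --parameter H --grid 0,1,2 --out sens.csv
careloc validate inst.json --stage1 run/stage1_solution.json
```

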