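# Methods

## Model

The network lives on `I` nodes that are simultaneously demand points and
candidate sites for both facility tiers. Services form a nested hierarchy:
every service an LLHCC offers is also offered at HLHCCs, and some services
(`hlhcc_exclusive`, e.g. emergency care) may never be referred down.

### Stage 1 — location (MILP)

Minimize fixed opening costs `F_k X_kk + f_j y_j` plus capacity
installation `G_knm z_knm`, subject to:

- assignment only to open HLHCCs (`X_jk <= X_kk`) and within coverage;
- each open LLHCC assigned to exactly one HLHCC other than itself;
- exactly one capacity level per (open HLHCC, service);
- at most one facility per node (`X_ii + y_i <= 1`);
- coverage floors: every (node, service) covered by >= H open HLHCCs and
  >= V open LLHCCs.

The assignment-within-coverage constraint is printed in big-M product form
in the source formulation; the default build uses the tight equivalent
`X_jk <= sum_n b_jkn` (same integer feasible set, better LP relaxation),
with the literal big-M form available via `eq6_mode="literal"`.

Because capacity never enters the stage-1 objective beyond its cost, and
level costs are strictly increasing, a cost-minimal design always installs
the cheapest level. Capacity sized for stage 2 is deliberately *not*
anticipated — the two stages are solved sequentially, which is the point
of the strategic/operational split. The total covered demand attained by
the cost-minimal design is reported as a diagnostic (`covered_demand`),
never optimized.

### Stage 2 — allocation (MILP)

Given the located network, per period: direct HLHCC service `u`, referral
`w` (HLHCC to its assigned LLHCCs, within coverage, blocked for exclusive
services), LLHCC service `e`, directed per-period transfer links `x` with
fixed cost per open period and transfer flows `h`, and shortage `B` with
per-unit penalty. LLHCCs hold no intrinsic capacity; a flow-balance row at
each (LLHCC, service, period) forces everything dispensed or forwarded to
be covered by referral/transfer inflow. The balance is an inequality
(inflow >= outflow) as printed; with positive flow costs optima never
over-ship, so it behaves like an equality economically.

**Equity.** `alpha_nt = max_i B/D − min_i B/D` is capped by
`alpha_max[n]`. The max/min is linearized with binary selectors
(`beta'`, `gamma'`, exactly one per (service, period)) and product
variables (`beta'' = beta' * B`, `gamma''`) via big-M rows; side
constraints `beta >= B/D` and `gamma <= B/D` for every demand-positive
node force the selectors onto the extremal nodes, so the linearization is
exact. Nodes with zero demand in a period are excluded from the selector
sets (their ratio is undefined); a (service, period) with no
demand-positive node carries no equity rows. After every optimal solve the
extremal ratios are re-verified against a direct nonlinear recomputation
from `B` and `D` (tolerance 1e-5); the independent validator repeats this
check without ever consulting the selector variables.

The min-side product rows appear in the source formulation with the
plus/minus constants swapped, which makes them jointly infeasible whenever
a selector is off and M > 0. The default build uses the corrected
symmetric mirror of the max side; `equity_sign_mode="printed"` reproduces
the defective variant, and the test suite demonstrates its infeasibility
on a 2-node witness.

**Shortage bound and padding.** `B` is given the variable bound
`B <= D`: its defining constraint is a lower bound only, so without an
upper bound no finite big-M in the product rows would be valid. The bound
is always admissible (the floor `D − served` never exceeds `D`) and never
cuts an optimum. A consequence worth knowing: because reported shortage
may exceed its floor, a solution can *pad* a node's `B` upward to equalize
ratios, so a tight equity cap produces padding cost, never infeasibility —
setting `B = D` everywhere always satisfies any cap. The infeasibility
certificate path for the cap is implemented but unreachable on real
instances.

**Big-M choices** (when `big_m="auto"`, the default): flow variables are
bounded by the per-service total demand; the transfer-link gate uses the
sum of those bounds; the equity product rows use the per-service peak
demand (valid because `B <= D`). A literal single global constant is
available by setting `big_m` to a number; it degrades the LP relaxation
and is kept only for faithfulness experiments.

Stage-2 flow variables are continuous by default (fractional patients are
accepted as rates); `integer_flows=True` switches them to integers.

## Solvers

Both stages build a sparse model once and hand it to a backend:

- `highs` (default): scipy's bundled HiGHS branch-and-cut
  (`scipy.optimize.milp`), proven optimality.
- `bnb`: an in-repo best-bound branch-and-bound over
  `scipy.optimize.linprog` relaxations — a deliberately independent second
  route used to cross-check backend-invariance of results on small models.

Models can be exported in LP text format for inspection.

## GA-SQP metaheuristic

**Encoding.** Real random keys in `[0, 1]^L`, the only scheme compatible
with the continuous convex-combination crossover. Stage-1 layout:
I HLHCC keys, I LLHCC keys (threshold 0.5 opens; co-location conflicts
resolved toward the larger key, HLHCC on ties), I assignment keys
(quantized pick among covering open HLHCCs; an LLHCC with no covering
HLHCC is closed), N capacity keys (quantized level per service).
Assignment, co-location and level-count rules hold by construction;
coverage floors are penalized at `weight x missing coverage units` with
`weight = 10 x` an upper bound on the unpenalized objective, so any
feasible decode dominates any infeasible one.

**Operators.** Roulette selection on reverse-rank desirability (worst = 1,
best = population size) — rank weights avoid the scale-sensitivity of
1/cost on a minimization problem. Crossover: per-gene uniform mask,
`child1 = p1*m + p2*(1−m)`, `child2` mirrored; children conserve the
parents' componentwise sum exactly. Mutation: per-gene uniform gate at
rate `Pm`, additive `N(0, sigma)` noise, clipped to `[0, 1]`. Elitism
copies the best E unchanged, making the best-fitness trace monotone. One
`numpy` generator seeded once drives all randomness; reruns are
bit-identical.

**Stage 2.** The chromosome's link keys decode to a transfer-link pattern
(threshold 0.5, restricted to ordered pairs of open LLHCCs); allocation
keys are retained for layout stability but are inert because each decode
is completed exactly: a residual LP without the equity cap first, and only
when the achieved nonlinear gap violates the cap a small MILP over the
selector binaries. Every decode is therefore flow-feasible, and completed
decodes are fully feasible; patterns whose cap cannot be met carry a
penalty proportional to the violation. Completions are cached by link
pattern. The SQP warm start solves the continuous relaxation (all binaries
in `[0, 1]`) with SLSQP from a fixed interior point — termination status 8
(degenerate boundary) is accepted when the iterate is feasible to 1e-5 —
and seeds the initial population; the reported relaxation value is
certified by an LP solve of the same relaxation, so it is always a valid
lower bound on the allocation optimum. A practical consequence of the
exact completion: the discrete search space is small enough that warm and
cold starts usually both find the optimum already in the initial
population, so the warm start's measurable benefit is a never-worse
guarantee rather than faster convergence.

**Defaults** (population 100, 150 generations, Pc = 0.9, Pm = 0.2,
sigma = 0.3, 2 elites) were chosen with the package's own factorial sweep
harness (`parameter_sweep`) on 8-node batteries, where the tuned stage-1
GA reproduces the exact optimum on 20/20 seeded instances. Stage-2 runs
use a smaller budget (population 30, 30 generations) because the
link-pattern space is far smaller than the stage-1 design space.

## Synthetic instances

The generator emulates a regional planning problem: nodes uniform in a
square (side 100 distance units), binary coverage by thresholding
Euclidean distance against per-tier, per-service radii (closed balls —
a node exactly on the radius is covered; HLHCC radius >= LLHCC radius,
default 120 vs 80, generous enough that small instances are usually
H = V = 1 feasible). Demand is integer-uniform in [5, 50]
patients/period — strictly positive so equity ratios are always defined.
Costs are integers (fixed costs ~10^3, unit costs ~10^0 with a mild
distance surcharge, shortage penalties 50–150 per unit, dominating unit
service costs); capacity menus are strictly increasing in both size and
cost, with per-level steps of 40–120 units so installed capacity is
scarce relative to demand and shortage/equity are active. `alpha_max`
defaults to 1.0 (vacuous); batteries exercising the cap set 0.25–0.5.
Instances whose candidate pools cannot meet the floors are flagged
(`coverage_warning`) rather than rejected.

Not emulated: road-network travel times, population-weighted or stochastic
demand, congestion, patient choice. Passing tests therefore show model and
solver correctness under the stated generative assumptions, not predictive
validity on real geographies.

## Oracles and validation

- `enumerate_stage1` (<= 6 nodes): all 3^I node-role patterns, coverage
  floors checked directly, assignment existence verified, cheapest-level
  pricing.
- `enumerate_stage2` (<= 4 nodes, <= 2 periods, <= 12 link variables): all
  binary link patterns; given links (and flows bounded by per-service total
  demand) the residual decomposes by (service, period), each block solved
  as a tiny LP, with (argmax, argmin) selector-pair enumeration when the
  uncapped optimum violates the cap. Shares no code with the MILP path and
  checks equity nonlinearly.
- `validate`: every constraint family re-checked by direct arithmetic on
  dense tensors at absolute tolerance 1e-6, binaries exact; objectives
  recomputed by direct summation; equity checked in max-min form.

## Numerical choices and degenerate inputs

Tolerances: 1e-6 absolute in the validator, 1e-5 relative for
stage-2-vs-oracle agreement (LP degeneracy), integrality rounding at 1e-6.
Ties among equal-cost optima are left to the backend; tests compare
objectives, never variable values, unless uniqueness is forced. Zero
demand anywhere is legal at solve time (excluded from equity); the
generator never produces it. Empty stage-2 models (no demand, nothing
open) return objective 0.

## Problem sizes

Test batteries use 4–8 nodes, 2 services, 1–2 periods, 2 capacity levels —
sizes at which the enumeration oracles are exact and both stages solve in
milliseconds, so every acceptance battery reruns from scratch. The exact
solvers themselves handle tens of nodes; the GA-SQP path is the intended
route beyond that.

## Known limitations

- The two stages are optimized sequentially; no feedback from allocation
  cost to location (by design, but a global planner could do better).
- Stage-1 capacity choice is cost-myopic (see above).
- The equity cap controls the *reported* shortage spread and can be met by
  padding; interpreting `B` as true unmet demand requires positive
  penalties and a slack cap.
- The `bnb` backend is for tiny cross-check models only.
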