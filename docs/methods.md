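# Methods

## Model

### Gravity 2SFCA with a chronic-disease focus

The accessibility of residential division *k* to a set of hospitals is a
supply-per-demand score.  In catchment form, each hospital *j* first gets a
physician-to-population ratio `R_j = S_j / Σ_{d_jk ≤ d0} M_k` over the
divisions within a travel-cost threshold `d0`, and each division then sums
the ratios of its reachable hospitals.  Replacing the hard threshold with a
smooth distance-decay weight `f(d) = d^(−β)` yields the gravity form used
throughout:

    a_k = Σ_j S_j f(d_jk) / Σ_l M_l f(d_jl)

Demand `M` is the chronic-disease population by default (`demand_stratum`
also accepts `total` and `elderly`): the model scopes offline first-line
care to community hospitals, which in the Chinese system are chartered for
chronic-disease management.  Medical resources are measured in physician
consultation-time units per day; any consistent unit works since the model
is homogeneous of degree one in supply.

Key exact properties (all unit-tested):

* **Conservation.** Σ_k M_k a_k = Σ_j S_j whenever every hospital has
  positive weighted demand.  This holds for any β and any geometry without
  a threshold, and is the backbone sanity check of the implementation.
* **Uniform limit.** β = 0 gives every division the same ratio ΣS / ΣM.
* **Threshold consistency.** With β = 0 and d0 = ∞ the catchment form and
  the gravity form coincide.

### Referral and tele-health

Chronic patients are treated first at community hospitals; a referral rate
`r` (fraction making an additional tertiary-A visit) mixes the two tiers:
`a_k = (1 − r) a_k^c + r a_k^a`.  No published value of `r` exists for the
modeled setting; the default is 0.2, i.e. one in five community consultations
leads to a tertiary follow-up, a mid-range figure for urban hierarchical
referral, and every entry point accepts an explicit value.

Online visits are distance-free and are provided only by tertiary-A
hospitals, each of which may dedicate at most a fraction `ρ_i` (default
0.4) of its resource `T_i` to them.  With pooled online resource ΣV and
online-preference fractions `Q_k`, two variants of the online component are
implemented behind `online_mode`:

* `as_printed` — `a_k^v = ΣV · Q_k / Σ_l Q_l M_l`.  Because the overall
  combination multiplies the online term by `Q_k` again, the online
  contribution to division *k* carries a net factor `Q_k²`.
* `conserving` — `a_k^v = ΣV / Σ_l Q_l M_l`, so that the demand-weighted
  online accessibility recovers the allocated resource exactly:
  Σ_k M_k Q_k a_k^v = ΣV, the online analogue of offline conservation.

`as_printed` is the package default.  The reference tele-health scenario
(below) uses `conserving`: under the `as_printed` reading, shifting
resource online strictly destroys weighted accessibility (the net `Q_k²`
factor), the optimized mean *falls* and tight equity bounds become
infeasible on realistic instances — the opposite of the behaviour the
model is meant to capture.  The conserving reading is the one under which
"moving physician time online" is resource-neutral.

The combined index is

    a_k = (1 − Q_k) [ (1 − r) a_k^c + r a_k^a ] + Q_k a_k^v

with the grouping chosen so that a fraction `Q_k` of demand shifts online
and the remainder follows the offline referral path; at Q = 0 it reduces
exactly to the referral index and at Q = 1 to the online component.

`Q_k` is assigned in two tiers from the purely offline baseline: divisions
strictly below the regional mean get `q_poor` (default 0.35), the rest —
ties included, a deterministic tie-break — get `q_good` (default 0.1).
Willing-to-go-online fractions of roughly a third in underserved areas and
a tenth in well-served areas sit inside the range survey studies report.

### Offline resource accounting

`offline_mode` controls what online allocation does to offline supply:

* `resource_shift` (default) — tertiary offline supply becomes `T_i − V_i`:
  total system resource is conserved exactly, and well-served central
  divisions lose some offline access when capacity moves online.
* `as_printed` — `T_i` is left untouched, treating online capacity as
  additional.

### Equity statistics

For a profile `a`: the gap `a_max − a_min`; the equilibrium index
`(a_max − a_min)/(a_max + a_min)`, a scale-invariant spread in [0, 1]
(0 for an all-zero profile by convention); and a population-weighted Gini
coefficient (weighted by default because division demand spans two orders
of magnitude, so an unweighted Gini over-represents tiny divisions).  The
Gini uses the O(n log n) sorted form and is verified in tests against the
O(n²) pairwise double sum.

### Allocation program

Decision variables are the per-site online allocations `V_i` (continuous
by default; integral in `integer` mode for headcount semantics, solved as
a MIP with 0.01 relative gap).  Every `a_k` is affine in V — the online
pool enters linearly and, in `resource_shift` mode, each unit of `V_i`
subtracts `f(d_ik)/Σ_l M_l f(d_il)` from the tertiary component — so the
program

    maximize   (1/P) Σ_k a_k(V)
    subject to 0 ≤ V_i ≤ ρ_i T_i
               a_min ≤ a_k(V) ≤ a_max        for all k
               (1 − G) a_max ≤ (1 + G) a_min

is an LP.  `a_min`/`a_max` are auxiliary decision variables by default
(`variable_extremes`): the sandwich constraints pin them around the
realized extremes, so the last row — the exact linearization of the
equilibrium-index ratio bound, valid whenever a_max + a_min > 0 — caps the
realized spread at G.  A `fixed_bounds` mode instead imposes user-chosen
constants when a desired accessibility corridor is known a priori.

Solution path: HiGHS through `scipy.optimize.linprog`/`milp` with a 1e-6
feasibility tolerance.  The returned profile is always recomputed through
the accessibility equations from the optimal V rather than read off the
solver, guarding against drift between the algebraic model and the engine.
When no division has online demand the objective is flat in V and the
solution is canonicalized to V = 0.  On infeasibility, the minimal
feasible G is located by bisection and reported as a diagnostic.

The brute-force oracle enumerates V on a regular grid over the cap box
(guarded to ≤ 4 sites and ≤ 50 steps), re-deriving the evaluation directly
from the decay weights, independent of the LP assembly.  Because the LP
optimum sits at a polytope vertex, the oracle matches it to within the
grid's resolution bound — (objective gradient)·(spacing) — which the
cross-check instances keep below 1% of the objective.

## Synthetic districts

`generate_city` emulates a central metropolitan district:

* **Divisions** — `n_divisions` (13), of which `n_towns` (2) are remote
  towns on an outer ring at 0.55–0.65 of the extent from the center; the
  urban rest sit on a jittered grid over the central 85% of the extent,
  with an odd column count so one division anchors the center.
* **Supply** — `n_tertiary` (6) tertiary-A hospitals Gaussian around the
  center with spread `max(0.5·(1−centralization), 0.05)·extent`;
  `n_community` (56) community hospitals with a milder center bias
  (`community_centralization` = 0.5).  Mean community resource 220
  units/day; tertiary resource `tier_ratio` = 45× that, reflecting the
  actual asymmetry between a tertiary-A hospital (thousands of staff) and
  a community health centre (tens); both lognormally dispersed.
* **Demand** — chronic populations log-uniform over `pop_range`
  (10²–10⁴), reproducing a two-orders-of-magnitude spread across
  divisions; elderly and total populations derived with noisy realistic
  ratios (elderly share of residents drawn in 18–30%).
* **Costs** — haversine km between synthesized lon/lat coordinates.

Everything derives from `numpy.random.default_rng(seed)`; identical seeds
give field-for-field identical instances and byte-identical CSV exports.

The `lubei_like` fixture draws candidates from a deterministic seed
sequence and keeps the first whose *baseline* (offline, Q = 0) profile
shows gap ≥ 3× the mean and equilibrium index ≥ 0.7 with the G = 0.7
equity bound attainable through reallocation — the strongly unequal regime
in which an equity-bounded tele-health allocation is the interesting
problem.  About two in three candidates qualify, so the search is short;
selection looks only at the baseline regime, never at the optimization
outcomes.  These geometry and magnitude constants were calibrated once
against a 300-seed Monte-Carlo run and then frozen.

What the generator does **not** emulate: road networks (straight-line
distance proxies travel cost), intra-division heterogeneity (demand sits
at division centroids), insurance/economic access barriers, waiting times,
and correlated demand-supply co-location.  Tests passing on these
instances therefore validate the model mechanics and the optimizer —
conservation, equity-bound satisfaction, monotonicity, oracle agreement —
not the empirical accessibility of any real district.

## Numerical choices

* Distances are floored at `d_floor` (default 0.1, in the cost unit)
  before applying `d^(−β)`, bounding the decay weight at co-location.
* The hard threshold `d0` is off by default (pure gravity decay); when
  set, weights vanish strictly beyond it.
* Hospitals whose weighted demand is zero (empty catchment) contribute
  zero accessibility and emit a warning rather than aborting, so
  degenerate corners of parameter sweeps fail soft.
* Ties in the poor/good classification (a_k equal to the mean) classify
  good — a deterministic tie-break.
* Brute-force ties are broken by the lexicographically smallest V.
* All floats in CSV/JSON artefacts are serialized at 12 significant
  digits, making rerun outputs byte-identical.
* Problem sizes in the test-suite cross-checks: 200 random 8-division
  districts for conservation, 50 random ≤6-division/≤3-site instances at
  grid step 20 for oracle agreement — small enough to run in seconds,
  large enough that the grid resolution bound stays below the comparison
  tolerance.

## Known limitations

* The two online-term readings (`as_printed` vs `conserving`) differ by a
  factor `Q_k` in the online component; results under tight equity bounds
  are sensitive to this choice, which is why both are exposed and the
  conserving one is used wherever total-resource neutrality is asserted.
* The equilibrium index only sees the extremes; a profile can become more
  unequal in the middle without moving it.  The weighted Gini is reported
  alongside for that reason.
* With `resource_shift`, divisions with high *offline* tertiary access can
  lose accessibility; the optimizer is free to trade their surplus for the
  periphery's gain, which is the intended policy semantics but should be
  communicated when presenting per-division results.
* The LP treats consultation time as divisible; `integer` mode exists for
  headcount semantics but inherits the usual MIP tolerance (1% relative
  gap).
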