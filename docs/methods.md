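# Methods

## Problem and model

The package solves a p-median-style facility configuration problem for
residential elderly care. Inputs are population centers (planar coordinates
in meters, elderly counts, care demands *w_i*), candidate sites with bed
capacity bounds, and a strictly positive travel-distance matrix *d_ij*. A
configuration opens *p* sites, assigns beds *v_j*, and allocates every
center to its nearest open facility (ties to the lowest site index, for
determinism).

Accessibility follows the improved gravity formulation: facility *j*'s beds
are shared among centers in proportion to *w_i d_ij^(−β)*, and a center's
accessibility sums its shares over open facilities. Two exact algebraic
properties anchor the test suite: the demand-weighted mean of the field
equals total beds over total demand (*V/W*) identically, and the field is
homogeneous of degree one in beds and invariant under uniform distance
scaling.

Distances must be positive because *d^(−β)* diverges at zero; co-located
pairs are clamped to a configurable floor (`clamp_distances`, default 1 m).
The synthetic generator uses a larger floor (150 m, see below).

### Objectives and scalarization

Equity (minimize Σ(A_i − a)²), efficiency (maximize mean relative
accessibility change versus a baseline field; skipped with its weight
renormalized away when no baseline exists), travel cost (minimize
Σ w_i d_ij Z_ij) and profit (maximize mean monthly margin per open
facility; the margin defaults to 2050 − 1250 = 800 currency/bed/month).
Profit divides by the number of *open* facilities — dividing by the
candidate count would not reproduce the mean-per-facility unit the model
reports.

Min–max standardization maps each objective to "smaller is better" on
[0, 1]; degenerate ranges map to 0.5. Weighted sums use equal weights by
default (an optional range-adaptive mode reweights objectives inversely to
their observed spread). Constraint violations are measured per family
(facility count, coverage, linkage, capacity — including open sites with
zero beds) and enter a penalty multiplier r = 1 + mean((Δb/Δb_max)^η) with
η = 2, so any violation strictly worsens the score; the weighted sum is
floored at 10⁻⁶ so the affinity 1/F stays finite.

### The canonical scalarization frame

Min–max standardization is only defined relative to a population of
solutions, which makes "the best solution" frame-dependent. The package
therefore fixes one canonical frame per (instance, p): the standardization
bounds are computed over a deterministic reference population of p-subsets —
the full enumeration when C(J, p) ≤ 4096, otherwise a fixed pseudo-random
sample of 512 subsets whose seed depends only on J and p, never on the run
seed. Every algorithm scores, archives and reports in this frame, and the
enumeration oracle minimizes the same F, so "optimal" is a property of the
instance rather than of the search path. Out-of-reference values map
outside [0, 1]; the map stays monotone, which is all that ordering needs.

An earlier design standardized per generation (bounds from the current
antibody population). That made the incumbent's identity drift with the
frame: instrumentation showed the true best solution present in the
population in only ~20 % of generations and receiving ~0.7 % of clones, so
its neighborhood was never exploited and the algorithm missed enumerable
optima in a triple-digit number of evaluations per subset. The canonical
frame removed that failure mode entirely.

## The modified immune algorithm

Antibodies are ordered sets of *p* distinct site indices, completed
deterministically (nearest allocation, demand-sized beds) before scoring,
so count/coverage/linkage constraints hold by construction and only
capacity can be violated — exactly the violation the penalty must steer
away from. Scoring is vectorized over whole populations (an einsum over the
distance-decay kernel); a district-scale generation costs well under a
millisecond.

Per generation: affinity = 1/F in the canonical frame; concentration = the
fraction of the population whose encoding Jaccard similarity is ≥ 0.8; a
memory bank keeps the best unique antibodies and damps (×0.5) the selection
score of population members identical to a non-incumbent memory cell;
antibodies scoring above the σ(t) quantile of normalized-affinity ×
(1 − concentration) are cloned, clone counts proportional to score
(largest-remainder rounding, total = N). σ(t) is 0.3 until t_max/2, then a
quarter-sine ramp to 1. Each clone mutates through the Guo elite operator
with probability P_m(t) = 0.1·|cos(2πt/T)| + γ (elite pool = the best
distinct max(2, ⌈0.1 N⌉) antibodies; weights drawn uniformly in
[−0.5, 1.5] and renormalized; offspring rounded, clipped and
duplicate-repaired to the nearest unused index), or else undergoes a single
random index exchange with probability 0.05. Survivors are the best unique
encodings of parents ∪ clones (duplicates of a survivor have reduced
ability to survive — the diversity role of the memory bank; without
uniqueness the population collapses onto copies, and recombining identical
elites is a fixed point). The working copy of the global best is perturbed
every θ iterations by exp(−t/θ)·u²; the incumbent archive itself is never
touched, so the reported best-F trace is non-increasing. The returned
incumbent is the best solution ever *evaluated* (an archive of all distinct
evaluations re-ranked in the canonical frame), not merely the best
survivor.

Parameter defaults, with units and rationale: population N = 40 and
t_max = 200 iterations (district-scale runs converge in well under half
that); threshold coefficient a_sel = 0.3 (the standard early-stage value);
mutation amplitude ε = 0.1 (customary) with period T = 40 iterations and
floor γ = 0.1 — γ is specified only as 0 < γ ≤ ε, and setting it equal to ε
keeps the mutation stage from idling at the cosine zeros, which measurably
improves ergodicity on small landscapes; perturbation interval θ = 10;
memory capacity N/2; penalty exponent η = 2. All randomness flows from one
seed through named substreams (initialization, mutation, perturbation,
generator), so reordering draws in one component never shifts another's
sequence.

Baselines (GA with tournament selection, one-point crossover and duplicate
repair; global-best PSO on the relaxed real index vector with rounding
repair; standard IA with fixed threshold and exchange mutation only) share
the encoding, scorer, archive and canonical frame, so comparisons isolate
the search strategy. Convergence iteration = first iteration within 10⁻⁶
of the final best.

## Planning workflow

* **Assessment** uses β = 1.8 for existing configurations (the decay that
  matches observed travel behaviour for facilities people actually use) and
  β = 1.0 in optimization contexts (the minimum-dispersion value on the
  scanned grid 0.8–2.4 in steps of 0.2). The radius-restricted
  beds-per-100 indicator cuts both the supply term and the competition
  denominator at the service radius (consistent catchment semantics); the
  one-hour service radius is expressed as a distance, default 3000 m at the
  synthetic district's scale.
* **Step 1** flags a facility as mislocated when it is farther than a
  tolerance (default 500 m) from every site of a same-count optimized
  reference run *and* every center it serves has another existing facility
  at most that tolerance farther away (closing it strands nobody). Retained
  facilities are resized to min(assigned demand, cap) with overflow
  attributed to their most distant centers.
* **Step 2** solves the residual problem (centers with unmet demand, sites
  not already occupied) for each candidate facility count from
  ⌈unmet/cap⌉ upward, compares the per-count best configurations in one
  shared frame, and keeps the lowest-F count among those admitting a
  feasible (cap-respecting) configuration, extending the range if none
  does.
* **Step 3** sizes each new facility to its catchment demand. The final
  assembly then re-sizes *all* open facilities to their capacitated nearest
  catchments (closest-served-first): once new facilities open, retained
  catchments shrink, and keeping step-1 bed counts would leave beds
  mismatched with local demand — the same demand-oriented sizing rule,
  applied to the final layout. The final configuration always holds exactly
  W beds.
* **Evaluation** reports before/after equity, demand-weighted Gini (Lorenz
  trapezoid over per-capita accessibility), per-capita travel cost, mean
  profit, max/mean nearest-facility distance, mean radius-restricted
  beds-per-100, the share of centers with accessibility within ±10 % of the
  field mean, and the mean relative accessibility change. Changes are plain
  relative differences — (before−after)/before for minimized metrics,
  (after−before)/before for maximized ones; no other rate formula is used.

## Synthetic districts

The generator emulates a dense urban district at desk scale: 60 centers in
5 Gaussian clusters over a 6 km square, lognormal elderly counts (log-mean
7.2, log-sd 0.5, i.e. a median committee of ~1300 elderly), demand = 2.5 %
of elderly, 120 candidate sites (70 % tracking the clusters), 12 existing
facilities, 300-bed cap. Planted defects make the current configuration
deliberately imbalanced: 25 % of facilities sit in demand-empty corners,
the rest crowd the densest clusters (historical accretion), bed counts are
drawn independently of the demand each facility faces and scaled so total
supply is 80 % of demand. Distances are Euclidean with a 150 m intra-zonal
floor — door-to-door network distance between a zone centroid and a
facility is never a few meters, and without the floor the diverging gravity
kernel lets single co-located pairs dominate the equity sum — or shortest
paths on a thinned Delaunay road graph with per-edge rush-hour speeds
(3–8 m/s) and intersection dwell times (0–60 s) converted to distance.

What passing tests on these districts show — and what they do not: the
generator reproduces the *structure* of a real planning problem (clustered
demand, scarce and misallocated supply, network-like detours) but not real
geography, behavioral travel choices, or empirically calibrated β; results
on synthetic districts validate the machinery and its qualitative behavior,
not any particular city's numbers.

## Numerical choices and edge cases

Nearest-allocation ties break to the lowest site index; the β grid scan
uses the unweighted population standard deviation (ties to the smaller β);
standardization of an all-NaN objective column yields 0.5 with zero weight;
the Guo weight vector is redrawn when its sum is within 0.1 of zero; repair
replaces duplicate indices by the nearest unused site and always succeeds
for p ≤ J; the exhaustive oracle refuses enumerations beyond 200 000
subsets; Gini requires nonnegative values, positive weights and a nonzero
total. Problem sizes in the test and acceptance runs (15-center/12-site
oracle instances, 60-center districts, 10 seeds × 20 runs) were chosen so
the full suite and the acceptance script each complete in a few minutes on
one CPU while C(J, p) stays exhaustively checkable where the oracle is
asserted.

## Known limitations

The scalarized model returns one compromise solution, not a Pareto front.
The "unreasonable location" rule and the capacitated rebalance are one
consistent reading of a procedure whose published description is narrative.
Absolute published case-study values depend on unavailable geographic data
and are not reproduced; only the arithmetic relations among printed values
are. The adaptive-weighting mode is a simple range-inverse rule, offered
alongside (not instead of) equal weights. PSO's rounding repair makes its
search granular on small instances; its comparison numbers should be read
qualitatively.
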