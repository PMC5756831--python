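# Methods

This note documents the models and procedures implemented in `channelweb`,
the choices made where several designs were defensible, and what the test
suite does and does not establish.

## Flow networks and steady state

The universal input is a quantitative flow network: per node a category
(producer, consumer, decomposer, detritus), a carbon stock B (g C m⁻²), and
boundary flows (import, export, respiration, g C m⁻² day⁻¹), plus an S×S
matrix `F` of internal fluxes. A web is at steady state when every node's
inflow (imports + Σᵢ F[i,j]) equals its outflow (exports + respiration +
Σₖ F[j,k]). `validate_network` reports per-node residuals relative to
throughflow and flags self-loops, isolated nodes, and living nodes with
zero biomass. Self-loops (cannibalism) are accepted and participate in all
sums; no equation below excludes i = j.

Producers and detritus pools are *basal* by category, not by topology:
detritus pools receive recycled inflows yet act as energy origins, so
inferring basal status from in-degree would misclassify them.

## Balancing

Field data rarely balance exactly. `balance_flows` iterates an
input/output averaging scheme: each node's target throughflow is the mean
of its current total input and output; incoming flows (including imports)
and outgoing flows (including exports and respiration, rescaled as one
block) move toward the target, and an internal flux receives the average of
its source's output factor and its target's input factor. Defaults:
relative tolerance 1e-6, cap 10,000 iterations. The zero pattern of `F` is
preserved by construction; the trace of max residuals is monotone
non-increasing in practice and is exposed for auditing. A node with a
residual but structurally no inputs (or no outputs) cannot be repaired by
rescaling and raises an error naming the node. The scheme satisfies the
same contract as the input/output-averaging family used for ecosystem
network models; it does not claim to reproduce any particular legacy
implementation flux-for-flux.

## Basal reliance and seed subgroups

Diet proportions are `P[i,j] = F[i,j] / Σᵢ F[i,j]`, normalized over
*internal* prey only; imports are excluded from the denominator because the
basal set contains only in-web nodes (a `imports_as_source` flag adds a
pseudo-basal import column instead). The reliance of a consumer on each
basal node satisfies `row_i = Σⱼ P[j,i] row_j` with basal rows fixed at
unit self-vectors — basal nodes are absorbing, which cuts every loop
through detritus. Nodes with no directed path from the basal set are
detected first (depth-first reachability) and flagged with all-zero rows;
removing them guarantees the remaining linear system is nonsingular,
because every surviving consumer cycle then leaks toward the basal set.
The exact solve is cross-checked in tests against an independent
fixed-point iteration to 1e-13.

Each node seeds into the subgroup of its arg-max basal column; exact ties
go to the tied basal node with the lowest node-table index (the arg-max
margin is recorded for diagnosing near-ties). Unreachable nodes become
singleton subgroups so the merge phase can still absorb them.

## Weighted directed modularity and greedy merging

Modularity of a partition c is

    Q = (1/2W) Σᵢⱼ [ wᵢⱼ − wᵢᵒᵘᵗ wⱼⁱⁿ / 2W ] δ(cᵢ, cⱼ)

with w the internal flux matrix and 2W its total; boundary flows never
enter. Q of the one-compartment partition is exactly zero (the two terms
cancel analytically) and Q is invariant under uniform rescaling of all
fluxes — both are pinned by tests.

Detection starts from the seed subgroups and repeatedly merges the pair
with the largest ΔQ while that gain is positive. Gains are maintained
incrementally from per-compartment totals
(ΔQ(c,d) = e_cd + e_dc − a_cᵒᵘᵗ a_dⁱⁿ − a_dᵒᵘᵗ a_cⁱⁿ, O(k²) per sweep);
their equality with brute-force recomputation is a tested contract
(≤ 1e-10). Ties break on the lexicographically smallest label pair, making
the algorithm deterministic. Merging the best pair (rather than the first
positive one) is standard agglomerative practice; the merge trace makes the
path auditable. Nodes never move individually, so the final partition is a
coarsening of the seed subgroups. Greedy merging guarantees local
optimality (no single further merge improves Q) — verified exhaustively in
tests for up to 8 seed subgroups — not global optimality.

## Monte Carlo null model

Each null web redraws, for every column with positive intake, the same
number of prey uniformly without replacement from the S−1 other nodes
(basal nodes and detritus included; the matrix diagonal stays empty) and
splits the column's total intake proportionally to uniform(0,1) draws.
Column sums, per-column prey counts, and hence total flow 2W are preserved
exactly; row structure is free. The empirical partition is held fixed and
rescored on each null web; `p` is the fraction of null Q values at least as
large as the empirical Q. The comparison is non-strict (≥) with an absolute
tie tolerance of 1e-12 so that analytic ties — e.g. Q ≡ 0 under the
one-compartment partition — count as ties; the convention is recorded in
the result metadata, and the raw count is stored alongside the formatted
"<1/reps" text. Per-repetition RNG streams are spawned from one master seed
(`numpy` SeedSequence), so runs are reproducible and parallelizable.
The Bonferroni helper returns α/n for a family of n tests.

## Bioenergetic model

State: biomass B_i of every node. Categories map to equations:

* **Producers**: `dB/dt = r B (1 − Σ_pro B / K) − Σ Φ_ij B_j − d B − (x + ex) B`,
  logistic growth over summed producer biomass, losses to herbivory, death
  (routed to detritus), respiration and export.
* **Consumers/decomposers**: `dB/dt = a Σ Φ_ji B_i − Σ Φ_ij B_j − (x + ex) B`;
  only the assimilated fraction a of intake is gained, the egested
  fraction e = 1 − a flows to detritus.
* **Detritus**: inflows from producer death and consumer egestion, both
  routed by proportions p (rows sum to 1 over detritus pools), plus
  detritus-to-detritus conversion at rates c; outflows to detritivores and
  decomposers via Φ, outgoing conversion, respiration/export if the data
  record them.

The functional response is multi-prey with interference:

    Φ_ij = y_j ω_ij B_i^h / ( H_j^h (1 + q_j B_j) + Σ_k ω_kj B_k^h )

`h` interpolates Holling type II (h = 1, saturating) to type III (h = 2,
sigmoid at low density); both limits are asserted numerically in tests.

### Calibration (inverse, equilibrium-exact)

All parameters are derived so the observed balanced web is an exact
equilibrium:

| parameter | value | meaning |
|---|---|---|
| x_i | respiration_i / B_i | respiration rate |
| ex_i | exports_i / B_i | export rate |
| a_j | 1 − (flux to detritus)/(internal intake) | assimilation efficiency |
| ω_ij | ∝ F[i,j] / B_i^h, column-normalized | diet preference |
| H_j | Σ_prey B_i | half-saturation at observed prey density |
| y_j | solved so Φ_ij B_j = F[i,j] at B* | maximum consumption rate |
| d_i | (producer flux to detritus)/B_i | producer death rate |
| r_i | 2 × gross production / B_i, with K = 2 Σ B*_pro | logistic term = 1/2 at B* |
| p_ji | F[j, det_i] / Σ_det F[j, ·] | detrital routing |
| c_ji | F[j, det_i] / B_j (detritus j) | conversion rate |

Producer imports are interpreted as gross primary production and folded
into the logistic term by default (flag `producer_imports_as_production`);
other imports enter as constant forcing. Two boundary-flow choices deserve
emphasis because the alternatives fail:

* **Exports are a rate, not a constant drain.** With a fixed export term a
  consumer above equilibrium gains proportionally to B but loses a
  constant, so every consumer equilibrium is linearly repelling; runs drift
  by orders of magnitude within 2000 days. With `ex_i B_i` the equilibrium
  is neutral in that direction and prey feedback stabilizes it.
* **Defaults h = 1.2, q = 1.** `q` is expressed as the dimensionless
  interference level at the empirical state; the per-consumer coefficient
  is q_j = q / B*_j, so the interference term equals q·H_j^h at
  equilibrium. With q = 0 the saturating response leaves roughly one in six
  synthetic calibrated equilibria with a positive Jacobian eigenvalue
  (consumer–resource oscillations; measured max +0.011 day⁻¹ over 60 webs),
  whereas q = 1 gives a worst max eigenvalue of −0.07 day⁻¹ over the same
  ensemble. Both are config-exposed (`calibrate_parameters(h=…, q=…)`,
  `simulate --config`).

Calibration errors are raised (naming the node) when the data are
infeasible for the model: a flowing node with zero biomass, egestion not
below intake, or internal flux into a producer.

### Integration and removal protocol

Adaptive Runge–Kutta 4/5 (`scipy.integrate.solve_ivp`, RK45), rtol 1e-6,
atol 1e-9, with a biomass floor of 1e-10: below the floor a negative
derivative is clipped to zero (a clamp, not an extinction event). The
removal protocol integrates 1000 days of burn-in from the empirical
biomasses, averages each node over the next 1000 days (B⁺, sampled daily),
freezes the removed node at zero (its equation dropped), integrates another
1000 days and averages again (B⁻). Removal candidates are the living
(non-detritus) nodes, drawn uniformly without replacement; the burn-in run
is shared across removals of the same web. Burn-in and window lengths are
configurable; the shipped tests shorten them only where the quantity under
test does not depend on them.

## Removal effects

`RE_i = ln[(B_i⁺+1)/(B_i⁻+1)] / (B_k+1)` (natural log; the +1 terms keep
small B_k from inflating the statistic). The removed node is excluded from
both aggregates. Within/between means use |RE| by default so that positive
(release) and negative (loss) responses cannot cancel; a `signed` flag
averages raw values instead. A singleton compartment leaves the within mean
undefined (NaN, flagged via n_within = 0). The paired t test across webs is
computed from the textbook formula with a scipy p-value and is
cross-checked against `scipy.stats.ttest_rel`; zero-variance differences
yield t = 0 (p = 1) for identical samples and ±∞ otherwise.

## Benchmark algorithms

Girvan–Newman (edge betweenness, networkx) and walktrap (random walks,
igraph, walk length 4) run on the symmetrized graph (wᵢⱼ + wⱼᵢ; self-loops
dropped — they carry no path or walk information), with betweenness using
distance 1/weight. Both are classic undirected algorithms; directedness
enters only through the scoring: every dendrogram level (plus the no-cut
and connected-component baselines) is scored with the same weighted
directed modularity as the energy-channel method, and the best level is
returned. Disconnected inputs are partitioned per component with a warning.

## Synthetic planted-channel webs

The generator builds k channels of m nodes over L trophic levels: one basal
node per channel (detritus/producer alternating), consumers dealt
round-robin over levels 1..L−1, lognormal flux weights (σ = 0.5 by default,
emulating the strongly uneven link weights of empirical quantitative webs),
and a coupling fraction ε of every consumer's diet rerouted to lower-level
nodes of foreign channels. Intakes are generated from the top level down so
that each node's intake covers its consumers' demand at a trophic transfer
efficiency drawn in [0.2, 0.5]; the surplus splits between respiration and
export, and basal imports equal basal demand — webs are therefore balanced
to machine precision by construction, and biomasses follow throughflow with
a turnover time of ~3 days. Generation is deterministic per seed.

Default conditions used across tests and the acceptance script: k = 2–3
channels (5 for recovery checks), m = 6–8 nodes per channel, L = 3 levels,
ε = 0.05 for coupled-web studies, 20-web ensembles, 6 removals per web,
1000 Monte Carlo repetitions. These sizes sit at the small end of the
empirical range (S = 23–124) and keep the full suite fast.

What the generator does **not** emulate: recycling loops into detritus
(egestion returns to the channel's export budget, not its basal pool),
cannibalism, strong omnivory spanning many levels, import-fed mid-web
nodes, and empirical-scale webs. Passing tests therefore establish the
method's correctness and its behaviour under controlled channel coupling —
not how strongly any particular empirical web is compartmentalized. The
pipeline accepts real exports (see README) for that purpose.

## Known limitations

* The greedy merge is order-deterministic but only locally optimal; webs
  where two different merge sequences cross can end at different (equally
  defensible) local optima.
* The dynamics model requires every flowing living node to have positive
  biomass and cannot represent flux into producers; such data must be
  re-categorized or pre-processed.
* Stability of the calibrated equilibrium is a property of the chosen
  defaults (q = 1, exports as rates), not a theorem; extreme parameter
  choices (q = 0 with h near 1) reintroduce oscillations.
* The Monte Carlo p-value has binomial resolution 1/reps; comparisons
  should use bounds, not equality, and the raw exceedance count is stored.
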