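# channelweb

Energy-channel compartment detection for quantitative food webs, with a
Monte Carlo significance test and a flow-calibrated bioenergetic model for
node-removal experiments.

Food webs are often organized into *compartments*: subgroups of taxa with
many strong interactions inside the subgroup and few weak ones between
subgroups. Generic community-detection algorithms can find such subgroups,
but they say nothing about *why* they exist. `channelweb` detects
compartments from an explicitly ecological quantity — the **energy
channel**: the set of carbon fluxes originating at one basal resource
(a producer or a detritus pool) and flowing up to consumers. It is aimed at
ecologists working with quantitative (flux-weighted) food-web data such as
the ecosystem-network models distributed with the `enaR` R package.

## The method

Given an S×S carbon-flux matrix `F` (`F[i,j]` = flux from node *i* to node
*j*, g C m⁻² day⁻¹) of a web at steady state:

1. **Basal reliance.** For every node, the fraction of its carbon derived
   from each basal node is computed from the diet recursion
   `%BR_C = Σ P_C · %BR_R`, where `P_C` is the share of the consumer's
   internal diet supplied by each resource. Basal nodes are absorbing
   (recycling into detritus is not traversed); consumer cycles are resolved
   by an exact linear solve.
2. **Seed subgroups.** Each node joins the subgroup of its dominant
   (arg-max) basal source; each basal node seeds its own subgroup.
3. **Merge gains.** For every pair of current subgroups, the change
   ΔQ = Q_after − Q_before in weighted directed modularity

       Q = (1/2W) Σᵢⱼ [ wᵢⱼ − wᵢᵒᵘᵗ wⱼⁱⁿ / 2W ] δ(cᵢ, cⱼ)

   is computed (w = internal fluxes, 2W = total flow).
4. **Greedy merging.** The best pair is merged while ΔQ > 0; the result is
   the compartment partition, its Q, and an auditable merge trace.

Significance is assessed against a null model that redraws every predator's
prey set (uniformly from the other S−1 nodes) and re-splits its total
intake with uniform weights, preserving each column's sum and prey count;
`p` is the fraction of 1000 null webs whose Q reaches the empirical value.

To test whether compartments buffer perturbations, a bioenergetic ODE model
(logistic producers, saturating multi-prey functional response with hill
exponent *h* and predator interference *q*, explicit detritus pools fed by
death and egestion) is calibrated so that the observed web is an exact
equilibrium. After a burn-in, one node is removed and the **removal
effect** on every other node is scored as
`RE_i = ln[(B_i⁺+1)/(B_i⁻+1)] / (B_k+1)`; mean |RE| is compared within vs
between the removed node's compartment.

All of this is testable offline: `channelweb.synthgen` generates balanced
webs with *planted* energy channels and tunable cross-channel coupling.

## Worked example

```sh
channelweb synth --channels 3 --per-channel 8 --levels 3 --eps 0.05 \
    --seed 1 --out toy.json --truth truth.tsv
channelweb all --in toy.json --outdir out --seed 42 --reps 1000 --removals 8
cat out/summary.json
```

prints

```json
{
 "S": 24,
 "S_c": 3,
 "Q": 0.615941829255019,
 "p": 0.0,
 "p_text": "<0.001",
 "null_mean": -0.0330498428195754,
 "null_sem": 0.0030281868984793066,
 "mean_within_RE": 0.03426212495473843,
 "mean_between_RE": 0.0018321367384537088,
 "comparison_Q": {
  "energy": 0.615941829255019,
  "betweenness": 0.17738425414199022,
  "walktrap": 0.615941829255019
 },
 "seed": 42
}
```

Reading this: the 24-node synthetic web with three weakly coupled channels
is resolved into `S_c = 3` compartments with modularity `Q = 0.62`; none of
the 1000 column-sum-preserving null webs reached that value (`p < 0.001`;
the null distribution is centred at −0.03 ± 0.003). Removing a node changes
biomasses inside its own compartment about 19× more than outside it
(mean |RE| 0.034 vs 0.002), and the walktrap baseline finds the same
partition while edge betweenness scores lower (Q = 0.18) — compartments
here really are energy channels.

The same steps run on any web in the package's JSON/TSV schema
(`nodes`: id, name, category ∈ {producer, consumer, decomposer, detritus},
biomass, import, export, respiration; `edges`: source, target, flux). An
`enaR` model `m` can be exported from R by writing `m%n%"flow"` plus the
vertex attributes to those tables; point the optional empirical check in
`tests/test_acceptance.py` at `data/chesapeake_bay.json`. Webs that are not
at steady state should pass through `channelweb balance` first.

## Documentation

`docs/methods.md` describes the model equations, the calibration, every
tunable parameter with its default and rationale, what the synthetic
generator does and does not emulate, and known limitations.
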