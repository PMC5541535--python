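# Methods

`troopmove` infers *who moves whom* in a stable social group from sparse,
asynchronous GPS fixes, and asks whether the dyad-level answers assemble
into group-level structure (a core of mutually dependent animals versus a
single leader versus diffuse influence).  This note documents the models,
the estimators, the synthetic-data generator used to validate them, and the
numerical choices, in that order.

## 1. Direction matching

For a focal animal *i*, each pair of consecutive same-day fixes defines a
step with observed unit direction of travel **v̂**ₜ.  The model predicts it
as a linear combination of unit direction vectors, with no intercept:

    v̂_t = Σ_{j≠i} β_{i,j} v̂_{i,j}  +  β_cm v̂_cm  +  β_{t−1} v̂_{t−1}

where **v̂**ᵢⱼ points from the focal to group member *j* at the step start,
**v̂**cm points to the mean position of all other adults, and **v̂**ₜ₋₁ is the
direction of the previous step.  β_{i,j} > 0 is read as attraction to *j*,
β_{i,j} < 0 as repulsion, β_{t−1} as directional persistence.

Because fixes are asynchronous (a single observer rotates through the
group), neighbour positions at the step start are linearly interpolated
between their flanking fixes.  Interpolation never extrapolates, never
crosses a day boundary, and refuses gaps longer than `max_gap` (default
30 min).  The focal's own positions are never interpolated.  Steps are kept
only when the displacement is at least `min_step` = 5 m (the GPS noise
floor; direction is meaningless below it), the previous step supplies a
defined v̂ₜ₋₁, and *every* other adult is interpolatable — complete-case
selection, because the model needs the full predictor set.

The x and y components of each step are stacked as independent observations
with a shared residual standard deviation.  They are not truly independent;
the known consequence is intervals that are somewhat too narrow, which is
why sign decisions use a conservative 99% highest-posterior-density
interval (HPDI) rather than 95%.

**Fitting.**  Coefficients get Normal(0, 0.1) shrinkage priors; the
residual sd gets half-Normal(1).  Because the model is a Gaussian linear
model, the coefficient block is conjugate given the residual scale, so the
posterior is sampled by an exact Gibbs scheme: a joint multivariate-Normal
draw of all coefficients, then a 1-D slice-sampling update of log σ.  This
mixes essentially perfectly (the only coupling is through one scalar),
is deterministic given a seed, and costs milliseconds per fit.  Defaults:
1000 retained draws after 1000 warmup sweeps, 2 chains; the
replicate-heavy recovery studies use 500–1000 draws on a single chain.

**Model comparison.**  A group-only model (persistence + centroid only) is
compared to the full model by WAIC on the deviance scale:
lppd_i = log mean_s exp(ll_si), p_i = var_s(ll_si),
WAIC = −2 Σ_i (lppd_i − p_i), with the standard error
√(n · var_i(pointwise)) and sample variances using ddof = 1.  dWAIC is
group-only minus full, so positive values favour the full model; dSE comes
from the pointwise differences.

## 2. Influence network and core/periphery structure

A directed edge j → i (j influences i) is retained when the 99% HPDI of
β_{i,j} excludes zero; the posterior mean is the edge weight.  Positive
weights form the attraction subgraph; negative ones form the repulsion
subgraph with the magnitude stored as weight and the sign kept as an
attribute.  Under this orientation the *out*-strength of a node is the
total influence it exerts (what field studies often call in-strength:
"others are sensitive to it") and its in-strength is its responsiveness;
the code uses the graph-theoretic definitions and the reports say which
reading they use.

Alpha centrality x = (I − αAᵀ)⁻¹·1 is provided as a soft companion measure
(it stays defined for nodes without incoming edges); α defaults to
0.9/λ_max(A).  In practice it is nearly redundant with strength and is not
used for any decision.

**Weighted k-shell.**  Core/periphery structure is measured on the
attraction subgraph, symmetrised by summing reciprocal weights.  Each node
gets the score k′ = √(k·s) (current degree × current strength — the
weighted k-core with both exponents 1; note that a node with k = 2, s = 4
scores √8 ≈ 2.83).  Pruning removes, simultaneously, every node with k′ at
or below the running threshold, assigns it the threshold as its shell
value, recomputes k′, and raises the threshold to the minimum remaining k′
when no node qualifies.  Isolated nodes have shell 0; the innermost
(maximal) shell is the detected core.

**D_core and the permutation null.**  The scalar magnitude of
core/periphery structure is D_core = Σᵢ Σⱼ |xᵢ − xⱼ| over *all ordered*
node pairs of shell values (translation-invariant, linear in scale).  Its
null distribution comes from random graphs that keep the node set and the
exact multiset of observed edge weights but place them on uniformly
sampled distinct directed non-self pairs (edge count fixed; the
alternative of redrawing an edge *probability* would inject density
variance that the observed network does not have).  The observed structure
is called significant when D_core exceeds the null's 95% quantile.
Feeding the test graphs drawn from its own null flags ~5% of them, as it
should (verified at ±2.5% over 400 replicates).

## 3. Rank model

Posterior-mean coefficients β_{i,j} are regressed on rank difference with
a varying intercept per influenced animal:

    β_{i,j} = β_r · Δrank_{i,j} + g_i + ε

Δrank_{i,j} is the merged group-wide ordinal rank of *i* minus that of
*j* (males ranked above females by default; the merge order is
configurable), so β_r > 0 means animals are more influenced by those above
them.  Priors: Normal(0, 0.1) on β_r, hierarchical Normal(0, σ_g) on the
intercepts, half-Normal(1) on both scales; the sampler is the same Gibbs +
slice scheme.  This is deliberately a two-stage procedure — first-stage
posterior uncertainty in β_{i,j} is not propagated.

Explained variance is a posterior variance-components R²: per draw, with
v_f = var(fitted rank term), v_g = var(realised intercepts) and σ² the
residual variance, r2_fixed = v_f/(v_f+v_g+σ²) and
r2_full = (v_f+v_g)/(v_f+v_g+σ²), summarised by posterior medians.  This
marginal/conditional convention nests by construction (r2_fixed ≤ r2_full
in every draw); the naive var(fit)/(var(fit)+σ²) form does not, because
fitted intercepts can anticorrelate with the rank trend.

## 4. Synthetic troop generator

The simulator is the generative mirror of the direction-matching model.
Per tick, each agent's new heading is the normalisation of

    w_persist · ĥ_prev  +  Σ_j W[i,j] · û(i→j)  +  w_cm · û(i→centroid_excl_i)

followed by a Gaussian rotation (sd `heading_noise_sd`); the agent then
advances `speed` metres along the new heading.  Influence acts on heading
only; speed is constant.  Defaults, chosen once for field realism:
tick 30 s; speed 12 m/tick (≈0.4 m/s, a travel-foraging pace); persistence
0.5; heading noise 0.3 rad; initial spread 15 m; optional reflecting square
arena (home range).  Observation days are 12-h follows; no step or
interpolation crosses a day.

The observer model is a fixed cyclic sweep: one fix per animal per
rotation, visit times jittered (sd 5 s), snapped to the nearest simulated
tick, with isotropic GPS noise (sd 5 m).  Fourteen animals at a 38.6-s
dwell reproduce a 9-minute mean revisit; the desk-scale studies here use
6–12 agents degraded to an 8-minute revisit over 100 h, which yields
≈700 usable steps per animal — deliberately the *sparse* end of what a
field season produces, so recovery results are lower bounds.

**Scenario definitions** (all planted weights are design choices of this
package, frozen before the recovery studies and reported with every
experiment):

- *leader*: everyone is attracted (weight 1) to one individual.
- *chain*: agent k follows agent k−1 (weight 1); the head follows nobody.
- *ring*: closed chain; every agent has exactly one planted influence.
- *diffuse*: all pairwise weights equal at 1/(n−1).
- *core_periphery*: a core of ⌈n/3⌉ agents mutually attracting with row
  sum 1.2; each periphery agent weakly follows one core member (0.25,
  round-robin); heading noise 1.0 rad.  The strong-dense-core /
  sparse-weak-periphery contrast is what defines the scenario: when
  periphery animals are instead strongly tied to *all* core members, the
  screened network is dense and shell-flat and the observed D_core falls
  *below* its own null — a genuine property of the statistic, not an
  estimator failure.
- *pairs* (calibration only): disjoint follower pairs with `w_cm = 0` and a
  2-km reflecting arena.  Cross-pair dyads then have no causal pathway in
  either direction, making them genuine planted-zero dyads: with any
  group-centroid pull each neighbour owns a real 1/(n−1) share of the
  centroid, and shrinkage redistributes that real effect across the
  collinear per-neighbour predictors, so "zero" dyads would not be zero.
  The arena keeps the direction predictors stationary once cohesion is
  removed.
- *rank*: lower-ranked agents follow superiors with pull growing linearly
  in the rank gap (rows normalised to 1).

The travelling scenarios (leader/chain/ring/diffuse/rank) keep a mild
centroid pull w_cm = 0.2 so the troop stays bunched as a real one does.

## 5. What the simulations do and do not show

The generator emulates: individual-specific attraction, group attraction,
persistence, constant-speed travel, observer-sweep sparsity, timing jitter
and GPS noise.  It does not emulate habitat structure, resource-driven
route choice, speed modulation, fission–fusion, context-dependent
switching of influence, or the true x–y dependence of movement noise.
Passing recovery tests therefore demonstrates that the estimator chain is
correct and calibrated *under its own assumptions at field sampling
density*; it does not certify the behavioural realism of any particular
field inference.

Known, deliberately reproduced limitations:

- **Downstream attribution.** In an open chain the head acquires a positive
  fitted influence on the tail although the coupling is entirely indirect;
  at 8-min resolution mid-chain followers can lose credit to animals
  further upstream.  Influence estimates identify *who systematically
  shapes whose movement*, not the proximate mechanism.
- **Reverse-causation edges.** A follower's position is caused by its
  leader's past movement, so leader-side fits can show spurious
  (often negative) coefficients toward their own followers.  Roughly half
  of such reverse dyads are flagged in the pairs calibration; causally
  isolated dyads are flagged at well under the nominal 1%.
- **Anti-conservatism.** The x/y-stacking makes intervals narrow; the 99%
  screening rule compensates but does not fully cure it.
- **Core over-inclusiveness.** The detected innermost shell reliably
  contains the planted core and may include extra animals; its membership
  is a coarse estimate.

## 6. Numerical details

- Unit vectors are undefined below 0.1 m displacement and return nothing
  rather than a zero-filled vector.
- HPDI: minimal-width window over the sorted draws (exact for the unimodal
  posteriors produced here).
- k-shell pruning uses a 1e-9 tolerance on threshold comparisons; ties are
  removed in the same pass.
- The permutation test uses strict inequality (observed > q95), and
  `numpy.quantile`'s default linear interpolation for q95.
- All randomness flows through `numpy.random.Generator` seeded per
  component; identical (config, seed) reruns are bit-identical, and the
  two-chain sampler spawns independent child seeds via `SeedSequence`.
- Problem sizes in the shipped tests and acceptance studies — 6–12 agents,
  100 h, 8-min revisit, 40 specificity replicates, 400 calibration
  replicates at 200 permutations, 10 000 permutations in the worked
  example — are the package's chosen desk-scale study conditions.
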