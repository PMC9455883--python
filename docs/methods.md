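# Methods

This note documents the models and procedures implemented in `conngen`,
the assumptions behind them, the defaults and why they were chosen, and
what the validation machinery does and does not establish.

## Connectivity rules and their semantics

A projection applies one rule to an ordered source population `S` (size
`N_s`) and target population `T` (size `N_t`). The admissible pair space is
the Cartesian product `S × T`; when `S` and `T` are the same population and
autapses (self-connections) are disallowed, the diagonal is removed, so per
node the admissible pool shrinks by one and the space has `N_s (N_s − 1)`
pairs. Multapses are repeated (source, target) pairs; edge lists are
ordered sequences precisely so multapses are representable and output is
byte-reproducible.

Sampling algorithms are chosen for speed but are equivalent in law to the
per-pair definitions:

- **Pairwise Bernoulli** draws the edge count from Binomial(M, p) over the
  M admissible pairs and then a uniform subset of that size. This has
  exactly the distribution of M independent per-pair trials (the subset
  conditional on the count is uniform in both constructions). Multapses
  cannot occur because each pair is decided once.
- **Fixed total** samples `N_syn` linear pair indices without replacement
  (uniform subsets) or with replacement (i.i.d. uniform draws).
- **Fixed in-degree** lets every target draw `K_in` sources from its own
  admissible pool, independently of other targets, without or with
  replacement; **fixed out-degree** is the mirror image. Edges are emitted
  target-major (in-degree rules) or source-major (out-degree rules); the
  order is documented but carries no semantics.

Pair iteration order is deliberately unspecified for the Bernoulli rule
(the pairs are exchangeable), so only distributional properties are tested.

## Analytic oracles

For each rule the closed-form degree marginals are exposed
(binomial; hypergeometric and binomial marginals of the multivariate
hypergeometric and multinomial joints; point masses for the fixed-degree
side), together with the expected edge count and an exact probability
measure over whole networks. Networks are compared as unordered multisets
of edges. The joint degree distributions are *not* materialized — their
support grows combinatorially — because the marginals plus the exact
network measure suffice for validation: at tiny sizes all possible networks
are enumerated, their probabilities must sum to 1, and marginalizing the
enumeration must reproduce the closed forms (this is tested).

For the fixed in-degree rule the out-degree statement is interpreted with
targets drawing independently, so a source's total out-degree is
Binomial(N_t, K_in/N_s) without multapses and Binomial(N_t·K_in, 1/N_s)
with them (per-dimension counts reduced by one on diagonal-excluded
spaces). The single-target marginal is then Bernoulli(K_in/N_s), consistent
with viewing the joint as a sum of independent per-target instances.

All probability computation is in log-space via log-gamma; normalization
tests use an absolute tolerance of 1e-10.

## Statistical self-validation

Two layers of checks, with chi-square verdicts at α = 0.01:

1. **Network-level**: 60 000 seeded samples per rule/constraint combination
   at `N_s = N_t = 2` against the exactly enumerated measure. Combinations
   whose measure is a point mass (e.g. fixed in-degree 1 on a two-node pool
   without autapses) are checked for the forced outcome instead.
2. **Marginal-level**: pooled degree histograms over 200 realizations at
   N up to 50 against the closed forms. Expected counts below 5 are merged
   from the histogram tails inward; degrees of different nodes are pooled,
   which is exact for rules with independent per-node draws and a mild
   approximation for fixed-total rules (weak negative coupling through the
   shared total).

A correct sampler fails a single α = 0.01 comparison one time in a
hundred by construction. Each failing comparison is therefore repeated
once on an independent RNG substream and only a double failure counts:
the per-comparison false-failure probability drops to 1e-4 while a wrong
sampler still fails essentially always. Constraint audits (no autapse, no
multapse, exact degrees/totals, handshake identity) are exact and allow
zero violations.

## Spatial connectivity

Spaces are boxes `[0, L)^d` (d = 1, 2, 3) with ℓ2 or ℓ∞ metric and
periodic or open boundaries; periodic distances use the minimum-image
convention (per-dimension separation ≤ L/2). Profile values are clamped to
[0, 1] after evaluation — the leading constant is taken literally and
clamping is logged — because the profile forms are defined only up to a
proportionality constant. Distance-modulated Bernoulli connectivity
evaluates each admissible pair exactly once in source blocks (no full
distance matrix), and the pair-level check is that the distance-binned
connection frequency recovers the generating profile. Open boundaries
perform no edge-effect correction; border bins are simply inhomogeneous.

## The patchy (PB) generator

Two-dimensional periodic square, excitatory neurons uniform, inhibitory on
a jittered grid with grid constant `L/√N_I`. The square is tiled into a
`group_grid × group_grid` partition; group membership is by containing
square (the group count is a config parameter — it is a property of the
model family, not derivable from first principles). Each group draws
`Np ~ U{Np_min..Np_max}` patch centers at distance `dp ~ Normal(dp_mean,
dp_sd)` (non-positive draws redrawn, logged) and uniform angle. Each
neuron projects to `Npn ~ Binomial(n_Npn, p_Npn)` of its group's patches
(draws above `Np` redrawn — truncation by redraw), chosen uniformly
without replacement.

Out-degree quotas are drawn first — `Binomial(N − 1, c_loc)` locally and
`Binomial(N − 1, c_total − c_loc)` for patches, giving means `c·(N − 1)` —
then met exactly: local edges by accepting uniform candidates with the
Gaussian profile probability (capped at 10⁴ attempts per source, then
truncated with a warning), patchy edges as uniform subsets of the targets
within radius `rp` of the chosen patches ("constant within a certain
radius"). Multapses and autapses are excluded in both systems. The
accepted-distance distribution follows the profile-weighted pair-distance
density faithfully only while quotas are small relative to the footprint
capacity; the defaults keep that regime. Patch sets of different groups
may overlap; nothing forbids it.

Defaults (units of L): `c_loc = 0.02`, `c_total = 0.03`, `p0 = 0.8`,
`σ = 0.1`, `rp = 0.1`, `dp_mean = 0.3`, `dp_sd = 0.05`, `Np ∈ {2..4}`,
`Npn ~ B(4, 0.5)`, 4×4 groups, jitter `J = 0.0125` (half the inhibitory
grid constant at `N_I = 400`). These place patches well outside the local
footprint (dp ≈ 3σ), keep patch capacity comfortably above the patchy
quotas, and yield a realized density within a few percent of `c_total`
(the shortfall comes from neurons whose patches contain slightly fewer
targets than their quota; it is logged, not hidden).

## Balanced random network

Leaky integrate-and-fire neurons with delta synapses: between grid points
the membrane decays exactly (`exp(−dt/τ_m)`); a spike arriving after delay
`d` jumps the membrane by the connection weight (J excitatory, −gJ
inhibitory); threshold crossing emits a spike and resets with an absolute
refractory period during which input is ignored. Delays are handled by a
ring buffer, so `dt` must divide `d`. Each neuron receives an independent
external Poisson drive of rate `η·ν_thr·C_E` with
`ν_thr = θ/(J·C_E·τ_m)`, delivered as J-sized jumps — independent per
target even though simulators often implement this with a single shared
generator device.

Defaults follow the public reference implementation of this model family:
`g = 5`, `η = 2`, `J = 0.1 mV`, `d = 1.5 ms`, `τ_m = 20 ms`, `θ = 20 mV`,
`V_reset = 0`, `t_ref = 2 ms`, `C_E = 0.1·N_E`, `C_I = 0.1·N_I`,
`N_E = 10 000`, `N_I = 2 500`, `dt = 0.1 ms`. All are config-overridable
and documented as defaults, not certified values.

The *fixed in-degree* variant gives every neuron exactly `C_E` excitatory
and `C_I` inhibitory inputs (autapses prohibited, multapses allowed). The
*fixed out-degree* variant fixes, per projection, the out-degree at the
value that makes each projection's edge total match the fixed in-degree
variant exactly (`C·N_t/N_s`); non-integer cases are rejected with a
suggestion. The demonstration runs both variants at 20% scale for 1 s:
totals are equal by construction, network-mean rates agree within a few
percent, and the per-neuron rate SD is roughly an order of magnitude
larger under fixed out-degree. The 20% scale and 1 s duration are the
reference configuration for the shipped checks; the full-scale network is
available through the same API.

## Notation and diagrams

Rule symbols (δ, Ω, X, p, N_syn, K_in, K_out, p(r)) and constraint flags
follow the convention that a plain letter means *allowed* and a struck-out
letter *prohibited*; ASCII fallbacks (`delta`, `!A`, `w=const`) exist
because many DOT renderers mishandle combining characters. The autapse
flag is emitted only for within-population projections (self-connections
cannot occur between disjoint populations) and the multapse flag only for
rules that can produce multapses — the notation deliberately does not
distinguish configurations that are semantically identical. DOT export
maps roles to node shapes (square/triangle/circle/hexagon/parallelogram),
population nodes to `peripheries=2`, determinism to solid vs dashed edges,
and symmetric connections to two-headed arrows.

## Reproducibility machinery

A single root seed plus a per-projection substream index (NumPy
`SeedSequence` spawn keys) derives every generator stream, so adding a
projection to a config never perturbs earlier ones, and identical
(config, seed) gives byte-identical outputs. Configs require an explicit
seed; within-population projections that omit the autapse policy default
to *disallowed* with a warning, since roughly half of published models
exclude them and silence is the main source of ambiguity. Provenance
records embed the canonical config, its SHA-256 hash, the seed, and
per-projection edge counts; regeneration from the record is tested to be
byte-identical.

## Known limitations

- Degree-correlated, motif-constrained, small-world, and scale-free
  generators are out of scope, as are dendrite-level connectivity and
  plastic evolution of the connectivity.
- Edge lists are dense in memory; the toolkit targets desk-scale networks
  (≲ 10⁷ edges), not supercomputer-scale instantiation.
- The chi-square marginal tests pool nodes; for fixed-total rules this is
  approximate (see above). The passing suite shows the generators match
  their defining distributions — it does not certify any biological
  realism of the synthetic layouts (uniform/jittered-grid placement,
  isotropic Gaussian footprints) relative to real cortical tissue.
- Open-boundary spatial connectivity has uncorrected border effects.
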