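# conngen

Connectivity concepts for neuronal network models, as an executable
toolkit: rule-based connectivity generators with explicit autapse/multapse
semantics, closed-form degree distributions that double as validation
oracles, distance-dependent and patchy connectivity on periodic domains,
statistical self-tests, a symbolic/graphical notation export, and a
balanced-random-network demonstration of why the precise connection rule
matters dynamically.

## The problem

Statements like "*N_s* sources and *N_t* targets are connected randomly
with probability *p*" admit several inequivalent readings: per-pair
Bernoulli trials, a fixed total number of edges drawn with or without
replacement, or a fixed number of inputs per neuron. These readings differ
in their degree distributions — and networks built from them can behave
differently even when their edge totals coincide. `conngen` makes each
reading an explicit, seeded, auditable generator:

| rule | symbol | in-degree distribution |
|---|---|---|
| one-to-one | δ | δ(K, 1) |
| all-to-all | Ω | δ(K, N_s) |
| explicit list / adjacency matrix | X | given |
| pairwise Bernoulli(p) | p | B(K \| N_s, p) |
| fixed total N_syn, no multapses | N_syn | hypergeometric marginal |
| fixed total N_syn, multapses | N_syn, M | B(K \| N_syn, 1/N_t) |
| fixed in-degree K_in | K_in | δ(K, K_in) |
| fixed out-degree K_out | K_out | hypergeometric / binomial marginal |

Every rule takes a `Constraints(allow_autapses, allow_multapses)` policy
(A = self-connections, M = repeated source–target pairs), and every
probabilistic rule is backed by an exact network-level probability measure
(`network_log_probability`) so generated ensembles can be chi-square-tested
against enumeration at small sizes.

Spatially embedded networks specify dimension, layout (uniform or jittered
grid), metric (ℓ2 or ℓ∞), boundary (periodic with minimum-image distances,
or open), and a connectivity profile p(r): boxcar, linear, sigmoidal,
exponential, Gaussian, or anisotropic Gaussian. A patchy-connectivity
generator (the "PB model") combines a local Gaussian footprint with
group-shared, disk-shaped long-range patches.

## Worked example

```python
from conngen import compare_variants, run_demo

stats = {}
for variant in ("fixed_in", "fixed_out"):
    net, spikes, st = run_demo(variant, scale=0.2, duration=1000.0, seed=0)
    stats[variant] = st
    print(variant, net.n_syn_total, round(st["mean_rate"], 1),
          round(st["sd_rate"], 2))
```

prints

```
fixed_in  625000 52.9 0.81
fixed_out 625000 52.6 8.04
```

Both balanced excitatory–inhibitory LIF networks (2000 E + 500 I neurons,
20% of the reference scale, 1 s biological time) have exactly the same
number of connections (625 000) and nearly the same network-mean rate
(~53 spikes/s), but with a fixed *out*-degree each neuron's random
*in*-degree sets its operating point: the per-neuron rate SD grows from
0.81/s to 8.04/s — a tenfold broadening caused solely by the reading of
"randomly connected".

More narrative scripts live in `examples/` (one per capability: rules,
analytics, validation, spatial, patchy, Brunel contrast, notation export,
config workflow). A thin CLI mirrors them:

```bash
conngen generate config.json --out network_out/
conngen validate config.json
conngen export-dot config.json > net.dot
conngen brunel-demo --variant fixed_out --scale 0.2 --seed 1
```

Configs are JSON with a mandatory seed; outputs are edge-list TSVs plus a
provenance record from which every file can be regenerated byte for byte.

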