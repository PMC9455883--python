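"""The PB model: local Gaussian plus non-local patchy connectivity.

Lays out excitatory neurons uniformly and inhibitory neurons on a jittered
grid in a periodic square, tiles the square into neuron groups, assigns
each group a set of distant disk-shaped patches, and wires local
(Gaussian-footprint) and patchy (within-patch) excitatory connections with
exact per-neuron out-degree quotas.
"""

import numpy as np

from conngen import (PatchySpec, assign_groups, assign_patches, build_pb_layout,
                     connect_local, connect_patchy, degree_counts, derive_rng)

spec = PatchySpec(n_e=1600, n_i=400)
rng = derive_rng(seed=6)

exc, inh, space = build_pb_layout(spec, rng)
print(f"layout: {exc.size} E uniform, {inh.size} I on a jittered grid "
      f"(grid constant {spec.L / np.sqrt(spec.n_i):.3f})")

group_id, centers = assign_groups(spec, exc.positions)
patches = assign_patches(spec, centers, rng)
n_patches = [len(p) for p in patches]
print(f"{len(patches)} groups with {min(n_patches)}-{max(n_patches)} patches each "
      f"(radius rp={spec.rp}, distance ~N({spec.dp_mean}, {spec.dp_sd}))")

local, q_loc = connect_local(exc, exc, spec, rng)
patchy, q_patch, _ = connect_patchy(exc, exc, spec, group_id, patches, rng)
density = (len(local) + len(patchy)) / (exc.size * (exc.size - 1))
print(f"local edges: {len(local)} (quotas met: "
      f"{np.array_equal(degree_counts(local, 'out'), q_loc)})")
print(f"patchy edges: {len(patchy)} (quotas met: "
      f"{np.array_equal(degree_counts(patchy, 'out'), q_patch)})")
print(f"overall density {density:.4f} vs target c_total={spec.c_total}")
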