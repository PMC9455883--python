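"""Deterministic and probabilistic connection rules on small populations.

Builds a few projections between an 8-neuron source and 6-neuron target
population and prints the edge counts and degree sequences each rule
produces.  Note how the fixed in-degree rule pins every target's in-degree
exactly while leaving out-degrees random.
"""

from conngen import (Constraints, Population, connect_all_to_all,
                     connect_fixed_indegree, connect_one_to_one,
                     connect_pairwise_bernoulli, degree_counts, derive_rng)

src = Population("S", 8)
tgt = Population("T", 6, offset=8)
rng = derive_rng(seed=1)

all2all = connect_all_to_all(src, tgt)
print(f"all-to-all: {len(all2all)} edges (= N_s * N_t = {8 * 6})")

bern = connect_pairwise_bernoulli(src, tgt, p=0.25, rng=rng)
print(f"pairwise Bernoulli p=0.25: {len(bern)} edges "
      f"(expected {0.25 * 48:.0f}), in-degrees {degree_counts(bern, 'in')}")

fin = connect_fixed_indegree(src, tgt, k_in=3,
                             constraints=Constraints(allow_multapses=True),
                             rng=rng)
print(f"fixed in-degree K_in=3: in-degrees {degree_counts(fin, 'in')} (all 3),"
      f" out-degrees {degree_counts(fin, 'out')} (random)")

same = Population("A", 6)
one = connect_one_to_one(same, Population("B", 6, offset=6))
print(f"one-to-one: every degree is 1 -> {degree_counts(one, 'out')}")

# self-projection without self-connections: the diagonal is excluded
noauto = connect_all_to_all(same, same, Constraints(allow_autapses=False))
print(f"all-to-all on itself without autapses: {len(noauto)} edges "
      f"(= N(N-1) = {6 * 5})")
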