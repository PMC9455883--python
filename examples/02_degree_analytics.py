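"""Closed-form degree distributions and exact network probabilities.

The analytic marginals are the oracles against which the samplers are
validated: binomial for pairwise Bernoulli, hypergeometric for fixed
totals without multapses, binomial marginals of the multinomial for draws
with replacement.  The exact network measure assigns a probability to any
concrete edge multiset.
"""

import math

from conngen import (Constraints, DegreeModel, Population, RuleSpec,
                     connect_explicit, expected_total_edges, indegree_pmf,
                     network_log_probability, outdegree_pmf)

model = DegreeModel(RuleSpec("pairwise_bernoulli", p=0.5), n_s=4, n_t=4)
print(f"Bernoulli N_s=4 p=0.5: P(K_in=2) = {indegree_pmf(model, 2):.4f} "
      "(binomial C(4,2)/16 = 0.375)")
print(f"  expected edge count = {expected_total_edges(model):.1f}")

mult = Constraints(allow_multapses=True)
m2 = DegreeModel(RuleSpec("fixed_in", k_in=3, constraints=mult), n_s=2, n_t=4)
print(f"fixed K_in=3 with multapses, N_s=2, N_t=4: out-degree ~ B(12, 1/2); "
      f"P(K_out=6) = {outdegree_pmf(m2, 6):.4f}")

# exact probability of a concrete network under 'fixed total number'
s, t = Population("S", 2), Population("T", 2, offset=2)
m3 = DegreeModel(RuleSpec("fixed_total", n_syn=2), 2, 2)
net = connect_explicit([(0, 2), (1, 3)], s, t)
logp = network_log_probability(m3, net)
print(f"fixed N_syn=2 on 2x2: any 2-subset has probability "
      f"exp({logp:.4f}) = {math.exp(logp):.4f} (1/C(4,2) = 1/6)")
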