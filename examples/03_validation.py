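"""Statistical self-validation of a generated ensemble.

Draws 300 realizations of a Bernoulli projection, pools the in-degree
histogram, and chi-square-tests it against the analytic binomial marginal;
then audits hard constraints on a fixed in-degree realization.  A passing
test (p > alpha) means the ensemble is statistically indistinguishable
from the rule's definition.
"""

from conngen import (DegreeModel, Population, RuleSpec, audit_constraints,
                     connect_explicit, derive_rng,
                     empirical_degree_distribution, gof_chi_square,
                     indegree_pmf)
from conngen.probabilistic import generate

src = Population("S", 30)
tgt = Population("T", 30, offset=30)
rule = RuleSpec("pairwise_bernoulli", p=0.2)
model = DegreeModel.for_projection(rule, src, tgt)

rng = derive_rng(seed=4)
ensemble = [generate(rule, src, tgt, rng) for _ in range(300)]
hist = empirical_degree_distribution(ensemble, "in")
result = gof_chi_square(hist, lambda k: indegree_pmf(model, k), alpha=0.01)
print(f"in-degree GoF vs Binomial(30, 0.2): {result}")

clean = generate(RuleSpec("fixed_in", k_in=4), src, tgt, rng)
print(f"audit of a fixed in-degree realization: "
      f"{audit_constraints(clean, RuleSpec('fixed_in', k_in=4)) or 'no violations'}")

# an injected duplicate under a no-multapse rule is caught
bad = connect_explicit([(0, 30), (0, 30)], src, tgt)
print(f"audit of an injected duplicate: "
      f"{audit_constraints(bad, RuleSpec('fixed_total', n_syn=2))}")
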