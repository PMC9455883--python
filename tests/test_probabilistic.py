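"""Probabilistic rules: exact constraints, distributional correctness."""

from collections import Counter

import numpy as np
import pytest

from conngen import (Constraints, DegreeModel, Population, RuleSpec,
                     chi_square_counts, connect_fixed_indegree,
                     connect_fixed_outdegree, connect_fixed_total,
                     connect_pairwise_bernoulli, degree_counts, derive_rng,
                     enumerate_networks)
from conngen.probabilistic import generate


class TestPairwiseBernoulli:
    def test_p_zero_empty(self, pops, rng):
        src, tgt = pops
        assert len(connect_pairwise_bernoulli(src, tgt, 0.0, rng=rng)) == 0

    def test_p_one_full(self, rng):
        s, t = Population("S", 3), Population("T", 3, offset=3)
        el = connect_pairwise_bernoulli(s, t, 1.0, rng=rng)
        assert len(el) == 9
        assert len(set(el.pairs())) == 9

    def test_p_out_of_range(self, pops, rng):
        with pytest.raises(ValueError):
            connect_pairwise_bernoulli(*pops, 1.5, rng=rng)

    def test_edge_count_distribution_binomial(self):
        """N_s=N_t=2, p=0.5: edge count over the 16 equally likely outcomes."""
        s, t = Population("S", 2), Population("T", 2, offset=2)
        rng = derive_rng(42)
        n = 20_000
        counts = Counter(len(connect_pairwise_bernoulli(s, t, 0.5, rng=rng))
                         for _ in range(n))
        from scipy.stats import binom
        probs = {k: binom.pmf(k, 4, 0.5) for k in range(5)}
        res = chi_square_counts(counts, probs, n, alpha=0.01)
        assert res.passed, str(res)

    def test_mean_edge_count_within_4_se(self):
        s, t = Population("S", 20), Population("T", 20, offset=20)
        p, reps = 0.1, 1000
        rng = derive_rng(5)
        sizes = [len(connect_pairwise_bernoulli(s, t, p, rng=rng))
                 for _ in range(reps)]
        m = 400
        se = np.sqrt(m * p * (1 - p) / reps)
        assert abs(np.mean(sizes) - p * m) < 4 * se


class TestFixedTotal:
    def test_full_capacity_forced(self, rng):
        s, t = Population("S", 2), Population("T", 3, offset=2)
        el = connect_fixed_total(s, t, 6, rng=rng)
        assert sorted(el.pairs()) == sorted((a, b) for a in (0, 1) for b in (2, 3, 4))

    def test_zero_empty(self, pops, rng):
        assert len(connect_fixed_total(*pops, 0, rng=rng)) == 0

    def test_capacity_error_reports_max(self, rng):
        s, t = Population("S", 2), Population("T", 2, offset=2)
        with pytest.raises(ValueError, match="at most 4"):
            connect_fixed_total(s, t, 5, rng=rng)

    def test_uniform_over_the_six_networks(self):
        """N_s=N_t=2, N_syn=2 without multapses: all C(4,2)=6 subsets equiprobable."""
        s, t = Population("S", 2), Population("T", 2, offset=2)
        rng = derive_rng(99)
        n = 30_000
        counts = Counter(connect_fixed_total(s, t, 2, rng=rng).canonical()
                         for _ in range(n))
        assert len(counts) == 6
        probs = {key: 1 / 6 for key in counts}
        res = chi_square_counts(counts, probs, n, alpha=0.01)
        assert res.passed, str(res)


class TestFixedDegree:
    def test_exact_indegrees(self, rng):
        s, t = Population("S", 5), Population("T", 3, offset=5)
        el = connect_fixed_indegree(s, t, 2, rng=rng)
        assert len(el) == 6
        assert np.all(degree_counts(el, "in") == 2)

    def test_exact_outdegrees(self, rng):
        s, t = Population("S", 3), Population("T", 5, offset=3)
        el = connect_fixed_outdegree(s, t, 2, rng=rng)
        assert len(el) == 6
        assert np.all(degree_counts(el, "out") == 2)

    def test_zero_degree_empty(self, pops, rng):
        assert len(connect_fixed_indegree(*pops, 0, rng=rng)) == 0
        assert len(connect_fixed_outdegree(*pops, 0, rng=rng)) == 0

    def test_capacity_errors(self, rng):
        s, t = Population("S", 3), Population("T", 3, offset=3)
        with pytest.raises(ValueError, match="K_in=4 exceeds"):
            connect_fixed_indegree(s, t, 4, rng=rng)
        a = Population("A", 3)
        with pytest.raises(ValueError, match="exceeds"):
            connect_fixed_indegree(a, a, 3, Constraints(allow_autapses=False), rng=rng)
        # with multapses the draw is with replacement, so no capacity limit
        el = connect_fixed_indegree(s, t, 7, Constraints(allow_multapses=True), rng=rng)
        assert np.all(degree_counts(el, "in") == 7)

    def test_outdegree_marginal_matches_binomial(self):
        """Fixed in-degree with multapses: source out-degree ~ B(N_t*K_in, 1/N_s)."""
        from conngen import gof_chi_square, outdegree_pmf
        s, t = Population("S", 2), Population("T", 4, offset=2)
        rule = RuleSpec("fixed_in", k_in=3,
                        constraints=Constraints(allow_multapses=True))
        model = DegreeModel.for_projection(rule, s, t)
        rng = derive_rng(11)
        hist = Counter()
        for _ in range(5000):
            el = connect_fixed_indegree(s, t, 3, rule.constraints, rng)
            hist.update(degree_counts(el, "out").tolist())
        res = gof_chi_square(dict(hist), lambda k: outdegree_pmf(model, k))
        assert res.passed, str(res)

    def test_transpose_equivalence(self):
        """fixed_out(S,T,K) has the law of transposed fixed_in(T,S,K)."""
        s, t = Population("S", 2), Population("T", 2, offset=2)
        n = 20_000
        rng = derive_rng(21)
        out_counts = Counter(connect_fixed_outdegree(s, t, 1, rng=rng).canonical()
                             for _ in range(n))
        model = DegreeModel(RuleSpec("fixed_in", k_in=1), 2, 2)
        exact = enumerate_networks(model)
        # transpose the enumerated fixed_in networks (local indices) into
        # the fixed_out frame: swap roles and map back to global offsets
        probs = {}
        for net, pr in exact.items():
            key = tuple(sorted((t_loc, s_loc + 2) for s_loc, t_loc in net))
            probs[key] = probs.get(key, 0.0) + pr
        res = chi_square_counts(out_counts, probs, n, alpha=0.01)
        assert res.passed, str(res)


RULES_GRID = [
    RuleSpec("pairwise_bernoulli", p=0.3),
    RuleSpec("pairwise_bernoulli", p=0.3, constraints=Constraints(allow_autapses=True)),
    RuleSpec("fixed_total", n_syn=10),
    RuleSpec("fixed_total", n_syn=10, constraints=Constraints(allow_multapses=True)),
    RuleSpec("fixed_in", k_in=3),
    RuleSpec("fixed_in", k_in=3, constraints=Constraints(allow_multapses=True)),
    RuleSpec("fixed_out", k_out=3),
    RuleSpec("fixed_out", k_out=3, constraints=Constraints(allow_multapses=True)),
]


@pytest.mark.parametrize("rule", RULES_GRID,
                         ids=lambda r: f"{r.variant}-A{int(r.constraints.allow_autapses)}"
                                       f"M{int(r.constraints.allow_multapses)}")
@pytest.mark.parametrize("same_pop", [False, True])
def test_constraint_exactness_over_realizations(rule, same_pop):
    """No duplicate pair without multapses; no self-pair without autapses."""
    if same_pop:
        src = tgt = Population("A", 6)
    else:
        src, tgt = Population("S", 6), Population("T", 6, offset=6)
    rng = derive_rng(17)
    for _ in range(100):
        el = generate(rule, src, tgt, rng)
        pairs = el.pairs()
        if not rule.constraints.allow_multapses:
            assert len(set(pairs)) == len(pairs)
        if same_pop and not rule.constraints.allow_autapses:
            assert all(s != t for s, t in pairs)


def test_rulespec_validation():
    with pytest.raises(ValueError, match="unknown rule"):
        RuleSpec("bernouli", p=0.5)
    with pytest.raises(ValueError, match="requires parameter"):
        RuleSpec("fixed_in")
    with pytest.raises(ValueError, match="does not take"):
        RuleSpec("fixed_in", k_in=2, p=0.5)
    with pytest.raises(ValueError):
        RuleSpec("pairwise_bernoulli", p=1.2)
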