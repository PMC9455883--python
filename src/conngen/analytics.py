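"""Closed-form degree distributions and exact network-level probabilities.

For each probabilistic rule this module provides the analytic in-/out-degree
marginals, the expected edge count, and the exact probability measure over
whole networks.  The marginals are:

- pairwise Bernoulli with probability ``p``: in-degree ``B(K | N_s, p)``,
  out-degree ``B(K | N_t, p)`` (one fewer trial on a diagonal-excluded space);
- fixed total ``N_syn`` without multapses: hypergeometric marginals of the
  multivariate hypergeometric joint;
- fixed total with multapses: binomial marginals ``B(K | N_syn, 1/N_t)``
  (in) and ``B(K | N_syn, 1/N_s)`` (out) of the multinomial joint;
- fixed in-degree: in-degree is the point mass at ``K_in``; a source's
  out-degree aggregates independent per-target draws, giving
  ``B(K | N_t, K_in/N_s)`` without multapses and ``B(K | N_t K_in, 1/N_s)``
  with multapses;
- fixed out-degree: mirror image.

Joint degree distributions (multivariate hypergeometric / multinomial) are
exposed only through the exact network measure plus exhaustive enumeration
at tiny sizes; materializing them over degree vectors blows up
combinatorially and the marginals plus the network measure suffice for
validation.  All computation is in log-space via log-gamma.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import EdgeList, Population, same_population
from .probabilistic import RuleSpec

__all__ = [
    "DegreeModel",
    "indegree_pmf",
    "outdegree_pmf",
    "expected_total_edges",
    "network_log_probability",
    "enumerate_networks",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class DegreeModel:
    """A rule applied to an (N_s, N_t) projection, ready for analytics.

    ``same_pop`` states whether source and target are the same population,
    which (with autapses disallowed) removes the diagonal from the
    admissible pair space.
    """

    rule: RuleSpec
    n_s: int
    n_t: int
    same_pop: bool = False

    def __post_init__(self) -> None:
        if self.n_s < 1 or self.n_t < 1:
            raise ValueError("population sizes must be >= 1")
        if self.same_pop and self.n_s != self.n_t:
            raise ValueError("same_pop requires N_s = N_t")

    @classmethod
    def for_projection(cls, rule: RuleSpec, source: Population,
                       target: Population) -> "DegreeModel":
        return cls(rule, source.size, target.size,
                   same_pop=same_population(source, target))

    # --- admissibility geometry -------------------------------------------
    @property
    def _exclude_diag(self) -> bool:
        return self.same_pop and not self.rule.constraints.allow_autapses

    @property
    def m_admissible(self) -> int:
        """Number of admissible (source, target) pairs."""
        return self.n_s * self.n_t - (self.n_s if self._exclude_diag else 0)

    @property
    def sources_per_target(self) -> int:
        """Admissible sources for any single target."""
        return self.n_s - (1 if self._exclude_diag else 0)

    @property
    def targets_per_source(self) -> int:
        """Admissible targets for any single source."""
        return self.n_t - (1 if self._exclude_diag else 0)


def _point_mass(k: int | np.ndarray, at: int) -> np.ndarray:
    return (np.asarray(k) == at).astype(float)


def indegree_pmf(model: DegreeModel, k: int | np.ndarray) -> float | np.ndarray:
    """P(in-degree of a node = k) under the rule."""
    return _degree_pmf(model, k, direction="in")


def outdegree_pmf(model: DegreeModel, k: int | np.ndarray) -> float | np.ndarray:
    """P(out-degree of a node = k) under the rule."""
    return _degree_pmf(model, k, direction="out")


def _degree_pmf(model: DegreeModel, k, direction: str):
    kk = np.asarray(k)
    if np.any(kk < 0):
        raise ValueError("degree must be >= 0")
    r = model.rule
    mult = r.constraints.allow_multapses
    m = model.m_admissible
    # number of admissible counterparts seen by the node whose degree we ask for
    n_pool = model.sources_per_target if direction == "in" else model.targets_per_source

    if r.variant == "pairwise_bernoulli":
        out = stats.binom.pmf(kk, n_pool, r.p)
    elif r.variant == "fixed_total":
        if mult:
            out = stats.binom.pmf(kk, r.n_syn, n_pool / m)
        else:
            out = stats.hypergeom.pmf(kk, m, n_pool, r.n_syn)
    elif r.variant == "fixed_in":
        if direction == "in":
            out = _point_mass(kk, r.k_in)
        elif mult:
            out = stats.binom.pmf(kk, n_pool * r.k_in, 1.0 / model.sources_per_target)
        else:
            out = stats.binom.pmf(kk, n_pool, r.k_in / model.sources_per_target)
    elif r.variant == "fixed_out":
        if direction == "out":
            out = _point_mass(kk, r.k_out)
        elif mult:
            out = stats.binom.pmf(kk, n_pool * r.k_out, 1.0 / model.targets_per_source)
        else:
            out = stats.binom.pmf(kk, n_pool, r.k_out / model.targets_per_source)
    else:  # pragma: no cover - RuleSpec validates variants
        raise NotImplementedError(r.variant)
    return float(out) if np.isscalar(k) or np.asarray(k).ndim == 0 else out


def expected_total_edges(model: DegreeModel) -> float:
    """Exact expectation of the edge count N_syn under the rule."""
    r = model.rule
    if r.variant == "pairwise_bernoulli":
        return r.p * model.m_admissible
    if r.variant == "fixed_total":
        return float(r.n_syn)
    if r.variant == "fixed_in":
        return float(model.n_t * r.k_in)
    if r.variant == "fixed_out":
        return float(model.n_s * r.k_out)
    raise NotImplementedError(r.variant)  # pragma: no cover


def _log_factorial(n: int) -> float:
    return math.lgamma(n + 1)


def _multiset_log_perms(counts: Counter) -> float:
    """log of the multinomial coefficient n! / prod(m_e!)."""
    n = sum(counts.values())
    return _log_factorial(n) - sum(_log_factorial(m) for m in counts.values())


def network_log_probability(model: DegreeModel, edges: EdgeList) -> float:
    """Exact log-probability of the (multi)set of edges under the rule.

    Networks are compared as unordered multisets of (source, target) pairs;
    a network violating any hard constraint of the rule (autapse, multapse,
    exact degree, exact count) has probability 0 and returns ``-inf``.
    Exponentials over the full enumerable space sum to 1.
    """
    r = model.rule
    mult = r.constraints.allow_multapses
    pairs = edges.pairs()
    counts = Counter(pairs)
    n_edges = len(pairs)

    if model._exclude_diag and any(s == t for s, t in counts):
        return NEG_INF
    if not mult and any(c > 1 for c in counts.values()):
        return NEG_INF
    m = model.m_admissible

    if r.variant == "pairwise_bernoulli":
        if r.p == 0.0:
            return 0.0 if n_edges == 0 else NEG_INF
        if r.p == 1.0:
            return 0.0 if n_edges == m else NEG_INF
        return n_edges * math.log(r.p) + (m - n_edges) * math.log1p(-r.p)

    if r.variant == "fixed_total":
        if n_edges != r.n_syn:
            return NEG_INF
        if mult:
            return _multiset_log_perms(counts) - n_edges * math.log(m)
        return -(_log_factorial(m) - _log_factorial(n_edges)
                 - _log_factorial(m - n_edges))

    if r.variant in ("fixed_in", "fixed_out"):
        by_node: dict[int, Counter] = {}
        for (s, t), c in counts.items():
            node = t if r.variant == "fixed_in" else s
            other = s if r.variant == "fixed_in" else t
            by_node.setdefault(node, Counter())[other] = c
        k = r.k_in if r.variant == "fixed_in" else r.k_out
        n_nodes = model.n_t if r.variant == "fixed_in" else model.n_s
        pool = (model.sources_per_target if r.variant == "fixed_in"
                else model.targets_per_source)
        if not mult and k > pool:
            raise ValueError(f"degree {k} infeasible: only {pool} admissible "
                             "counterparts per node without multapses")
        if k == 0:
            return 0.0 if n_edges == 0 else NEG_INF
        if len(by_node) != n_nodes:
            return NEG_INF
        logp = 0.0
        for node_counts in by_node.values():
            if sum(node_counts.values()) != k:
                return NEG_INF
            if mult:
                logp += _multiset_log_perms(node_counts) - k * math.log(pool)
            else:
                logp -= (_log_factorial(pool) - _log_factorial(k)
                         - _log_factorial(pool - k))
        return logp

    raise NotImplementedError(r.variant)  # pragma: no cover


def _admissible_pairs(model: DegreeModel) -> list[tuple[int, int]]:
    return [(s, t) for s in range(model.n_s) for t in range(model.n_t)
            if not (model._exclude_diag and s == t)]


def enumerate_networks(model: DegreeModel) -> dict[tuple[tuple[int, int], ...], float]:
    """All possible networks with their exact probabilities (tiny sizes only).

    Keys are canonical sorted edge tuples in local indices; probabilities
    come from :func:`network_log_probability` and sum to 1.  Intended as an
    oracle for validating the samplers at ``N_s, N_t <= 3``.
    """
    from .core import Population  # local to avoid confusion with global offsets

    if model.n_s * model.n_t > 9:
        raise ValueError("enumeration is restricted to N_s * N_t <= 9")
    r = model.rule
    mult = r.constraints.allow_multapses
    pairs = _admissible_pairs(model)
    src_pop = Population("S", model.n_s)
    tgt_pop = src_pop if model.same_pop else Population("T", model.n_t)

    networks: list[tuple[tuple[int, int], ...]] = []
    if r.variant == "pairwise_bernoulli":
        for size in range(len(pairs) + 1):
            networks.extend(itertools.combinations(pairs, size))
    elif r.variant == "fixed_total":
        combiner = (itertools.combinations_with_replacement if mult
                    else itertools.combinations)
        networks.extend(combiner(pairs, r.n_syn))
    elif r.variant in ("fixed_in", "fixed_out"):
        k = r.k_in if r.variant == "fixed_in" else r.k_out
        nodes = range(model.n_t) if r.variant == "fixed_in" else range(model.n_s)
        per_node: list[list[tuple[tuple[int, int], ...]]] = []
        for node in nodes:
            if r.variant == "fixed_in":
                cands = [(s, node) for s in range(model.n_s)
                         if not (model._exclude_diag and s == node)]
            else:
                cands = [(node, t) for t in range(model.n_t)
                         if not (model._exclude_diag and t == node)]
            combiner = (itertools.combinations_with_replacement if mult
                        else itertools.combinations)
            per_node.append(list(combiner(cands, k)))
        for combo in itertools.product(*per_node):
            networks.append(tuple(itertools.chain.from_iterable(combo)))
    else:  # pragma: no cover
        raise NotImplementedError(r.variant)

    out: dict[tuple[tuple[int, int], ...], float] = {}
    for net in networks:
        key = tuple(sorted(net))
        if key in out:
            continue
        el = EdgeList([s for s, _ in key], [t for _, t in key], src_pop, tgt_pop)
        logp = network_log_probability(model, el)
        if logp > NEG_INF:
            out[key] = math.exp(logp)
    total = sum(out.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise AssertionError(f"enumerated probabilities sum to {total}, not 1")
    return out
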