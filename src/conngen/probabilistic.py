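"""Probabilistic connectivity rules with exact autapse/multapse semantics.

Four rule families are implemented, matching the vocabulary shared by the
major simulators:

- *pairwise Bernoulli*: every admissible (source, target) pair is considered
  exactly once and connected with probability ``p``; multapses are impossible
  by construction.
- *random, fixed total number*: exactly ``N_syn`` edges drawn uniformly from
  the admissible edge set, without replacement (no multapses; every
  ``N_syn``-subset equiprobable) or with replacement (i.i.d. uniform draws).
- *random, fixed in-degree*: every target draws exactly ``K_in`` sources,
  without or with replacement, independently of other targets.
- *random, fixed out-degree*: mirror image of fixed in-degree.

Sampling is equivalent in law to the per-pair definitions: pairwise
Bernoulli draws a binomial edge count and then a uniform subset of that
size, which has the same distribution as independent per-pair trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Constraints, EdgeList, Population, same_population

__all__ = [
    "RuleSpec",
    "connect_pairwise_bernoulli",
    "connect_fixed_total",
    "connect_fixed_indegree",
    "connect_fixed_outdegree",
    "generate",
    "PROBABILISTIC_RULES",
]

PROBABILISTIC_RULES = ("pairwise_bernoulli", "fixed_total", "fixed_in", "fixed_out")


@dataclass(frozen=True)
class RuleSpec:
    """A probabilistic rule variant together with its parameters.

    Exactly the parameter of the chosen variant must be set: ``p`` for
    ``pairwise_bernoulli``, ``n_syn`` for ``fixed_total``, ``k_in`` for
    ``fixed_in``, ``k_out`` for ``fixed_out``.
    """

    variant: str
    p: float | None = None
    n_syn: int | None = None
    k_in: int | None = None
    k_out: int | None = None
    constraints: Constraints = field(default_factory=Constraints)

    def __post_init__(self) -> None:
        if self.variant not in PROBABILISTIC_RULES:
            raise ValueError(f"unknown rule variant {self.variant!r}; "
                             f"supported: {PROBABILISTIC_RULES}")
        required = {"pairwise_bernoulli": "p", "fixed_total": "n_syn",
                    "fixed_in": "k_in", "fixed_out": "k_out"}[self.variant]
        for name in ("p", "n_syn", "k_in", "k_out"):
            value = getattr(self, name)
            if name == required and value is None:
                raise ValueError(f"rule {self.variant!r} requires parameter {name!r}")
            if name != required and value is not None:
                raise ValueError(f"rule {self.variant!r} does not take parameter {name!r}")
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        for name in ("n_syn", "k_in", "k_out"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")


def _admissible(source: Population, target: Population,
                constraints: Constraints) -> tuple[int, bool]:
    """Size of the admissible pair space and whether the diagonal is excluded."""
    exclude_diag = same_population(source, target) and not constraints.allow_autapses
    m = source.size * target.size - (source.size if exclude_diag else 0)
    return m, exclude_diag


def _linear_to_pairs(lin: np.ndarray, source: Population, target: Population,
                     exclude_diag: bool) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices of the admissible space to global (source, target).

    Source-major enumeration; with the diagonal excluded, row ``i`` lists the
    ``N - 1`` targets ``j != i`` in ascending order.
    """
    n_t = target.size
    if not exclude_diag:
        s_loc, t_loc = np.divmod(lin, n_t)
    else:
        s_loc, r = np.divmod(lin, n_t - 1)
        t_loc = r + (r >= s_loc)
    return s_loc + source.offset, t_loc + target.offset


def connect_pairwise_bernoulli(
    source: Population,
    target: Population,
    p: float,
    constraints: Constraints = Constraints(),
    rng: np.random.Generator | None = None,
) -> EdgeList:
    """Connect each admissible pair independently with probability ``p``.

    In-degrees are Binomial(N_s, p) and out-degrees Binomial(N_t, p)
    (one fewer trial on the diagonal-excluded space); the expected total
    number of edges is ``p * N_s * N_t``.  No multapses can occur.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng() if rng is None else rng
    m, excl = _admissible(source, target, constraints)
    n_edges = int(rng.binomial(m, p)) if m > 0 else 0
    lin = rng.choice(m, size=n_edges, replace=False) if n_edges else np.empty(0, np.int64)
    src, tgt = _linear_to_pairs(np.asarray(lin, dtype=np.int64), source, target, excl)
    return EdgeList(src, tgt, source, target)


def connect_fixed_total(
    source: Population,
    target: Population,
    n_syn: int,
    constraints: Constraints = Constraints(),
    rng: np.random.Generator | None = None,
) -> EdgeList:
    """Draw exactly ``n_syn`` edges uniformly from the admissible edge set.

    Without multapses the draw is without replacement, making every
    ``n_syn``-subset equiprobable; with multapses each draw is i.i.d.
    uniform over admissible pairs.
    """
    if n_syn < 0:
        raise ValueError("n_syn must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    m, excl = _admissible(source, target, constraints)
    if constraints.allow_multapses:
        lin = rng.integers(0, m, size=n_syn) if n_syn else np.empty(0, np.int64)
    else:
        if n_syn > m:
            raise ValueError(f"n_syn={n_syn} exceeds capacity: at most {m} distinct "
                             f"edges are possible without multapses")
        lin = rng.choice(m, size=n_syn, replace=False) if n_syn else np.empty(0, np.int64)
    src, tgt = _linear_to_pairs(np.asarray(lin, dtype=np.int64), source, target, excl)
    return EdgeList(src, tgt, source, target)


def connect_fixed_indegree(
    source: Population,
    target: Population,
    k_in: int,
    constraints: Constraints = Constraints(),
    rng: np.random.Generator | None = None,
) -> EdgeList:
    """Connect each target to exactly ``k_in`` sources.

    Each target draws its sources independently of the other targets,
    without replacement (no multapses) or with replacement (multapses
    allowed).  With ``S = T`` and autapses disallowed, the per-target pool
    is ``S`` minus the target itself, so capacity is ``N_s - 1``.  Edges
    are emitted target-major.
    """
    src, tgt = _fixed_degree_draw(source, target, k_in, constraints, rng, indegree=True)
    return EdgeList(src, tgt, source, target)


def connect_fixed_outdegree(
    source: Population,
    target: Population,
    k_out: int,
    constraints: Constraints = Constraints(),
    rng: np.random.Generator | None = None,
) -> EdgeList:
    """Connect each source to exactly ``k_out`` targets (mirror of fixed in-degree).

    Edges are emitted source-major.
    """
    tgt, src = _fixed_degree_draw(target, source, k_out, constraints, rng, indegree=False)
    return EdgeList(src, tgt, source, target)


def _fixed_degree_draw(
    pool_pop: Population,
    fixed_pop: Population,
    k: int,
    constraints: Constraints,
    rng: np.random.Generator | None,
    indegree: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``k`` pool nodes per fixed-side node; returns (pool, fixed) indices."""
    if k < 0:
        raise ValueError("degree must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    exclude_self = (same_population(pool_pop, fixed_pop)
                    and not constraints.allow_autapses)
    pool_size = pool_pop.size - (1 if exclude_self else 0)
    if not constraints.allow_multapses and k > pool_size:
        kind = "K_in" if indegree else "K_out"
        raise ValueError(f"{kind}={k} exceeds capacity: only {pool_size} admissible "
                         f"{'sources' if indegree else 'targets'} per node without multapses")
    if k == 0 or fixed_pop.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    pool_all = np.empty((fixed_pop.size, k), dtype=np.int64)
    for i in range(fixed_pop.size):
        if constraints.allow_multapses:
            draw = rng.integers(0, pool_size, size=k)
        else:
            draw = rng.choice(pool_size, size=k, replace=False)
        if exclude_self:
            draw = draw + (draw >= i)
        pool_all[i] = draw
    fixed_idx = np.repeat(fixed_pop.global_indices, k)
    pool_idx = pool_all.ravel() + pool_pop.offset
    return pool_idx, fixed_idx


def generate(
    rule: RuleSpec,
    source: Population,
    target: Population,
    rng: np.random.Generator | None = None,
) -> EdgeList:
    """Dispatch a :class:`RuleSpec` to the matching generator."""
    c = rule.constraints
    if rule.variant == "pairwise_bernoulli":
        return connect_pairwise_bernoulli(source, target, rule.p, c, rng)
    if rule.variant == "fixed_total":
        return connect_fixed_total(source, target, rule.n_syn, c, rng)
    if rule.variant == "fixed_in":
        return connect_fixed_indegree(source, target, rule.k_in, c, rng)
    if rule.variant == "fixed_out":
        return connect_fixed_outdegree(source, target, rule.k_out, c, rng)
    raise ValueError(f"unsupported rule variant {rule.variant!r}")
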