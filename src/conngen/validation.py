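"""Statistical self-tests of generated ensembles against analytic models.

Generated connectivity can be wrong in ways that are invisible on a single
realization (a biased sampler still satisfies every hard constraint), so the
module offers two complementary checks: a chi-square goodness-of-fit of
pooled degree histograms against the closed-form marginals, and exact audits
of the hard constraints (no autapse / no multapse / exact degrees / exact
totals / handshake identity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .analytics import DegreeModel
from .core import EdgeList, degree_counts
from .probabilistic import RuleSpec

__all__ = [
    "GofResult",
    "empirical_degree_distribution",
    "gof_chi_square",
    "chi_square_counts",
    "audit_constraints",
]


@dataclass(frozen=True)
class GofResult:
    """Outcome of a chi-square goodness-of-fit test."""

    statistic: float
    dof: int
    p_value: float
    passed: bool
    alpha: float
    n_samples: int

    def __str__(self) -> str:
        verdict = "pass" if self.passed else "FAIL"
        return (f"chi2={self.statistic:.3f}, dof={self.dof}, "
                f"p={self.p_value:.4g} ({verdict} at alpha={self.alpha})")


def empirical_degree_distribution(
    realizations: Sequence[EdgeList],
    direction: str,
) -> dict[int, int]:
    """Pooled degree histogram (degree -> node count) over realizations.

    All realizations must share the same population shapes; the counts sum
    to ``len(realizations) * N`` where ``N`` is the relevant side's size.
    """
    if not realizations:
        raise ValueError("need at least one realization")
    ref = realizations[0]
    hist: Counter[int] = Counter()
    for el in realizations:
        if (el.source_pop.size != ref.source_pop.size
                or el.target_pop.size != ref.target_pop.size):
            raise ValueError("realizations have inconsistent population shapes")
        hist.update(degree_counts(el, direction).tolist())
    return dict(sorted(hist.items()))


def gof_chi_square(
    observed: dict[int, int],
    model_pmf: Callable[[np.ndarray], np.ndarray],
    alpha: float = 0.01,
    min_expected: float = 5.0,
) -> GofResult:
    """Chi-square test of a degree histogram against an analytic PMF.

    Expected counts are built from the PMF over ``0..max(observed degree)``
    plus the remaining upper-tail mass in a final open bin.  Bins with
    expected count below ``min_expected`` are merged from the tails inward;
    the test is deterministic given its inputs.  ``dof = bins - 1``.
    """
    if not observed:
        raise ValueError("empty histogram")
    n = sum(observed.values())
    if n <= 0 or any(c < 0 for c in observed.values()):
        raise ValueError("observed counts must be non-negative and sum > 0")
    k_max = max(observed)
    support = np.arange(k_max + 1)
    pmf = np.asarray(model_pmf(support), dtype=float)
    if np.any(pmf < -1e-12):
        raise ValueError("model PMF returned negative probabilities")
    pmf = np.clip(pmf, 0.0, None)
    tail = max(0.0, 1.0 - pmf.sum())
    probs = np.append(pmf, tail)
    obs = np.zeros(k_max + 2)
    for k, c in observed.items():
        obs[k] = c
    exp = probs * n

    obs_m, exp_m = _merge_bins(obs, exp, min_expected)
    if len(obs_m) < 2:
        raise ValueError("fewer than 2 bins remain after merging; test degenerate")
    # renormalize tiny truncation slack so totals match exactly
    exp_m = exp_m * (obs_m.sum() / exp_m.sum())
    stat = float(np.sum((obs_m - exp_m) ** 2 / exp_m))
    dof = len(obs_m) - 1
    p = float(stats.chi2.sf(stat, dof))
    return GofResult(stat, dof, p, passed=p > alpha, alpha=alpha, n_samples=n)


def _merge_bins(obs: np.ndarray, exp: np.ndarray,
                min_expected: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge low-expectation bins from both tails toward the center."""
    o, e = list(obs), list(exp)
    while len(e) > 1 and e[-1] < min_expected:
        le, lo = e.pop(), o.pop()
        e[-1] += le
        o[-1] += lo
    while len(e) > 1 and e[0] < min_expected:
        fe, fo = e.pop(0), o.pop(0)
        e[0] += fe
        o[0] += fo
    return np.asarray(o), np.asarray(e)


def chi_square_counts(
    observed: dict, expected_probs: dict, n: int, alpha: float = 0.01,
    min_expected: float = 5.0,
) -> GofResult:
    """Chi-square over categorical outcomes (e.g., whole networks).

    ``observed`` maps outcome -> count, ``expected_probs`` outcome -> exact
    probability (summing to 1 over all possible outcomes).  Outcomes with
    expected count below ``min_expected`` are merged into one bin.
    """
    keys = list(expected_probs)
    obs = np.array([observed.get(k, 0) for k in keys], dtype=float)
    exp = np.array([expected_probs[k] * n for k in keys], dtype=float)
    big = exp >= min_expected
    obs_m = list(obs[big])
    exp_m = list(exp[big])
    if np.any(~big):
        obs_m.append(obs[~big].sum())
        exp_m.append(exp[~big].sum())
    obs_a, exp_a = np.asarray(obs_m), np.asarray(exp_m)
    if len(obs_a) < 2:
        raise ValueError("fewer than 2 bins; test degenerate")
    exp_a = exp_a * (obs_a.sum() / exp_a.sum())
    stat = float(np.sum((obs_a - exp_a) ** 2 / exp_a))
    dof = len(obs_a) - 1
    p = float(stats.chi2.sf(stat, dof))
    return GofResult(stat, dof, p, passed=p > alpha, alpha=alpha, n_samples=n)


def audit_constraints(edges: EdgeList, rule: RuleSpec) -> list[str]:
    """Audit an edge list against the hard constraints of its rule.

    Returns a list of human-readable violations; empty means the realization
    satisfies every exact constraint (autapse/multapse policy, exact
    degrees for fixed-degree rules, exact count for fixed total, handshake).
    """
    violations: list[str] = []
    c = rule.constraints
    model = DegreeModel.for_projection(rule, edges.source_pop, edges.target_pop)

    if model.same_pop and not c.allow_autapses:
        auto = edges.sources == edges.targets
        for s in np.unique(edges.sources[auto]):
            violations.append(f"autapse ({s}, {s}) present but autapses are disallowed")
    if not c.allow_multapses:
        pair_counts = Counter(edges.pairs())
        for (s, t), m in pair_counts.items():
            if m > 1:
                violations.append(f"multapse: pair ({s}, {t}) occurs {m} times "
                                  "but multapses are disallowed")
    indeg = degree_counts(edges, "in")
    outdeg = degree_counts(edges, "out")
    if indeg.sum() != len(edges) or outdeg.sum() != len(edges):
        violations.append("handshake identity violated")  # pragma: no cover

    if rule.variant == "fixed_total" and len(edges) != rule.n_syn:
        violations.append(f"edge count {len(edges)} != N_syn={rule.n_syn}")
    if rule.variant == "fixed_in":
        bad = np.nonzero(indeg != rule.k_in)[0]
        for i in bad:
            violations.append(f"target {i + edges.target_pop.offset} has in-degree "
                              f"{indeg[i]} != K_in={rule.k_in}")
    if rule.variant == "fixed_out":
        bad = np.nonzero(outdeg != rule.k_out)[0]
        for i in bad:
            violations.append(f"source {i + edges.source_pop.offset} has out-degree "
                              f"{outdeg[i]} != K_out={rule.k_out}")
    return violations
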