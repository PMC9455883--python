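"""End-to-end statistical self-validation of the connectivity generators.

Each check here compares a sampled ensemble against an exact analytic
oracle from :mod:`conngen.analytics`:

- *network-level*: the empirical distribution over whole (multi)sets of
  edges at tiny sizes versus the exactly enumerated rule measure;
- *marginal-level*: pooled in-/out-degree histograms versus the closed-form
  marginals over a parameter grid;
- *constraint audits*: exact properties (no autapse/multapse, exact degrees
  and totals) that must hold on every realization;
- *law-of-large-numbers*: the mean edge count of the Bernoulli rule;
- *spatial*: distance-binned connection frequency versus the generating
  profile on a torus;
- *patchy* and *balanced-network* checks for the two worked examples.

Chi-square verdicts use alpha = 0.01 per comparison.  Because a correct
sampler still fails one comparison in a hundred by construction, each
chi-square check that fails is repeated once on an independent substream
and only a double failure counts: the false-failure probability per
comparison drops to 1e-4 while a genuinely wrong sampler still fails with
probability ~1 (standard practice for seeded ensemble tests of random
connection generators).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .analytics import DegreeModel, enumerate_networks, indegree_pmf, outdegree_pmf
from .core import Constraints, Population, degree_counts, derive_rng
from .probabilistic import RuleSpec, generate
from .spatial import (Profile, Space, connect_spatial_bernoulli, displacement,
                      eval_profile, mean_degree_vs_distance, place_uniform)
from .validation import (audit_constraints, chi_square_counts,
                         empirical_degree_distribution, gof_chi_square)

__all__ = [
    "oracle_equivalence_suite",
    "marginal_recovery_suite",
    "constraint_audit_suite",
    "expected_count_check",
    "spatial_profile_check",
    "patchy_audit",
    "brunel_contrast",
]

ALPHA = 0.01

_N = Constraints()
_M = Constraints(allow_multapses=True)
_A = Constraints(allow_autapses=True)
_AM = Constraints(allow_autapses=True, allow_multapses=True)


def _tiny_combos() -> list[tuple[RuleSpec, bool]]:
    """Every probabilistic rule variant with/without autapses and multapses
    on 2x2 projections (K and N_syn at most 2)."""
    combos: list[tuple[RuleSpec, bool]] = []
    for cons in (_N, _A):                      # Bernoulli cannot produce multapses
        combos.append((RuleSpec("pairwise_bernoulli", p=0.4, constraints=cons), True))
    combos.append((RuleSpec("pairwise_bernoulli", p=0.4), False))
    for cons in (_N, _M, _A, _AM):
        combos.append((RuleSpec("fixed_total", n_syn=2, constraints=cons), True))
        combos.append((RuleSpec("fixed_in", k_in=1, constraints=cons), True))
        combos.append((RuleSpec("fixed_out", k_out=1, constraints=cons), True))
    for cons in (_M, _AM):                     # K=2 needs replacement on a 2-pool
        combos.append((RuleSpec("fixed_in", k_in=2, constraints=cons), True))
        combos.append((RuleSpec("fixed_out", k_out=2, constraints=cons), True))
    combos.append((RuleSpec("fixed_total", n_syn=2, constraints=_M), False))
    combos.append((RuleSpec("fixed_in", k_in=2, constraints=_N), False))
    return combos


def _combo_id(rule: RuleSpec, same_pop: bool) -> str:
    c = rule.constraints
    par = rule.p or rule.n_syn or rule.k_in or rule.k_out
    return (f"{rule.variant}[{par}]-{'same' if same_pop else 'disjoint'}"
            f"-A{int(c.allow_autapses)}M{int(c.allow_multapses)}")


def oracle_equivalence_suite(seed: int, n_samples: int = 60_000) -> list[dict]:
    """Empirical network distribution vs. exact enumeration, all tiny combos."""
    results = []
    for k, (rule, same_pop) in enumerate(_tiny_combos()):
        if same_pop:
            src = tgt = Population("A", 2)
        else:
            src, tgt = Population("S", 2), Population("T", 2, offset=2)
        exact = enumerate_networks(DegreeModel(rule, 2, 2, same_pop=same_pop))
        # local-index canonical keys for the sampled networks
        off_t = tgt.offset

        def draw_counts(rng: np.random.Generator, n: int) -> Counter:
            counts: Counter = Counter()
            for _ in range(n):
                el = generate(rule, src, tgt, rng)
                counts[tuple(sorted(zip(el.sources.tolist(),
                                        (el.targets - off_t).tolist())))] += 1
            return counts

        if len(exact) < 2:
            # a forced outcome: every sample must be the unique network
            counts = draw_counts(derive_rng(seed, stream=100 + 2 * k), 200)
            ok = set(counts) == set(exact)
            results.append({"combo": _combo_id(rule, same_pop),
                            "p_value": 1.0 if ok else 0.0, "passed": ok,
                            "retried": False, "n_networks": len(exact)})
            continue

        def draw(rng: np.random.Generator):
            return chi_square_counts(draw_counts(rng, n_samples), exact,
                                     n_samples, alpha=ALPHA)

        res = draw(derive_rng(seed, stream=100 + 2 * k))
        retried = False
        if not res.passed:
            res = draw(derive_rng(seed, stream=101 + 2 * k))
            retried = True
        results.append({"combo": _combo_id(rule, same_pop),
                        "p_value": res.p_value, "passed": res.passed,
                        "retried": retried, "n_networks": len(exact)})
    return results


def _marginal_grid() -> list[tuple[RuleSpec, int, int]]:
    grid: list[tuple[RuleSpec, int, int]] = []
    for p in (0.05, 0.1, 0.5):
        grid.append((RuleSpec("pairwise_bernoulli", p=p), 50, 40))
    for cons in (_N, _M):
        grid.append((RuleSpec("fixed_total", n_syn=100, constraints=cons), 50, 40))
    for k in (1, 4):
        for cons in (_N, _M):
            grid.append((RuleSpec("fixed_in", k_in=k, constraints=cons), 50, 40))
            grid.append((RuleSpec("fixed_out", k_out=k, constraints=cons), 40, 50))
    return grid


def marginal_recovery_suite(seed: int, realizations: int = 200) -> list[dict]:
    """Pooled degree histograms vs. the closed-form marginals."""
    results = []
    for k, (rule, n_s, n_t) in enumerate(_marginal_grid()):
        src = Population("S", n_s)
        tgt = Population("T", n_t, offset=n_s)
        model = DegreeModel.for_projection(rule, src, tgt)

        def run(rng: np.random.Generator):
            ens = [generate(rule, src, tgt, rng) for _ in range(realizations)]
            out = {}
            for direction, pmf in (("in", indegree_pmf), ("out", outdegree_pmf)):
                # fixed degrees are point masses: check exactly, not by chi-square
                if (rule.variant, direction) in (("fixed_in", "in"),
                                                 ("fixed_out", "out")):
                    hist = empirical_degree_distribution(ens, direction)
                    want = rule.k_in if rule.variant == "fixed_in" else rule.k_out
                    ok = set(hist) == {want}
                    out[direction] = {"p_value": 1.0 if ok else 0.0, "passed": ok}
                else:
                    hist = empirical_degree_distribution(ens, direction)
                    res = gof_chi_square(hist, lambda kk: pmf(model, kk), alpha=ALPHA)
                    out[direction] = {"p_value": res.p_value, "passed": res.passed}
            return out

        out = run(derive_rng(seed, stream=300 + 2 * k))
        retried = False
        if not all(v["passed"] for v in out.values()):
            out = run(derive_rng(seed, stream=301 + 2 * k))
            retried = True
        results.append({"combo": _combo_id(rule, False), "retried": retried, **out})
    return results


def constraint_audit_suite(seed: int, realizations: int = 100) -> dict:
    """Exact-constraint audits across seeded realizations of every variant.

    Checks autapse/multapse policy, exact degrees and totals, and the
    handshake identity on every realization; returns the total violation
    count (must be zero).
    """
    rules = [RuleSpec("pairwise_bernoulli", p=0.3, constraints=c)
             for c in (_N, _A)]
    for c in (_N, _M, _A, _AM):
        rules.append(RuleSpec("fixed_total", n_syn=40, constraints=c))
        rules.append(RuleSpec("fixed_in", k_in=3, constraints=c))
        rules.append(RuleSpec("fixed_out", k_out=3, constraints=c))
    violations = 0
    checked = 0
    for k, rule in enumerate(rules):
        for same_pop in (False, True):
            if same_pop:
                src = tgt = Population("A", 12)
            else:
                src, tgt = Population("S", 12), Population("T", 12, offset=12)
            rng = derive_rng(seed, stream=400 + k)
            for _ in range(realizations):
                el = generate(rule, src, tgt, rng)
                report = audit_constraints(el, rule)
                violations += len(report)
                # handshake identity
                if (degree_counts(el, "in").sum() != len(el)
                        or degree_counts(el, "out").sum() != len(el)):
                    violations += 1
                checked += 1
    return {"violations": violations, "realizations_checked": checked,
            "n_rules": len(rules)}


def expected_count_check(seed: int, reps: int = 1000,
                         n_s: int = 30, n_t: int = 30, p: float = 0.1) -> dict:
    """Mean Bernoulli edge count vs. p*N_s*N_t, in standard-error units."""
    src = Population("S", n_s)
    tgt = Population("T", n_t, offset=n_s)
    rng = derive_rng(seed, stream=500)
    rule = RuleSpec("pairwise_bernoulli", p=p)
    sizes = np.array([len(generate(rule, src, tgt, rng)) for _ in range(reps)])
    m = n_s * n_t
    se = np.sqrt(m * p * (1 - p) / reps)
    z = abs(sizes.mean() - p * m) / se
    return {"mean_n_syn": float(sizes.mean()), "expected": p * m,
            "z": float(z), "n": reps}


def spatial_profile_check(seed: int, n: int = 2000, p0: float = 0.8,
                          sigma_frac: float = 0.1) -> dict:
    """Distance-binned connection frequency vs. the generating Gaussian
    profile on a periodic square; also verifies minimum-image distances."""
    space = Space(2, (1.0, 1.0), boundary="periodic")
    profile = Profile("gaussian", {"c": p0, "sigma": sigma_frac * 1.0})

    def run(stream: int) -> dict:
        rng = derive_rng(seed, stream=stream)
        pos = place_uniform(space, n, rng)
        pop = Population("N", n, positions=pos)
        el = connect_spatial_bernoulli(pop, pop, space, profile,
                                       Constraints(), rng)
        bins = np.linspace(0.0, 0.5, 26)
        res = mean_degree_vs_distance(el, space, bins)
        centers = (bins[:-1] + bins[1:]) / 2
        pred = np.atleast_1d(eval_profile(profile, centers))
        big = res["pair_count"] >= 100
        se = np.sqrt(pred * (1 - pred) / np.maximum(res["pair_count"], 1))
        dev = np.abs(res["frequency"] - pred) / np.where(se > 0, se, np.inf)
        max_dev = float(np.nanmax(dev[big]))
        # minimum-image check on random pairs
        idx = rng.integers(0, n, size=(500, 2))
        d = np.abs(displacement(space, pos[idx[:, 0]], pos[idx[:, 1]]))
        return {"max_dev_se": max_dev,
                "min_image_ok": bool(np.all(d <= 0.5 + 1e-12)),
                "n_edges": len(el), "n": n}

    out = run(600)
    if out["max_dev_se"] > 3.0:
        out = run(601)
        out["retried"] = True
    else:
        out["retried"] = False
    return out


def patchy_audit(seed: int, n_e: int = 1600, n_i: int = 400) -> dict:
    """Constraint and geometry audits of a seeded PB-model instance."""
    from .patchy import (PatchySpec, assign_groups, assign_patches,
                         build_pb_layout, connect_local, connect_patchy)
    from .spatial import distance

    spec = PatchySpec(n_e=n_e, n_i=n_i)
    rng = derive_rng(seed, stream=700)
    exc, inh, space = build_pb_layout(spec, rng)
    gid, centers = assign_groups(spec, exc.positions)
    patches = assign_patches(spec, centers, rng)
    el_loc, q_loc = connect_local(exc, exc, spec, rng)
    el_p, q_p, chosen = connect_patchy(exc, exc, spec, gid, patches, rng)

    violations = 0
    # quotas met exactly
    violations += int(np.sum(degree_counts(el_loc, "out") != q_loc))
    violations += int(np.sum(degree_counts(el_p, "out") != q_p))
    # no autapses / multapses in either system
    for el in (el_loc, el_p):
        pairs = el.pairs()
        violations += len(pairs) - len(set(pairs))
        violations += sum(1 for s, t in pairs if s == t)
    # every patchy edge within rp of a chosen patch of its source
    geometry_bad = 0
    for s, t in el_p.pairs():
        cen = chosen[s]
        d = distance(space, cen, np.broadcast_to(exc.positions[t], cen.shape))
        if np.min(d) > spec.rp + 1e-12:
            geometry_bad += 1
    density = (len(el_loc) + len(el_p)) / (exc.size * (exc.size - 1))
    return {"violations": violations, "patch_geometry_violations": geometry_bad,
            "density": float(density), "c_total": spec.c_total,
            "n_local": len(el_loc), "n_patchy": len(el_p), "n": n_e + n_i}


def brunel_contrast(seeds=range(5), scale: float = 0.2,
                    duration: float = 1000.0) -> dict:
    """Paired fixed-in/fixed-out runs: edge conservation and rate contrast."""
    from .brunel import run_demo

    per_seed = []
    for s in seeds:
        net_in, _, st_in = run_demo("fixed_in", scale, duration, seed=int(s))
        net_out, _, st_out = run_demo("fixed_out", scale, duration, seed=int(s))
        per_seed.append({
            "seed": int(s),
            "edge_diff": net_in.n_syn_total - net_out.n_syn_total,
            "mean_in": st_in["mean_rate"], "mean_out": st_out["mean_rate"],
            "sd_in": st_in["sd_rate"], "sd_out": st_out["sd_rate"],
        })
    rel = [abs(r["mean_out"] - r["mean_in"]) / r["mean_in"] for r in per_seed]
    return {
        "per_seed": per_seed,
        "edge_diff_max": max(abs(r["edge_diff"]) for r in per_seed),
        "sd_ordering_holds_all_seeds": all(r["sd_out"] > r["sd_in"]
                                           for r in per_seed),
        "sd_ratio_min": min(r["sd_out"] / r["sd_in"] for r in per_seed),
        "mean_rel_diff_max": max(rel),
        "n": int(2500 * scale * 5),
    }
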