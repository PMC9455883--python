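"""Metric spaces, layouts, profiles, and distance-modulated connectivity."""

import numpy as np
import pytest
from scipy import stats

from conngen import (Constraints, Population, Profile, Space,
                     connect_pairwise_bernoulli, connect_spatial_bernoulli,
                     degree_counts, derive_rng, distance, eval_profile,
                     mean_degree_vs_distance, place_grid, place_uniform)
from conngen.spatial import displacement


class TestSpace:
    def test_validation(self):
        with pytest.raises(ValueError):
            Space(4)
        with pytest.raises(ValueError):
            Space(2, (1.0, -1.0))
        with pytest.raises(ValueError):
            Space(2, metric="manhattan")
        s = Space(2, (2.0, 3.0))
        assert s.extent == (2.0, 3.0)

    def test_scalar_extent_broadcasts(self):
        assert Space(3, 2.0).extent == (2.0, 2.0, 2.0)


class TestDistance:
    def test_minimum_image_1d(self):
        s = Space(1, (10.0,), boundary="periodic")
        assert distance(s, [1.0], [9.0]) == pytest.approx(2.0)
        assert distance(s, [1.0], [1.0]) == 0.0

    def test_open_boundary_no_wrap(self):
        s = Space(1, (10.0,), boundary="open")
        assert distance(s, [1.0], [9.0]) == pytest.approx(8.0)

    def test_metrics_on_displacement(self):
        # displacement (1, 3): l-infinity gives 3, Euclidean sqrt(10)
        s_inf = Space(2, (100.0, 100.0), metric="maxnorm")
        s_l2 = Space(2, (100.0, 100.0), metric="euclidean")
        assert distance(s_inf, [0, 0], [1, 3]) == pytest.approx(3.0)
        assert distance(s_l2, [0, 0], [1, 3]) == pytest.approx(np.sqrt(10))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            distance(Space(2, (1.0, 1.0)), [0.0], [0.5])

    def test_minimum_image_bounded_by_half_extent(self, rng):
        s = Space(2, (4.0, 6.0), boundary="periodic")
        x = rng.uniform(0, 1, (200, 2)) * s.lengths
        y = rng.uniform(0, 1, (200, 2)) * s.lengths
        d = np.abs(displacement(s, x, y))
        assert np.all(d <= s.lengths / 2 + 1e-12)


class TestPlacement:
    def test_uniform_in_extent_and_reproducible(self):
        s = Space(2, (3.0, 3.0))
        a = place_uniform(s, 50, derive_rng(5))
        b = place_uniform(s, 50, derive_rng(5))
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a < 3.0))

    def test_uniform_mean_is_half_extent(self):
        s = Space(2, (2.0, 2.0))
        pos = place_uniform(s, 10_000, derive_rng(6))
        se = 2.0 / np.sqrt(12 * 10_000)
        assert np.all(np.abs(pos.mean(axis=0) - 1.0) < 4 * se)

    def test_grid_exact_without_jitter(self):
        s = Space(2, (2.0, 2.0))
        pos = place_grid(s, 4, jitter=0.0, rng=derive_rng(1))
        expect = {(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)}
        assert {tuple(p) for p in pos} == expect

    def test_grid_full_jitter_stays_wrapped(self):
        s = Space(2, (2.0, 2.0), boundary="periodic")
        pos = place_grid(s, 16, jitter=0.5, rng=derive_rng(2))
        assert np.all((pos >= 0) & (pos < 2.0))

    def test_grid_shape_requirements(self):
        s = Space(2, (1.0, 1.0))
        with pytest.raises(ValueError, match="perfect"):
            place_grid(s, 5, rng=derive_rng(0))
        pos = place_grid(s, 6, rng=derive_rng(0), shape=(2, 3))
        assert pos.shape == (6, 2)
        with pytest.raises(ValueError, match="jitter"):
            place_grid(s, 4, jitter=2.0, rng=derive_rng(0))

    def test_jitter_is_uniform(self):
        s = Space(1, (100.0,))
        pos = place_grid(s, 100, jitter=0.7, rng=derive_rng(3))
        offsets = pos - np.floor(pos)
        # pooled offsets across many draws
        all_off = np.concatenate([
            (place_grid(s, 100, jitter=0.7, rng=derive_rng(100 + i))
             - np.arange(100)[:, None]).ravel()
            for i in range(100)])
        ks = stats.kstest(all_off, stats.uniform(0, 0.7).cdf)
        assert ks.pvalue > 0.01


class TestProfiles:
    def test_gaussian_peak(self):
        p = Profile("gaussian", {"c": 0.8, "sigma": 1.0})
        assert eval_profile(p, 0.0) == pytest.approx(0.8)

    def test_boxcar_outside_support(self):
        p = Profile("boxcar", {"c": 0.5, "r_max": 2.0})
        assert eval_profile(p, 3.0) == 0.0
        assert eval_profile(p, 1.0) == pytest.approx(0.5)

    def test_exponential_value(self):
        p = Profile("exponential", {"c1": 1.0, "c2": 2.0})
        assert eval_profile(p, 2.0) == pytest.approx(np.exp(-1.0))

    def test_linear_and_sigmoidal(self):
        lin = Profile("linear", {"c1": 1.0, "c2": 0.5})
        assert eval_profile(lin, 1.0) == pytest.approx(0.5)
        assert eval_profile(lin, 3.0) == 0.0
        sig = Profile("sigmoidal", {"c1": 1.0, "c2": 0.5})
        assert eval_profile(sig, 1.0) == pytest.approx(0.5)

    def test_clamping(self):
        lin = Profile("linear", {"c1": 2.0, "c2": 1.0})
        assert eval_profile(lin, 0.0) == 1.0  # clamped from 2.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            Profile("gaussian", {"sigma": -1.0})
        with pytest.raises(ValueError):
            Profile("exponential", {"c1": 1.0, "c2": 0.0})
        with pytest.raises(ValueError):
            Profile("klingon", {})

    def test_anisotropic_gaussian(self):
        p = Profile("gaussian_anisotropic",
                    {"c": 0.9, "mu": [0.0, 0.0], "Sigma": [[0.04, 0], [0, 0.04]]})
        assert eval_profile(p, 0.0, displacement=np.array([0.0, 0.0])) == \
            pytest.approx(0.9)
        iso = Profile("gaussian", {"c": 0.9, "sigma": 0.2})
        d = np.array([0.1, 0.05])
        assert eval_profile(p, 0.0, displacement=d) == \
            pytest.approx(eval_profile(iso, float(np.linalg.norm(d))))


def _positioned_pop(name, n, space, seed, offset=0):
    pos = place_uniform(space, n, derive_rng(seed))
    from conngen.core import Role
    return Population(name, n, offset=offset, positions=pos)


class TestSpatialBernoulli:
    def test_profile_one_gives_all_to_all(self):
        space = Space(2, (1.0, 1.0))
        s = _positioned_pop("S", 6, space, 1)
        t = _positioned_pop("T", 5, space, 2, offset=6)
        el = connect_spatial_bernoulli(s, t, space,
                                       Profile("boxcar", {"c": 1.0, "r_max": 10.0}),
                                       rng=derive_rng(3))
        assert len(el) == 30

    def test_deterministic_boxcar_exact(self):
        space = Space(2, (1.0, 1.0))
        s = _positioned_pop("S", 40, space, 4)
        t = _positioned_pop("T", 40, space, 5, offset=40)
        r_max = 0.2
        el = connect_spatial_bernoulli(
            s, t, space, Profile("boxcar_deterministic", {"r_max": r_max}),
            rng=derive_rng(6))
        got = set(el.pairs())
        for i in range(40):
            for j in range(40):
                d = distance(space, s.positions[i], t.positions[j])
                assert ((i, j + 40) in got) == (d <= r_max)

    def test_missing_positions_rejected(self):
        space = Space(2, (1.0, 1.0))
        s = Population("S", 3)
        t = _positioned_pop("T", 3, space, 1, offset=3)
        with pytest.raises(ValueError, match="positions"):
            connect_spatial_bernoulli(s, t, space,
                                      Profile("gaussian", {"c": 0.5, "sigma": 0.1}))

    def test_constant_profile_equals_pairwise_bernoulli(self):
        """A flat profile is distributionally a plain Bernoulli rule."""
        space = Space(2, (1.0, 1.0))
        s = _positioned_pop("S", 30, space, 7)
        t = _positioned_pop("T", 30, space, 8, offset=30)
        rng_a, rng_b = derive_rng(9), derive_rng(10)
        deg_a, deg_b = [], []
        flat = Profile("boxcar", {"c": 0.3, "r_max": 10.0})
        for _ in range(100):
            deg_a.extend(degree_counts(
                connect_spatial_bernoulli(s, t, space, flat, rng=rng_a), "in"))
            deg_b.extend(degree_counts(
                connect_pairwise_bernoulli(s, t, 0.3, rng=rng_b), "in"))
        table = np.array([np.bincount(deg_a, minlength=31),
                          np.bincount(deg_b, minlength=31)])
        table = table[:, table.sum(axis=0) >= 10]
        chi2 = stats.chi2_contingency(table)
        assert chi2.pvalue > 0.01

    def test_no_autapses_when_requested(self):
        space = Space(2, (1.0, 1.0))
        a = _positioned_pop("A", 25, space, 11)
        el = connect_spatial_bernoulli(
            a, a, space, Profile("boxcar", {"c": 1.0, "r_max": 10.0}),
            Constraints(allow_autapses=False), rng=derive_rng(12))
        assert len(el) == 25 * 24
        assert all(s != t for s, t in el.pairs())


class TestMeanDegreeVsDistance:
    def test_all_to_all_frequency_one(self):
        space = Space(2, (1.0, 1.0))
        s = _positioned_pop("S", 15, space, 13)
        t = _positioned_pop("T", 15, space, 14, offset=15)
        el = connect_spatial_bernoulli(
            s, t, space, Profile("boxcar", {"c": 1.0, "r_max": 10.0}),
            rng=derive_rng(15))
        res = mean_degree_vs_distance(el, space, np.linspace(0, 0.8, 9))
        nonempty = res["pair_count"] > 0
        assert np.all(res["frequency"][nonempty] == 1.0)

    def test_empty_edgelist_zero_frequency(self):
        from conngen import EdgeList
        space = Space(2, (1.0, 1.0))
        s = _positioned_pop("S", 10, space, 16)
        t = _positioned_pop("T", 10, space, 17, offset=10)
        el = EdgeList([], [], s, t)
        res = mean_degree_vs_distance(el, space, np.linspace(0, 0.8, 9))
        nonempty = res["pair_count"] > 0
        assert np.all(res["frequency"][nonempty] == 0.0)
        # empty bins are reported as missing (NaN), not zero
        if np.any(~nonempty):
            assert np.all(np.isnan(res["frequency"][~nonempty]))

    def test_gaussian_profile_recovered(self):
        space = Space(2, (1.0, 1.0))
        pop = _positioned_pop("N", 800, space, 18)
        prof = Profile("gaussian", {"c": 0.8, "sigma": 0.1})
        el = connect_spatial_bernoulli(pop, pop, space, prof,
                                       Constraints(), rng=derive_rng(19))
        bins = np.linspace(0, 0.5, 21)
        res = mean_degree_vs_distance(el, space, bins)
        centers = (bins[:-1] + bins[1:]) / 2
        pred = eval_profile(prof, centers)
        big = res["pair_count"] >= 100
        se = np.sqrt(pred * (1 - pred) / np.maximum(res["pair_count"], 1))
        assert np.all(np.abs(res["frequency"][big] - pred[big]) <= 3 * se[big])
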