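"""PB model: layout, patch geometry, local and patchy connectivity."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from conngen import (PatchySpec, Population, assign_groups, assign_patches,
                     build_pb_layout, connect_local, connect_patchy,
                     degree_counts, derive_rng, distance)


@pytest.fixture(scope="module")
def small_spec():
    return PatchySpec(n_e=400, n_i=100, group_grid=2)


class TestLayout:
    def test_grid_exact_when_jitter_zero(self):
        spec = PatchySpec(n_e=50, n_i=4, L=2.0, jitter=0.0)
        _, inh, _ = build_pb_layout(spec, derive_rng(1))
        assert {tuple(p) for p in inh.positions} == \
            {(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)}

    def test_positions_inside_domain(self, small_spec):
        exc, inh, _ = build_pb_layout(small_spec, derive_rng(2))
        for pop in (exc, inh):
            assert np.all((pop.positions >= 0) & (pop.positions < small_spec.L))

    def test_excitatory_positions_uniform(self):
        spec = PatchySpec(n_e=10_000, n_i=4)
        exc, _, _ = build_pb_layout(spec, derive_rng(3))
        for axis in range(2):
            ks = stats.kstest(exc.positions[:, axis],
                              stats.uniform(0, spec.L).cdf)
            assert ks.pvalue > 0.01

    def test_inhibitory_grid_constant(self):
        spec = PatchySpec(n_e=10, n_i=25, L=1.0, jitter=0.0)
        _, inh, _ = build_pb_layout(spec, derive_rng(4))
        xs = np.unique(inh.positions[:, 0])
        assert np.allclose(np.diff(xs), 1.0 / 5)  # Delta = L / sqrt(N_I)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PatchySpec(c_loc=0.5, c_total=0.1)
        with pytest.raises(ValueError):
            PatchySpec(np_min=0)
        with pytest.raises(ValueError):
            PatchySpec(rp=-1.0)


class TestGroupsAndPatches:
    def test_group_membership_by_containing_square(self):
        spec = PatchySpec(group_grid=2, L=1.0)
        pos = np.array([[0.1, 0.1], [0.9, 0.1], [0.1, 0.9], [0.6, 0.7]])
        gid, centers = assign_groups(spec, pos)
        assert gid.tolist() == [0, 2, 1, 3]
        assert centers.shape == (4, 2)
        assert tuple(centers[0]) == (0.25, 0.25)

    def test_exact_patch_count_when_bounds_equal(self):
        spec = PatchySpec(np_min=3, np_max=3)
        patches = assign_patches(spec, np.array([[0.5, 0.5]]), derive_rng(5))
        assert len(patches) == 1 and patches[0].shape == (3, 2)

    def test_degenerate_distance_draw(self):
        """With dp_sd -> 0 every patch sits at distance dp_mean from the center."""
        spec = PatchySpec(dp_mean=0.3, dp_sd=1e-12, np_min=4, np_max=4)
        space = spec.space()
        centers = assign_patches(spec, np.array([[0.5, 0.5]]), derive_rng(6))[0]
        for c in centers:
            assert distance(space, [0.5, 0.5], c) == pytest.approx(0.3, abs=1e-9)

    def test_angles_uniform(self):
        spec = PatchySpec(np_min=1, np_max=1, dp_mean=0.2, dp_sd=1e-12)
        rng = derive_rng(7)
        angles = []
        for _ in range(10_000):
            c = assign_patches(spec, np.array([[0.5, 0.5]]), rng)[0][0]
            angles.append(np.arctan2(c[1] - 0.5, c[0] - 0.5) % (2 * np.pi))
        counts, _ = np.histogram(angles, bins=16, range=(0, 2 * np.pi))
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01


class TestConnectLocal:
    def test_zero_density_empty(self, small_spec):
        spec = PatchySpec(n_e=100, n_i=4, c_loc=0.0, c_total=0.01)
        exc, _, _ = build_pb_layout(spec, derive_rng(8))
        el, quotas = connect_local(exc, exc, spec, derive_rng(9))
        assert len(el) == 0 and quotas.sum() == 0

    def test_quotas_met_exactly_no_autapse_no_multapse(self, small_spec):
        exc, _, _ = build_pb_layout(small_spec, derive_rng(10))
        el, quotas = connect_local(exc, exc, small_spec, derive_rng(11))
        assert np.array_equal(degree_counts(el, "out"), quotas)
        pairs = el.pairs()
        assert len(set(pairs)) == len(pairs)
        assert all(s != t for s, t in pairs)

    def test_distance_histogram_follows_weighted_pair_density(self):
        """Accepted-edge distances ~ pair-distance density times the profile
        (valid when the quota is far below the footprint capacity)."""
        spec = PatchySpec(n_e=800, n_i=4, c_loc=0.004, c_total=0.006)
        exc, _, _ = build_pb_layout(spec, derive_rng(12))
        space = spec.space()
        el, _ = connect_local(exc, exc, spec, derive_rng(13))
        xs = exc.positions[el.sources]
        ys = exc.positions[el.targets]
        d_edges = distance(space, xs, ys)

        # expected density: all-pair distances weighted by the profile
        from conngen import Profile, eval_profile
        prof = Profile("gaussian", {"c": spec.p0, "sigma": spec.sigma * spec.L})
        diffs = distance(space, exc.positions[:, None, :],
                         exc.positions[None, :, :])
        iu = ~np.eye(exc.size, dtype=bool)
        weights = eval_profile(prof, diffs[iu])
        bins = np.linspace(0, 0.5, 21)
        expected, _ = np.histogram(diffs[iu], bins=bins, weights=weights)
        expected = expected / expected.sum()
        observed, _ = np.histogram(d_edges, bins=bins)
        observed = observed / observed.sum()
        assert np.abs(observed - expected).sum() / 2 < 0.05  # total variation


class TestConnectPatchy:
    def test_quota_and_geometry_audit(self, small_spec):
        exc, _, _ = build_pb_layout(small_spec, derive_rng(14))
        gid, centers = assign_groups(small_spec, exc.positions)
        patches = assign_patches(small_spec, centers, derive_rng(15))
        el, quotas, chosen = connect_patchy(exc, exc, small_spec, gid, patches,
                                            derive_rng(16))
        space = small_spec.space()
        assert np.array_equal(degree_counts(el, "out"), quotas)
        pairs = el.pairs()
        assert len(set(pairs)) == len(pairs)
        assert all(s != t for s, t in pairs)
        # every edge's target lies within rp of a chosen patch of its source
        for s, t in pairs:
            d = distance(space, chosen[s],
                         np.broadcast_to(exc.positions[t], chosen[s].shape))
            assert np.min(d) <= small_spec.rp + 1e-12

    def test_zero_patches_means_no_edges(self):
        spec = PatchySpec(n_e=100, n_i=4, n_npn=1, p_npn=0.0)
        exc, _, _ = build_pb_layout(spec, derive_rng(17))
        gid, centers = assign_groups(spec, exc.positions)
        patches = assign_patches(spec, centers, derive_rng(18))
        el, quotas, _ = connect_patchy(exc, exc, spec, gid, patches, derive_rng(19))
        assert len(el) == 0 and quotas.sum() == 0

    def test_targets_are_uniform_k_subsets(self):
        """With one patch holding m=4 targets and quota k=2, the chosen pair
        is uniform over the C(4,2)=6 subsets (conditioning on quota 2)."""
        spec = PatchySpec(n_e=1, n_i=4, group_grid=1, np_min=1, np_max=1,
                          n_npn=1, p_npn=1.0, dp_mean=1e-6, dp_sd=1e-12,
                          rp=0.45, c_loc=0.0, c_total=0.5)
        source = Population("S", 1, positions=np.array([[0.5, 0.5]]))
        tgt_pos = np.array([[0.4, 0.4], [0.6, 0.4], [0.4, 0.6], [0.6, 0.6]])
        target = Population("T", 4, offset=1, positions=tgt_pos)
        gid = np.array([0])
        rng = derive_rng(20)
        counts = Counter()
        for _ in range(6000):
            patches = assign_patches(spec, np.array([[0.5, 0.5]]), rng)
            el, quotas, _ = connect_patchy(source, target, spec, gid, patches, rng)
            if quotas[0] == 2:
                counts[tuple(sorted(el.targets.tolist()))] += 1
        assert len(counts) == 6
        res = stats.chisquare(list(counts.values()))
        assert res.pvalue > 0.01


def test_overall_density_close_to_c_total():
    spec = PatchySpec(n_e=800, n_i=4)
    exc, _, _ = build_pb_layout(spec, derive_rng(21))
    gid, centers = assign_groups(spec, exc.positions)
    patches = assign_patches(spec, centers, derive_rng(22))
    el_loc, _ = connect_local(exc, exc, spec, derive_rng(23))
    el_p, _, _ = connect_patchy(exc, exc, spec, gid, patches, derive_rng(24))
    density = (len(el_loc) + len(el_p)) / (exc.size * (exc.size - 1))
    assert density == pytest.approx(spec.c_total, rel=0.15)
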