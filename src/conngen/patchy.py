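"""Patchy long-range cortical connectivity (the "PB model").

A two-dimensional network on a periodic square combines two connection
systems observed in cortex: isotropic *local* connectivity, in which nearby
cells are more likely to be connected (Gaussian footprint), and *non-local
patchy* connectivity, in which groups of neighboring neurons project to a
shared set of disk-shaped distant regions ("patches") where axons form
clustered synapses.

Excitatory neurons are placed uniformly at random; inhibitory neurons on a
jittered grid with grid constant ``Delta = L / sqrt(N_I)``.  The space is
tiled into a square grid of group regions; each group draws its number of
patches ``Np`` uniformly from ``{Np_min..Np_max}`` and places each patch at
distance ``dp ~ Normal(dp_mean, dp_sd)`` (redrawn if non-positive) and angle
``phi ~ U[0, 2*pi)`` from the group center, wrapped periodically.  Each
neuron projects to ``Npn ~ Binomial(n_Npn, p_Npn)`` of its group's patches
(values above ``Np`` redrawn), and its quota of patchy synapses falls
uniformly on the targets within patch radius ``rp``.  Local out-degree
quotas are binomial with mean ``c_loc * (N - 1)``; candidate local edges are
accepted with the Gaussian profile probability until the quota is met.
Multapses and autapses are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EdgeList, Population, Role, logger, same_population
from .spatial import Profile, Space, distance, eval_profile, place_grid, place_uniform

__all__ = [
    "PatchySpec",
    "build_pb_layout",
    "assign_groups",
    "assign_patches",
    "connect_local",
    "connect_patchy",
]


@dataclass(frozen=True)
class PatchySpec:
    """Parameters of the PB model (lengths in units of the side length L).

    ``c_total`` is the overall connection density (realized connections over
    possible connections) and splits into a local part ``c_loc`` and a
    non-local, patchy part ``c_total - c_loc``.
    """

    L: float = 1.0
    n_e: int = 1600
    n_i: int = 400
    jitter: float = 0.0125          # inhibitory grid jitter bound J
    c_total: float = 0.03
    c_loc: float = 0.02
    p0: float = 0.8                 # peak of the local Gaussian profile
    sigma: float = 0.1              # local footprint (space constant)
    np_min: int = 2                 # patches per group, uniform {np_min..np_max}
    np_max: int = 4
    n_npn: int = 4                  # patches per neuron ~ B(n_npn, p_npn), <= Np
    p_npn: float = 0.5
    rp: float = 0.1                 # patch radius
    dp_mean: float = 0.3            # group-center-to-patch distance ~ N(mean, sd)
    dp_sd: float = 0.05
    group_grid: int = 4             # groups per dimension
    max_attempts: int = 10_000      # rejection-sampling cap per source

    def __post_init__(self) -> None:
        if not (0 <= self.c_loc <= self.c_total <= 1):
            raise ValueError("need 0 <= c_loc <= c_total <= 1")
        if self.np_min > self.np_max or self.np_min < 1:
            raise ValueError("need 1 <= Np_min <= Np_max")
        if self.rp <= 0 or self.dp_mean <= 0:
            raise ValueError("rp and dp_mean must be > 0")
        if self.sigma <= 0 or not (0 < self.p0 <= 1):
            raise ValueError("need sigma > 0 and 0 < p0 <= 1")

    @property
    def c_nonloc(self) -> float:
        return self.c_total - self.c_loc

    def space(self) -> Space:
        return Space(dimension=2, extent=(self.L, self.L),
                     metric="euclidean", boundary="periodic")


def build_pb_layout(
    spec: PatchySpec,
    rng: np.random.Generator,
) -> tuple[Population, Population, Space]:
    """Place the excitatory and inhibitory populations in the periodic square.

    Excitatory positions are i.i.d. uniform on [0, L)^2; inhibitory
    positions sit on a jittered grid with grid constant
    ``Delta = L / sqrt(N_I)`` (``N_I`` must be a perfect square unless an
    explicit shape is used via :func:`conngen.spatial.place_grid`).
    """
    space = spec.space()
    pos_e = place_uniform(space, spec.n_e, rng)
    pos_i = place_grid(space, spec.n_i, jitter=spec.jitter, rng=rng)
    exc = Population("E", spec.n_e, offset=0, role=Role.excitatory, positions=pos_e)
    inh = Population("I", spec.n_i, offset=spec.n_e, role=Role.inhibitory,
                     positions=pos_i)
    return exc, inh, space


def assign_groups(spec: PatchySpec,
                  positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group membership by containing square of the group tiling.

    Returns ``(group_id per node, group_centers)`` for the
    ``group_grid x group_grid`` partition of the space.
    """
    g = spec.group_grid
    cell = spec.L / g
    ij = np.clip((positions // cell).astype(int), 0, g - 1)
    group_id = ij[:, 0] * g + ij[:, 1]
    centers = np.array([[(i + 0.5) * cell, (j + 0.5) * cell]
                        for i in range(g) for j in range(g)])
    return group_id, centers


def assign_patches(
    spec: PatchySpec,
    group_centers: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Draw the patch centers for every group.

    Per group: ``Np ~ U{Np_min..Np_max}`` patches, each at
    ``x_g + dp * (cos phi, sin phi)`` with ``dp ~ Normal(dp_mean, dp_sd)``
    (non-positive draws redrawn, logged) and ``phi ~ U[0, 2*pi)``, wrapped
    periodically.  Patch sets of different groups may overlap.
    """
    space = spec.space()
    out: list[np.ndarray] = []
    for x_g in np.atleast_2d(group_centers):
        n_p = int(rng.integers(spec.np_min, spec.np_max + 1))
        centers = np.empty((n_p, 2))
        for k in range(n_p):
            dp = rng.normal(spec.dp_mean, spec.dp_sd)
            while dp <= 0:
                logger.info("non-positive patch distance redrawn")
                dp = rng.normal(spec.dp_mean, spec.dp_sd)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            centers[k] = x_g + dp * np.array([np.cos(phi), np.sin(phi)])
        out.append(space.wrap(centers))
    return out


def connect_local(
    source: Population,
    target: Population,
    spec: PatchySpec,
    rng: np.random.Generator,
) -> tuple[EdgeList, np.ndarray]:
    """Local Gaussian-footprint connectivity with exact per-source quotas.

    Per source ``i`` an out-degree quota ``K_loc,i ~ Binomial(N_adm, c_loc)``
    (mean ``c_loc * N_adm``) is drawn first; random candidate targets are
    then accepted with probability ``p0 * exp(-r^2 / 2 sigma^2)`` until the
    quota is reached.  No autapses, no multapses.  Returns the edge list and
    the per-source quotas actually used (truncated to capacity with a
    warning if the footprint/density combination is infeasible).
    """
    space = spec.space()
    profile = Profile("gaussian", {"c": spec.p0, "sigma": spec.sigma * spec.L})
    identical = same_population(source, target)
    n_adm = target.size - (1 if identical else 0)
    quotas = rng.binomial(n_adm, spec.c_loc, size=source.size)

    src_out, tgt_out = [], []
    realized = np.zeros(source.size, dtype=np.int64)
    for i in range(source.size):
        k = int(quotas[i])
        if k == 0:
            continue
        chosen: set[int] = set()
        attempts = 0
        pos_i = source.positions[i]
        while len(chosen) < k and attempts < spec.max_attempts:
            batch = min(4 * (k - len(chosen)) + 32, spec.max_attempts - attempts)
            cand = rng.integers(0, target.size, size=batch)
            attempts += batch
            if identical:
                cand = cand[cand != i]
            r = distance(space, pos_i, target.positions[cand])
            acc = rng.random(cand.size) < eval_profile(profile, r)
            for j in cand[acc]:
                if len(chosen) < k:
                    chosen.add(int(j))
        if len(chosen) < k:
            logger.warning(
                "local quota %d for source %d truncated to %d after %d attempts "
                "(footprint/density combination near infeasible)",
                k, i, len(chosen), attempts)
            quotas[i] = len(chosen)
        realized[i] = len(chosen)
        src_out.extend([i + source.offset] * len(chosen))
        tgt_out.extend(sorted(j + target.offset for j in chosen))
    edges = EdgeList(np.asarray(src_out, dtype=np.int64),
                     np.asarray(tgt_out, dtype=np.int64), source, target)
    return edges, quotas


def connect_patchy(
    source: Population,
    target: Population,
    spec: PatchySpec,
    group_ids: np.ndarray,
    patches: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[EdgeList, np.ndarray, list[np.ndarray]]:
    """Non-local patchy connectivity.

    Per source neuron: draw ``Npn ~ Binomial(n_Npn, p_Npn)`` (redrawn while
    above the group's ``Np``), pick that many of the group's patches
    uniformly without replacement, and place a quota
    ``K_patch ~ Binomial(N_adm, c_nonloc)`` of edges as a uniform subset of
    the targets lying within ``rp`` (minimum-image) of the chosen patches.
    Quotas exceeding the available targets are truncated (logged); neurons
    whose patches contain no targets get zero edges (logged).  No autapses,
    no multapses.

    Returns ``(edges, quotas used, chosen patch centers per source)``.
    """
    space = spec.space()
    identical = same_population(source, target)
    n_adm = target.size - (1 if identical else 0)
    quotas = rng.binomial(n_adm, spec.c_nonloc, size=source.size)

    # targets within rp of each patch, precomputed per group
    members_per_group: list[list[np.ndarray]] = []
    for centers in patches:
        members = []
        for c in centers:
            r = distance(space, c, target.positions)
            members.append(np.nonzero(r <= spec.rp)[0])
        members_per_group.append(members)

    src_out: list[int] = []
    tgt_out: list[int] = []
    chosen_centers: list[np.ndarray] = []
    for i in range(source.size):
        g = int(group_ids[i])
        n_p = len(patches[g])
        npn = int(rng.binomial(spec.n_npn, spec.p_npn))
        while npn > n_p:
            logger.info("Npn draw above Np redrawn")
            npn = int(rng.binomial(spec.n_npn, spec.p_npn))
        if npn == 0 or quotas[i] == 0:
            quotas[i] = 0
            chosen_centers.append(np.empty((0, 2)))
            continue
        which = rng.choice(n_p, size=npn, replace=False)
        chosen_centers.append(patches[g][which])
        cands = np.unique(np.concatenate([members_per_group[g][w] for w in which]))
        if identical:
            cands = cands[cands != i]
        if cands.size == 0:
            logger.warning("source %d has no admissible targets in its patches", i)
            quotas[i] = 0
            continue
        k = int(quotas[i])
        if k > cands.size:
            logger.warning("patchy quota %d for source %d truncated to %d",
                           k, i, cands.size)
            k = cands.size
            quotas[i] = k
        sel = rng.choice(cands.size, size=k, replace=False)
        src_out.extend([i + source.offset] * k)
        tgt_out.extend(sorted(int(cands[s]) + target.offset for s in sel))
    edges = EdgeList(np.asarray(src_out, dtype=np.int64),
                     np.asarray(tgt_out, dtype=np.int64), source, target)
    return edges, quotas, chosen_centers
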