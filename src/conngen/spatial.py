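"""Metric-space embeddings and distance-dependent connectivity.

Nodes live in a 1-, 2-, or 3-dimensional box ``[0, L_1) x ... x [0, L_d)``
with either open or periodic boundaries; under periodic boundaries opposite
faces are identified (a line becomes a ring, a square a torus) and distances
use the minimum-image convention.  A connectivity *profile* (also called a
spatial footprint) maps inter-node distance to a connection probability —
boxcar, linear, sigmoidal, exponential, isotropic Gaussian, or a non-centered
anisotropic Gaussian on the displacement vector.  The deterministic boxcar
variant returns 0/1 instead of a probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Constraints, EdgeList, Population, logger, same_population

__all__ = [
    "Space",
    "Profile",
    "place_uniform",
    "place_grid",
    "distance",
    "displacement",
    "eval_profile",
    "connect_spatial_bernoulli",
    "mean_degree_vs_distance",
]


@dataclass(frozen=True)
class Space:
    """A box-shaped metric space.

    Parameters
    ----------
    dimension
        1, 2, or 3.
    extent
        Side length per dimension (scalar broadcasts to all dimensions).
    metric
        ``"euclidean"`` (l2) or ``"maxnorm"`` (l-infinity).
    boundary
        ``"periodic"`` (minimum-image distances, positions wrapped) or
        ``"open"`` (no wrapping; border inhomogeneities are not corrected).
    """

    dimension: int
    extent: tuple[float, ...] = (1.0,)
    metric: str = "euclidean"
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2, or 3")
        ext = self.extent
        if np.isscalar(ext):
            ext = (float(ext),) * self.dimension
        ext = tuple(float(e) for e in np.broadcast_to(ext, (self.dimension,)))
        if any(e <= 0 for e in ext):
            raise ValueError("extents must be positive")
        object.__setattr__(self, "extent", ext)
        if self.metric not in ("euclidean", "maxnorm"):
            raise ValueError("metric must be 'euclidean' or 'maxnorm'")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.extent, dtype=float)

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Fold positions into [0, L) per dimension under periodic boundary."""
        pos = np.asarray(positions, dtype=float)
        if self.boundary == "periodic":
            return np.mod(pos, self.lengths)
        return pos


@dataclass(frozen=True)
class Profile:
    """Distance-dependent connectivity profile p(r) (or p of displacement).

    Kinds and parameters:

    - ``boxcar_deterministic``: 1 if ``r <= r_max`` else 0 (``c`` ignored).
    - ``boxcar``: ``c * Theta[r_max - r]``.
    - ``linear``: ``max(c1 - c2 * r, 0)``.
    - ``sigmoidal``: ``1 / (1 + exp((r - c1) / c2))``.
    - ``exponential``: ``c1 * exp(-r / c2)``.
    - ``gaussian``: ``c * exp(-r^2 / (2 sigma^2))`` (``c`` is the peak p0).
    - ``gaussian_anisotropic``: ``c * exp(-(d - mu)^T Sigma^-1 (d - mu) / 2)``
      on the displacement vector ``d``.

    Probabilistic kinds are clamped to [0, 1] after evaluation (the leading
    constant is taken literally; clamping is logged when triggered).
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = ("boxcar_deterministic", "boxcar", "linear", "sigmoidal",
              "exponential", "gaussian", "gaussian_anisotropic")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        p = self.params
        if self.kind == "gaussian" and p.get("sigma", 1.0) <= 0:
            raise ValueError("sigma must be > 0")
        if self.kind in ("sigmoidal", "exponential") and p.get("c2", 1.0) <= 0:
            raise ValueError("c2 must be > 0")

    @property
    def deterministic(self) -> bool:
        return self.kind == "boxcar_deterministic"


def eval_profile(profile: Profile, r: np.ndarray | float,
                 displacement: np.ndarray | None = None) -> np.ndarray | float:
    """Evaluate a profile at distance ``r`` (or displacement vectors).

    Scalar-kind profiles take ``r >= 0``; the anisotropic Gaussian requires
    the ``displacement`` array of shape ``(..., dim)``.  Probabilistic
    values are clamped to [0, 1].
    """
    p = profile.params
    if profile.kind == "gaussian_anisotropic":
        if displacement is None:
            raise ValueError("anisotropic Gaussian profiles require displacement vectors")
        d = np.asarray(displacement, dtype=float)
        mu = np.asarray(p.get("mu", np.zeros(d.shape[-1])), dtype=float)
        sigma = np.asarray(p["Sigma"], dtype=float)
        if sigma.shape != (d.shape[-1], d.shape[-1]):
            raise ValueError("Sigma must be (dim, dim)")
        diff = d - mu
        quad = np.einsum("...i,ij,...j->...", diff, np.linalg.inv(sigma), diff)
        val = p.get("c", 1.0) * np.exp(-quad / 2.0)
        return _clamp(val)

    rr = np.asarray(r, dtype=float)
    if np.any(rr < 0):
        raise ValueError("distance must be >= 0")
    if profile.kind == "boxcar_deterministic":
        return (rr <= p["r_max"]).astype(float)
    if profile.kind == "boxcar":
        val = p.get("c", 1.0) * (rr <= p["r_max"])
    elif profile.kind == "linear":
        val = np.maximum(p["c1"] - p["c2"] * rr, 0.0)
    elif profile.kind == "sigmoidal":
        val = 1.0 / (1.0 + np.exp((rr - p["c1"]) / p["c2"]))
    elif profile.kind == "exponential":
        val = p["c1"] * np.exp(-rr / p["c2"])
    elif profile.kind == "gaussian":
        val = p.get("c", 1.0) * np.exp(-(rr ** 2) / (2.0 * p["sigma"] ** 2))
    else:  # pragma: no cover
        raise NotImplementedError(profile.kind)
    return _clamp(val)


def _clamp(val):
    arr = np.asarray(val, dtype=float)
    if np.any(arr > 1.0) or np.any(arr < 0.0):
        logger.info("profile values outside [0, 1] clamped")
        arr = np.clip(arr, 0.0, 1.0)
    if np.ndim(val) == 0:
        return float(arr)
    return arr


def place_uniform(space: Space, n: int,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """``n`` i.i.d. uniform positions in the extent, shape ``(n, dim)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    return rng.uniform(0.0, 1.0, size=(n, space.dimension)) * space.lengths


def place_grid(space: Space, n: int, jitter: float = 0.0,
               rng: np.random.Generator | None = None,
               shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Jittered grid positions.

    Nodes sit on a regular grid with grid constant ``Delta = L / n_axis``
    per dimension plus a uniform jitter in ``[0, J]^d``; under periodic
    boundary the jittered positions are wrapped back into [0, L).  ``n``
    must be a perfect ``dim``-th power unless an explicit grid ``shape``
    is given.
    """
    rng = np.random.default_rng() if rng is None else rng
    d = space.dimension
    if shape is None:
        side = round(n ** (1.0 / d))
        if side ** d != n:
            raise ValueError(f"n={n} is not a perfect {d}-th power; pass an "
                             "explicit grid shape")
        shape = (side,) * d
    if int(np.prod(shape)) != n:
        raise ValueError("grid shape does not match n")
    deltas = space.lengths / np.asarray(shape, dtype=float)
    if jitter < 0 or np.any(jitter > deltas):
        raise ValueError("jitter must satisfy 0 <= J <= grid constant")
    axes = [np.arange(s) * dl for s, dl in zip(shape, deltas)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)
    pos = grid + rng.uniform(0.0, jitter, size=(n, d))
    return space.wrap(pos)


def displacement(space: Space, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Displacement ``y - x`` per dimension (minimum image under periodic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != space.dimension or y.shape[-1] != space.dimension:
        raise ValueError("position dimensionality does not match space")
    diff = y - x
    if space.boundary == "periodic":
        ll = space.lengths
        diff = diff - np.round(diff / ll) * ll
    return diff


def distance(space: Space, x: np.ndarray, y: np.ndarray) -> np.ndarray | float:
    """Distance between positions under the space's metric and boundary.

    Periodic boundaries use the minimum-image convention, so each
    per-dimension separation is at most L/2.
    """
    diff = np.abs(displacement(space, x, y))
    if space.metric == "euclidean":
        out = np.sqrt(np.sum(diff ** 2, axis=-1))
    else:
        out = np.max(diff, axis=-1)
    return float(out) if out.ndim == 0 else out


def connect_spatial_bernoulli(
    source: Population,
    target: Population,
    space: Space,
    profile: Profile,
    constraints: Constraints = Constraints(),
    rng: np.random.Generator | None = None,
    block: int = 512,
) -> EdgeList:
    """Pairwise Bernoulli with distance-dependent probability p(r).

    Each admissible pair is tried exactly once with probability
    ``eval_profile(distance(source, target))`` — no multapses can occur.
    With a deterministic boxcar profile the edge is present iff the distance
    is within ``r_max``.  Pairs are processed in source blocks so no full
    N_s x N_t distance matrix is materialized.
    """
    if source.positions is None or target.positions is None:
        raise ValueError("both populations need positions for spatial connectivity")
    rng = np.random.default_rng() if rng is None else rng
    exclude_diag = same_population(source, target) and not constraints.allow_autapses
    anisotropic = profile.kind == "gaussian_anisotropic"

    src_chunks, tgt_chunks = [], []
    for start in range(0, source.size, block):
        stop = min(start + block, source.size)
        xs = source.positions[start:stop][:, None, :]   # (b, 1, d)
        ys = target.positions[None, :, :]               # (1, N_t, d)
        if anisotropic:
            disp = displacement(space, np.broadcast_to(xs, (stop - start, target.size,
                                                            space.dimension)), ys)
            probs = eval_profile(profile, 0.0, displacement=disp)
        else:
            dists = distance(space, xs, ys)
            probs = eval_profile(profile, dists)
        probs = np.atleast_2d(probs)
        if exclude_diag:
            rows = np.arange(start, stop)
            probs[np.arange(stop - start), rows] = 0.0
        if profile.deterministic:
            hit = probs > 0.5
        else:
            hit = rng.random(probs.shape) < probs
        s_loc, t_loc = np.nonzero(hit)
        src_chunks.append(s_loc + start + source.offset)
        tgt_chunks.append(t_loc + target.offset)
    return EdgeList(np.concatenate(src_chunks), np.concatenate(tgt_chunks),
                    source, target)


def mean_degree_vs_distance(
    edges: EdgeList,
    space: Space,
    bin_edges: np.ndarray,
    block: int = 512,
) -> dict[str, np.ndarray]:
    """Distance-binned connection frequency.

    For every distance bin, reports the number of (ordered, admissible)
    node pairs at that distance, the number of connected pairs, and their
    ratio — the pair-level restatement of the mean-degree-vs-distance
    relation <K(r)> ~ rho(r) p(r).  Empty bins get frequency NaN (missing),
    not zero.
    """
    src_pop, tgt_pop = edges.source_pop, edges.target_pop
    if src_pop.positions is None or tgt_pop.positions is None:
        raise ValueError("populations need positions")
    bins = np.asarray(bin_edges, dtype=float)
    n_bins = len(bins) - 1
    pair_counts = np.zeros(n_bins, dtype=np.int64)
    conn_counts = np.zeros(n_bins, dtype=np.int64)
    identical = same_population(src_pop, tgt_pop)

    # all ordered pairs, in source blocks (no full distance matrix)
    for start in range(0, src_pop.size, block):
        stop = min(start + block, src_pop.size)
        xs = src_pop.positions[start:stop][:, None, :]
        ys = tgt_pop.positions[None, :, :]
        dists = np.atleast_2d(distance(space, xs, ys))
        mask = np.ones_like(dists, dtype=bool)
        if identical:
            mask[np.arange(stop - start), np.arange(start, stop)] = False
        which = np.digitize(dists, bins) - 1
        valid = mask & (which >= 0) & (which < n_bins)
        np.add.at(pair_counts, which[valid], 1)

    # realized edges (with multiplicity) binned by their distance
    if len(edges):
        xs = src_pop.positions[edges.sources - src_pop.offset]
        ys = tgt_pop.positions[edges.targets - tgt_pop.offset]
        d_edges = np.atleast_1d(distance(space, xs, ys))
        which = np.digitize(d_edges, bins) - 1
        ok = (which >= 0) & (which < n_bins)
        np.add.at(conn_counts, which[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(pair_counts > 0, conn_counts / np.maximum(pair_counts, 1), np.nan)
    return {"bin_edges": bins, "pair_count": pair_counts,
            "connected_count": conn_counts, "frequency": freq}
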