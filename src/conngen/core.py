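"""Foundational types for populations, edge lists, constraints, and RNG streams.

Connectivity is described between an ordered source population ``S`` of size
``N_s`` and an ordered target population ``T`` of size ``N_t``.  The set of
all possible directed edges is the Cartesian product ``S x T`` with
cardinality ``N_s * N_t``; if ``S`` and ``T`` are the same population and
self-connections (*autapses*) are excluded, the diagonal is removed and the
cardinality drops to ``N_s * (N_s - 1)``.  Several edges sharing source,
target, and direction form a *multapse*; edge lists are ordered sequences so
multapses are representable and output is reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("conngen")

__all__ = [
    "Role",
    "Population",
    "EdgeList",
    "Constraints",
    "derive_rng",
    "edge_space",
    "degree_counts",
    "count_possible_networks",
    "average_connection_probability",
]


class Role(str, Enum):
    """Node role; determines the shape used in diagram export."""

    generic = "generic"
    excitatory = "excitatory"
    inhibitory = "inhibitory"
    stimulator = "stimulator"
    recorder = "recorder"


@dataclass(frozen=True)
class Population:
    """Ordered, contiguously indexed set of nodes.

    Parameters
    ----------
    name
        Identifier used in configs, diagrams, and file names.
    size
        Number of nodes (``N_s`` or ``N_t``); must be >= 1.
    offset
        Global index of the first node.  Node ``k`` of the population has
        global index ``offset + k``; this mirrors the contiguous global
        identifier (GID) schemes of common simulators.
    role
        Node role (generic, excitatory, inhibitory, stimulator, recorder).
    positions
        Optional ``(size, dim)`` array of coordinates, one row per node.
    """

    name: str
    size: int
    offset: int = 0
    role: Role = Role.generic
    positions: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.name!r}: size must be >= 1, got {self.size}")
        if self.offset < 0:
            raise ValueError(f"population {self.name!r}: offset must be >= 0")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=float)
            if pos.ndim != 2 or pos.shape[0] != self.size:
                raise ValueError(
                    f"population {self.name!r}: positions must have shape ({self.size}, dim), "
                    f"got {pos.shape}"
                )
            object.__setattr__(self, "positions", pos)

    @property
    def global_indices(self) -> np.ndarray:
        """Contiguous global index range ``[offset, offset + size)``."""
        return np.arange(self.offset, self.offset + self.size)

    def __len__(self) -> int:
        return self.size


@dataclass(frozen=True)
class Constraints:
    """Autapse/multapse policy for a projection.

    ``allow_autapses`` (symbol A) only has meaning when source and target are
    the same population; for disjoint populations self-connections cannot
    occur by definition and the flag is ignored.
    ``allow_multapses`` (symbol M) states whether several edges may share the
    same (source, target) pair.
    """

    allow_autapses: bool = False
    allow_multapses: bool = False


class EdgeList:
    """Ordered multiset of directed (source, target) pairs in global indices.

    Duplicate pairs encode multapses.  The number of edges equals ``N_syn``
    and, by the handshake identity, the sum of in-degrees and the sum of
    out-degrees.
    """

    __slots__ = ("sources", "targets", "source_pop", "target_pop")

    def __init__(
        self,
        sources: Iterable[int],
        targets: Iterable[int],
        source_pop: Population,
        target_pop: Population,
    ) -> None:
        src = np.asarray(list(sources) if not isinstance(sources, np.ndarray) else sources,
                         dtype=np.int64).ravel()
        tgt = np.asarray(list(targets) if not isinstance(targets, np.ndarray) else targets,
                         dtype=np.int64).ravel()
        if src.shape != tgt.shape:
            raise ValueError("sources and targets must have equal length")
        lo_s, hi_s = source_pop.offset, source_pop.offset + source_pop.size
        lo_t, hi_t = target_pop.offset, target_pop.offset + target_pop.size
        if src.size and (src.min() < lo_s or src.max() >= hi_s):
            raise ValueError(f"source index out of range [{lo_s}, {hi_s})")
        if tgt.size and (tgt.min() < lo_t or tgt.max() >= hi_t):
            raise ValueError(f"target index out of range [{lo_t}, {hi_t})")
        self.sources = src
        self.targets = tgt
        self.source_pop = source_pop
        self.target_pop = target_pop

    def __len__(self) -> int:
        return int(self.sources.size)

    @property
    def n_syn(self) -> int:
        return len(self)

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.sources.tolist(), self.targets.tolist()))

    def canonical(self) -> tuple[tuple[int, int], ...]:
        """Edges sorted (source, target) ascending — a canonical multiset key."""
        return tuple(sorted(self.pairs()))

    def sorted_copy(self) -> "EdgeList":
        order = np.lexsort((self.targets, self.sources))
        return EdgeList(self.sources[order], self.targets[order],
                        self.source_pop, self.target_pop)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeList):
            return NotImplemented
        return (np.array_equal(self.sources, other.sources)
                and np.array_equal(self.targets, other.targets))

    def __repr__(self) -> str:
        return (f"EdgeList({len(self)} edges, {self.source_pop.name!r} -> "
                f"{self.target_pop.name!r})")


def derive_rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Return a generator for substream ``stream`` of root ``seed``.

    Substreams are derived with :class:`numpy.random.SeedSequence` spawn keys,
    so projection ``k`` always sees the same stream regardless of how many
    other projections a config contains: adding a projection does not perturb
    earlier ones.  Same (seed, stream) and call sequence give bit-identical
    output.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def same_population(source: Population, target: Population) -> bool:
    """True if source and target are the same index range (S = T)."""
    return source.offset == target.offset and source.size == target.size


def edge_space(source: Population, target: Population,
               allow_autapses: bool = True) -> EdgeList:
    """All possible edges of the projection, each exactly once, source-major.

    For disjoint populations this is the full Cartesian product with
    ``N_s * N_t`` edges; the autapse flag is then irrelevant (a note is
    logged if it was set to ``False``).  For ``S = T`` with autapses
    disallowed the diagonal is omitted, leaving ``N_s * (N_s - 1)`` edges.
    """
    identical = same_population(source, target)
    if not identical and not allow_autapses:
        logger.info(
            "autapse exclusion requested for disjoint populations %r -> %r; "
            "self-connections cannot occur by definition, flag ignored",
            source.name, target.name,
        )
    src_idx = source.global_indices
    tgt_idx = target.global_indices
    ss = np.repeat(src_idx, target.size)
    tt = np.tile(tgt_idx, source.size)
    if identical and not allow_autapses:
        keep = ss != tt
        ss, tt = ss[keep], tt[keep]
    return EdgeList(ss, tt, source, target)


def degree_counts(edges: EdgeList, direction: str) -> np.ndarray:
    """Per-node edge counts: in-degrees (length ``N_t``) or out-degrees (``N_s``).

    The vector sums to ``N_syn``; duplicates (multapses) count once per edge.
    """
    if direction == "in":
        pop, idx = edges.target_pop, edges.targets
    elif direction == "out":
        pop, idx = edges.source_pop, edges.sources
    else:
        raise ValueError("direction must be 'in' or 'out'")
    return np.bincount(idx - pop.offset, minlength=pop.size).astype(np.int64)


def count_possible_networks(n_s: int, n_t: int, n_syn: int,
                            allow_multapses: bool = False) -> int:
    """Exact number of distinct networks with ``n_syn`` edges.

    Without multapses this is the number of ``n_syn``-subsets of the
    ``n_s * n_t`` possible edges, ``C(n_s n_t, n_syn)``; with multapses the
    number of ``n_syn``-multisets, ``C(n_s n_t + n_syn - 1, n_syn)``.
    """
    if n_s < 1 or n_t < 1:
        raise ValueError("population sizes must be >= 1")
    if n_syn < 0:
        raise ValueError("n_syn must be >= 0")
    m = n_s * n_t
    if allow_multapses:
        return math.comb(m + n_syn - 1, n_syn)
    if n_syn > m:
        raise ValueError(f"n_syn={n_syn} exceeds the {m} possible edges without multapses")
    return math.comb(m, n_syn)


def average_connection_probability(
    pair_probabilities: Sequence[float] | np.ndarray,
    target_sizes: Sequence[int],
    source_sizes: Sequence[int] | int,
) -> float:
    """Connection-count-weighted average probability across population groups.

    For groups of target populations ``I`` (sizes ``N_I``) and source
    populations ``J`` (sizes ``N_J``) with pairwise probabilities ``p_IJ``,
    the average equals the expected total number of connections divided by
    the maximum possible number:

    ``p_avg = sum_IJ N_I N_J p_IJ / sum_IJ N_I N_J``.

    ``pair_probabilities`` may be a vector (one source group) or a matrix
    with rows indexing target groups and columns source groups.
    """
    p = np.atleast_2d(np.asarray(pair_probabilities, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one population group")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_t = np.asarray(target_sizes, dtype=float).ravel()
    n_s = np.atleast_1d(np.asarray(source_sizes, dtype=float)).ravel()
    if p.shape == (1, n_t.size) and n_s.size == 1:
        p = p.reshape(n_t.size, 1)
    if np.any(n_t <= 0) or np.any(n_s <= 0):
        raise ValueError("group sizes must be positive")
    if p.shape != (n_t.size, n_s.size):
        raise ValueError(f"probability matrix shape {p.shape} does not match "
                         f"({n_t.size} target groups, {n_s.size} source groups)")
    weights = np.outer(n_t, n_s)
    return float(np.sum(weights * p) / np.sum(weights))
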