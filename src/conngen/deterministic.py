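"""Deterministic connectivity rules: one-to-one, all-to-all, explicit lists.

These rules establish precisely defined connection sets with no variability
across realizations.  Adjacency matrices follow the computational-
neuroscience convention that the first index is the target and the second
the source: ``A[i, j]`` counts edges from source ``j`` to target ``i``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Constraints, EdgeList, Population, edge_space

__all__ = [
    "connect_one_to_one",
    "connect_all_to_all",
    "connect_explicit",
    "connect_adjacency",
    "adjacency_of",
]


def connect_one_to_one(
    source: Population,
    target: Population,
    source_perm: Sequence[int] | None = None,
    target_perm: Sequence[int] | None = None,
) -> EdgeList:
    """Connect each source node to exactly one target node (symbol delta).

    Requires ``N_s = N_t``.  By default local node ``k`` pairs with local
    node ``k``; sources and targets can be permuted independently via
    explicit permutations of ``0..N-1``.  Every in- and out-degree is 1.
    """
    if source.size != target.size:
        raise ValueError(
            f"one-to-one requires populations of identical cardinality, got "
            f"N_s={source.size}, N_t={target.size}"
        )
    n = source.size
    s_local = _check_perm(source_perm, n, "source_perm")
    t_local = _check_perm(target_perm, n, "target_perm")
    return EdgeList(s_local + source.offset, t_local + target.offset, source, target)


def _check_perm(perm: Sequence[int] | None, n: int, name: str) -> np.ndarray:
    if perm is None:
        return np.arange(n)
    arr = np.asarray(perm, dtype=np.int64)
    if arr.shape != (n,) or not np.array_equal(np.sort(arr), np.arange(n)):
        raise ValueError(f"{name} must be a permutation of 0..{n - 1}")
    return arr


def connect_all_to_all(
    source: Population,
    target: Population,
    constraints: Constraints = Constraints(allow_autapses=True),
) -> EdgeList:
    """Connect each source node to all target nodes (symbol Omega).

    The result equals the full edge space; with ``S = T`` and autapses
    disallowed the diagonal is omitted (Omega minus delta).
    """
    return edge_space(source, target, allow_autapses=constraints.allow_autapses)


def connect_explicit(
    pairs: Sequence[tuple[int, int]],
    source: Population,
    target: Population,
) -> EdgeList:
    """Connect according to an explicit (source, target) adjacency list.

    Global indices; order is preserved verbatim, and repeated pairs encode
    multapses.  Out-of-range indices raise a validation error naming the
    offending pair.
    """
    src, tgt = [], []
    for k, pair in enumerate(pairs):
        s, t = int(pair[0]), int(pair[1])
        if not (source.offset <= s < source.offset + source.size):
            raise ValueError(f"pair #{k} ({s}, {t}): source index {s} outside "
                             f"population {source.name!r}")
        if not (target.offset <= t < target.offset + target.size):
            raise ValueError(f"pair #{k} ({s}, {t}): target index {t} outside "
                             f"population {target.name!r}")
        src.append(s)
        tgt.append(t)
    return EdgeList(src, tgt, source, target)


def connect_adjacency(
    matrix: np.ndarray,
    source: Population,
    target: Population,
) -> EdgeList:
    """Expand an adjacency matrix into an edge list.

    ``matrix`` is ``N_t x N_s`` with non-negative integer entries;
    ``matrix[i, j] = m`` creates ``m`` edges from source ``j`` to target
    ``i`` (entries > 1 are multapse counts, booleans are 0/1).  Edges are
    emitted target-major.
    """
    a = np.asarray(matrix)
    if a.dtype == bool:
        a = a.astype(np.int64)
    if a.shape != (target.size, source.size):
        raise ValueError(f"adjacency matrix must be (N_t={target.size}, "
                         f"N_s={source.size}), got {a.shape}")
    if not np.issubdtype(a.dtype, np.integer) or np.any(a < 0):
        raise ValueError("adjacency entries must be non-negative integers")
    tgt_loc, src_loc = np.nonzero(a)
    counts = a[tgt_loc, src_loc]
    src = np.repeat(src_loc, counts) + source.offset
    tgt = np.repeat(tgt_loc, counts) + target.offset
    return EdgeList(src, tgt, source, target)


def adjacency_of(edges: EdgeList) -> np.ndarray:
    """Adjacency count matrix (targets as rows) of an edge list."""
    a = np.zeros((edges.target_pop.size, edges.source_pop.size), dtype=np.int64)
    np.add.at(
        a,
        (edges.targets - edges.target_pop.offset,
         edges.sources - edges.source_pop.offset),
        1,
    )
    return a
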