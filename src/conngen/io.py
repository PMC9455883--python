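"""Plain-text readers and writers: edge lists, positions, adjacency, spikes.

All files are TAB- or comma-separated text with a header line and 0-based
global node indices, so outputs diff cleanly and load anywhere.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .core import EdgeList, Population

__all__ = [
    "write_edge_list_tsv",
    "read_edge_list_tsv",
    "write_positions_tsv",
    "read_positions_tsv",
    "write_adjacency_csv",
    "read_adjacency_csv",
    "write_adjacency_coo_tsv",
    "write_spikes_tsv",
]


def write_edge_list_tsv(path: str | Path, edges: EdgeList,
                        weights: np.ndarray | float | None = None,
                        delays: np.ndarray | float | None = None) -> None:
    """Write ``source<TAB>target[<TAB>weight<TAB>delay]`` with a header."""
    path = Path(path)
    cols = ["source", "target"]
    data = [edges.sources, edges.targets]
    if weights is not None:
        cols.append("weight")
        data.append(np.broadcast_to(np.asarray(weights, dtype=float), (len(edges),)))
    if delays is not None:
        if weights is None:
            raise ValueError("delays require a weight column")
        cols.append("delay")
        data.append(np.broadcast_to(np.asarray(delays, dtype=float), (len(edges),)))
    with path.open("w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in zip(*data):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if float(v) == int(v) and not isinstance(v, float):
        return str(int(v))
    return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))


def read_edge_list_tsv(path: str | Path, source: Population,
                       target: Population) -> tuple[EdgeList, dict[str, np.ndarray]]:
    """Read an edge-list TSV; returns the edges and any extra columns."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        rows = [line.strip().split("\t") for line in fh if line.strip()]
    if header[:2] != ["source", "target"]:
        raise ValueError(f"{path}: expected header starting 'source\\ttarget'")
    arr = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header)))
    edges = EdgeList(arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64),
                     source, target)
    extras = {name: arr[:, i] for i, name in enumerate(header) if i >= 2}
    return edges, extras


def write_positions_tsv(path: str | Path, pop: Population) -> None:
    """Write ``node<TAB>x[<TAB>y[<TAB>z]]`` (global indices)."""
    if pop.positions is None:
        raise ValueError(f"population {pop.name!r} has no positions")
    path = Path(path)
    dim = pop.positions.shape[1]
    cols = ["node"] + ["x", "y", "z"][:dim]
    with path.open("w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for gid, row in zip(pop.global_indices, pop.positions):
            fh.write(str(gid) + "\t" + "\t".join(repr(float(c)) for c in row) + "\n")


def read_positions_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read positions; returns (global node indices, positions array)."""
    with Path(path).open() as fh:
        header = fh.readline().strip().split("\t")
        rows = [line.strip().split("\t") for line in fh if line.strip()]
    if header[0] != "node":
        raise ValueError("positions file must start with a 'node' column")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0].astype(np.int64), arr[:, 1:]


def write_adjacency_csv(path: str | Path, matrix: np.ndarray) -> None:
    """Dense adjacency counts, targets as rows, comma-separated."""
    np.savetxt(path, np.asarray(matrix, dtype=np.int64), fmt="%d", delimiter=",")


def read_adjacency_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, dtype=np.int64, delimiter=","))


def write_adjacency_coo_tsv(path: str | Path, matrix: np.ndarray) -> None:
    """Coordinate form ``target<TAB>source<TAB>count`` for nonzero entries."""
    a = np.asarray(matrix, dtype=np.int64)
    tgt, src = np.nonzero(a)
    with Path(path).open("w", newline="") as fh:
        fh.write("target\tsource\tcount\n")
        for i, j in zip(tgt, src):
            fh.write(f"{i}\t{j}\t{a[i, j]}\n")


def write_spikes_tsv(path: str | Path, neurons: np.ndarray,
                     times_ms: np.ndarray) -> None:
    """Write ``neuron<TAB>time_ms`` sorted by time."""
    with Path(path).open("w", newline="") as fh:
        fh.write("neuron\ttime_ms\n")
        for n, t in zip(neurons, times_ms):
            fh.write(f"{int(n)}\t{float(t):.6g}\n")
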