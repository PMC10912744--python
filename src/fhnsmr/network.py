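"""Watts-Strogatz small-world coupling topology.

The coupling matrix J is binary and symmetric: a ring lattice where every
neuron touches its k nearest neighbours, with each edge rewired to a random
target with probability p.  Rewiring preserves the edge count N*k/2 and never
introduces self-loops or duplicate edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NetworkParams",
    "build_ws_adjacency",
    "save_edge_list",
    "load_edge_list",
]


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the Watts-Strogatz construction."""

    N: int = 100
    k: int = 30
    p: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.k < 2 or self.k % 2 != 0:
            raise ValueError(f"k must be an even positive integer, got {self.k}")
        if self.k >= self.N:
            raise ValueError(f"k ({self.k}) must be smaller than N ({self.N})")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"rewiring probability p must lie in [0,1], got {self.p}")


def build_ws_adjacency(params: NetworkParams) -> np.ndarray:
    """Dense symmetric 0/1 coupling matrix of a Watts-Strogatz graph.

    With p=0 the result is exactly the circulant ring lattice (node i linked
    to the k/2 nearest nodes on each side).  Deterministic given the seed.
    """
    graph = nx.watts_strogatz_graph(params.N, params.k, params.p, seed=params.seed)
    J = nx.to_numpy_array(graph, nodelist=range(params.N), dtype=np.float64)
    return J


def save_edge_list(path, J: np.ndarray, params: NetworkParams | None = None) -> None:
    """Write the adjacency as a plain-text edge list (0-based, one edge/line)."""
    J = np.asarray(J)
    ii, jj = np.nonzero(np.triu(J, k=1))
    with open(path, "w") as fh:
        if params is not None:
            fh.write(
                f"# N={params.N} k={params.k} p={params.p} seed={params.seed}\n"
            )
        else:
            fh.write(f"# N={J.shape[0]}\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i} {j}\n")


def load_edge_list(path) -> np.ndarray:
    """Read an edge list written by :func:`save_edge_list`."""
    n = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    key, _, val = tok.partition("=")
                    if key == "N":
                        n = int(val)
                continue
            i, j = map(int, line.split())
            edges.append((i, j))
    if n is None:
        n = 1 + max(max(e) for e in edges) if edges else 0
    J = np.zeros((n, n), dtype=np.float64)
    for i, j in edges:
        J[i, j] = J[j, i] = 1.0
    return J
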