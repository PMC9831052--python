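"""Weighted undirected networks and their graph Laplacians.

A module (subnetwork) of ``p`` molecular features is represented by a
symmetric, non-negative adjacency matrix ``A`` with zero diagonal, where
``A[k, l]`` is the similarity (edge weight) between features ``k`` and
``l``.  The combinatorial Laplacian ``L = D - A`` — with ``D`` the
diagonal matrix of weighted degrees ``D[k, k] = sum_l A[k, l]`` — encodes
both direct connections and the degree distribution, and is the
topological ingredient of the NetSHy summarization.

This module also provides the Erdős–Rényi weighted-network generator used
by the simulation engine, simple topology queries (sparsity, degrees, hub
node), hard thresholding of weak edges, and plain-text readers/writers for
edge lists and adjacency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import InvalidNetworkError, NoHubError

__all__ = [
    "WeightedNetwork",
    "NetworkLaplacian",
    "build_laplacian",
    "generate_er_network",
    "hard_threshold",
    "sparsity",
    "node_degrees",
    "find_hub",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
]

#: tolerance for symmetry validation when loading matrices from text
SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class WeightedNetwork:
    """A weighted, non-negative, undirected network.

    Parameters
    ----------
    node_ids
        Ordered feature labels, one per node; must be unique.
    adjacency
        ``(p, p)`` symmetric matrix of non-negative edge weights with a
        zero diagonal.  Self-loops are not representable.
    """

    node_ids: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.node_ids)
        object.__setattr__(self, "node_ids", ids)
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidNetworkError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] != len(ids):
            raise InvalidNetworkError(
                f"{len(ids)} node labels for a {A.shape[0]}-node adjacency"
            )
        if len(set(ids)) != len(ids):
            raise InvalidNetworkError("node labels must be unique")
        if not np.array_equal(A, A.T):
            raise InvalidNetworkError("adjacency must be exactly symmetric")
        if np.any(A < 0):
            raise InvalidNetworkError("edge weights must be non-negative")
        if np.any(np.diagonal(A) != 0):
            raise InvalidNetworkError("diagonal (self-loop) entries must be zero")
        A = A.copy()
        A.setflags(write=False)
        object.__setattr__(self, "adjacency", A)

    @property
    def p(self) -> int:
        """Number of nodes."""
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass(frozen=True)
class NetworkLaplacian:
    """Graph Laplacian ``L = D - A`` with the degree vector attached.

    Every row (and column) of ``matrix`` sums to zero, the matrix is
    symmetric positive semidefinite, and its off-diagonal entries are
    non-positive.
    """

    matrix: np.ndarray = field(repr=False)
    degrees: np.ndarray = field(repr=False)


def build_laplacian(net: WeightedNetwork) -> NetworkLaplacian:
    """Compute ``L = D - A`` for a weighted network.

    ``D`` is diagonal with ``D[k, k] = sum_l A[k, l]`` (the weighted
    degree of node ``k``).  Zero row sums of ``L`` are what make the
    NetSHy transform ``X @ L`` invariant to per-subject constant offsets.
    """
    A = net.adjacency
    deg = A.sum(axis=1)
    L = np.diag(deg) - A
    return NetworkLaplacian(matrix=L, degrees=deg)


def generate_er_network(
    p: int,
    alpha0: float,
    w_low: float = 0.1,
    w_high: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> WeightedNetwork:
    """Generate a weighted Erdős–Rényi ``G(p, alpha0)`` network.

    Each unordered node pair is connected independently with probability
    ``alpha0``; each realized edge receives a weight drawn from
    ``Uniform(w_low, w_high)``, mirrored to both triangles.  The realized
    edge fraction is therefore approximately ``alpha0``, and the generator
    is bit-reproducible for a fixed seed.  Isolated nodes are permitted
    (the generator does not condition on connectivity).
    """
    if p < 2:
        raise InvalidNetworkError(f"need at least 2 nodes, got p={p}")
    if not 0.0 <= alpha0 <= 1.0:
        raise InvalidNetworkError(f"alpha0 must lie in [0, 1], got {alpha0}")
    if not w_low < w_high:
        raise InvalidNetworkError(f"need w_low < w_high, got [{w_low}, {w_high}]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    n_pairs = iu[0].size
    present = rng.random(n_pairs) < alpha0
    weights = np.where(present, rng.uniform(w_low, w_high, size=n_pairs), 0.0)
    A = np.zeros((p, p))
    A[iu] = weights
    A += A.T
    labels = tuple(f"v{k}" for k in range(p))
    return WeightedNetwork(node_ids=labels, adjacency=A)


def hard_threshold(net: WeightedNetwork, t: float) -> WeightedNetwork:
    """Remove weak edges: entries with ``A[k, l] < t`` are set to zero.

    Idempotent at fixed ``t``; sparsity is non-increasing in ``t``.
    """
    if t < 0:
        raise InvalidNetworkError(f"threshold must be non-negative, got {t}")
    A = np.where(net.adjacency < t, 0.0, net.adjacency)
    return WeightedNetwork(node_ids=net.node_ids, adjacency=A)


def sparsity(net: WeightedNetwork) -> float:
    """Realized fraction of connected node pairs.

    Counts unordered pairs with strictly positive weight and divides by
    ``p * (p - 1) / 2``.  This is the empirical counterpart of the edge
    probability used by :func:`generate_er_network`.
    """
    p = net.p
    iu = np.triu_indices(p, k=1)
    return float(np.count_nonzero(net.adjacency[iu] > 0) / iu[0].size)


def node_degrees(net: WeightedNetwork) -> np.ndarray:
    """Weighted degree of each node: the row sums of ``A``."""
    return net.adjacency.sum(axis=1)


def find_hub(net: WeightedNetwork) -> int:
    """Index of the most highly connected node (maximal weighted degree).

    Ties are broken by the lowest node index.  Raises :class:`NoHubError`
    on an edgeless network, where every degree is zero and "hub" is
    meaningless.
    """
    deg = node_degrees(net)
    if not np.any(deg > 0):
        raise NoHubError("network has no edges; no hub node exists")
    return int(np.argmax(deg))


# ---------------------------------------------------------------------------
# plain-text I/O


def write_edge_list(net: WeightedNetwork, path: str | Path, header: bool = True) -> None:
    """Write a 3-column tab-separated edge list (node_a, node_b, weight).

    One line per unordered pair with positive weight.
    """
    iu = np.triu_indices(net.p, k=1)
    rows = [
        (net.node_ids[k], net.node_ids[l], net.adjacency[k, l])
        for k, l in zip(*iu)
        if net.adjacency[k, l] > 0
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    df.to_csv(path, sep="\t", index=False, header=header)


def read_edge_list(
    path: str | Path, node_ids: Sequence[str] | None = None
) -> WeightedNetwork:
    """Read an undirected edge list (node_a, node_b, weight; TSV).

    A header line is detected by a non-numeric third column.  Node order
    defaults to first appearance; pass ``node_ids`` to fix the order and
    include isolated nodes.
    """
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    has_header = not _is_number(first.iloc[0, 2])
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=["node_a", "node_b", "weight"],
        dtype={"node_a": str, "node_b": str},
    )
    if node_ids is None:
        seen: dict[str, None] = {}
        for col in ("node_a", "node_b"):
            for v in df[col]:
                seen.setdefault(v, None)
        node_ids = list(seen)
    index = {v: k for k, v in enumerate(node_ids)}
    p = len(index)
    A = np.zeros((p, p))
    for a, b, w in df.itertuples(index=False):
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise InvalidNetworkError(f"edge references unknown node {exc}") from None
        if i == j:
            raise InvalidNetworkError(f"self-loop on node {a!r} is not allowed")
        A[i, j] = A[j, i] = float(w)
    return WeightedNetwork(node_ids=tuple(node_ids), adjacency=A)


def write_adjacency(net: WeightedNetwork, path: str | Path) -> None:
    """Write the labeled adjacency matrix as CSV (labels in row 0/column 0)."""
    df = pd.DataFrame(net.adjacency, index=net.node_ids, columns=net.node_ids)
    df.to_csv(path)


def read_adjacency(path: str | Path) -> WeightedNetwork:
    """Read a labeled square CSV adjacency matrix.

    Symmetry is validated to ``SYMMETRY_TOL`` (guards against corrupted
    files), then the matrix is made exactly symmetric by averaging with
    its transpose so that downstream exact-symmetry invariants hold.
    """
    df = pd.read_csv(path, index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise InvalidNetworkError("row and column labels differ")
    A = df.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=SYMMETRY_TOL, rtol=0.0):
        raise InvalidNetworkError(f"adjacency not symmetric within {SYMMETRY_TOL}")
    A = (A + A.T) / 2.0
    return WeightedNetwork(node_ids=labels, adjacency=A)


def _is_number(x: object) -> bool:
    try:
        float(x)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False
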