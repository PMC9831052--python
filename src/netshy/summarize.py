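"""Subject-level module summarization scores.

Given a subjects × features profile matrix ``X`` aligned to a weighted
network, three one-number-per-subject summaries are provided:

``nonet``
    The conventional first principal component of ``X`` (the "eigengene"
    of weighted correlation network analysis): topology is ignored.
``netshy``
    The first principal component of the Laplacian-weighted profile
    ``X* = X @ L`` with ``L = D - A``.  Multiplying by ``L`` re-expresses
    each feature as a degree-weighted contrast against its network
    neighbours, so the leading direction of variation reflects both the
    measurements and the module topology.
``hub``
    The raw profile of the most highly connected node, a classical
    single-feature baseline.

All PCA paths mean-center columns (no variance scaling) and use an SVD of
the centered matrix, which is robust when ``n < p``.  Loadings are unit
vectors with the sign fixed so that the entry of largest absolute value
is positive; scores follow the loading's sign.

A rank-based inverse-normal transform is included because summary scores
are typically Gaussianized before regression-based downstream association
(e.g. genome-wide association scans on the score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import (
    AlignmentError,
    DegenerateInputError,
    DegenerateTopologyError,
)
from .network import WeightedNetwork, build_laplacian, find_hub

__all__ = [
    "ProfileMatrix",
    "SummaryResult",
    "summarize_nonet",
    "summarize_netshy",
    "summarize_hub",
    "inverse_normal_transform",
    "read_profiles",
    "write_profiles",
    "write_scores",
    "read_scores",
    "write_loadings",
]


@dataclass(frozen=True)
class ProfileMatrix:
    """Subjects × features measurement matrix with aligned labels.

    ``values[i, j]`` is the measurement of feature ``feature_ids[j]`` on
    subject ``subject_ids[i]``.  Missing values are not accepted;
    imputation or filtering must happen upstream.
    """

    subject_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        subj = tuple(str(s) for s in self.subject_ids)
        feat = tuple(str(f) for f in self.feature_ids)
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape != (len(subj), len(feat)):
            raise ValueError(
                f"values shape {V.shape} does not match "
                f"({len(subj)} subjects, {len(feat)} features)"
            )
        if np.isnan(V).any():
            raise DegenerateInputError("profile matrix contains missing values")
        V = V.copy()
        V.setflags(write=False)
        object.__setattr__(self, "subject_ids", subj)
        object.__setattr__(self, "feature_ids", feat)
        object.__setattr__(self, "values", V)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def take_subjects(self, idx: Sequence[int]) -> "ProfileMatrix":
        """Row subset (e.g. a subsample), preserving label alignment."""
        idx = np.asarray(idx, dtype=int)
        return ProfileMatrix(
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            feature_ids=self.feature_ids,
            values=self.values[idx, :],
        )


@dataclass(frozen=True)
class SummaryResult:
    """One summarization of a module: per-subject scores plus loading.

    ``loading`` is a unit vector of per-node contributions (``None`` for
    the hub method, which has no linear-combination interpretation);
    ``centering`` is the column-mean vector subtracted before the
    decomposition (zeros for hub).  Sign convention: the loading entry of
    largest absolute value is positive.
    """

    method: str
    scores: np.ndarray = field(repr=False)
    loading: np.ndarray | None = field(repr=False, default=None)
    centering: np.ndarray | None = field(repr=False, default=None)
    extra_scores: np.ndarray | None = field(repr=False, default=None)
    extra_loadings: np.ndarray | None = field(repr=False, default=None)


def _first_pcs(M: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered-matrix SVD; returns (scores, loadings, column means).

    scores has shape (n, k), loadings (k, p); component j satisfies
    scores[:, j] = (M - mean) @ loadings[j].
    """
    mu = M.mean(axis=0)
    C = M - mu
    if not np.any(np.abs(C) > 0):
        raise DegenerateInputError("matrix is constant; no principal direction exists")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    k = min(n_components, s.size)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k]
    # sign convention: largest-|entry| coordinate of each loading positive
    for j in range(k):
        m = np.argmax(np.abs(loadings[j]))
        if loadings[j, m] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return scores, loadings, mu


def summarize_nonet(X: ProfileMatrix, n_components: int = 1) -> SummaryResult:
    """First principal component of the raw profile matrix (eigengene).

    Columns are mean-centered; no variance scaling.  ``n_components > 1``
    attaches further components in ``extra_scores``/``extra_loadings``
    for exploratory use, but the validated summary is always PC1.
    """
    if X.n < 2:
        raise DegenerateInputError(f"need at least 2 subjects, got {X.n}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    scores, loadings, mu = _first_pcs(X.values, n_components)
    return SummaryResult(
        method="nonet",
        scores=scores[:, 0],
        loading=loadings[0],
        centering=mu,
        extra_scores=scores if n_components > 1 else None,
        extra_loadings=loadings if n_components > 1 else None,
    )


def summarize_netshy(
    X: ProfileMatrix, net: WeightedNetwork, n_components: int = 1
) -> SummaryResult:
    """First principal component of the Laplacian-weighted profile ``X @ L``.

    The feature order of ``X`` must match the node order of ``net``.
    Because every column of ``L`` sums to zero, adding a per-subject
    constant to all features leaves the scores unchanged — the summary
    responds to contrasts across the module, not to overall level.  The
    returned loading lives in the column space of ``X* = X @ L`` and is a
    unit vector of length ``p``.
    """
    if X.feature_ids != net.node_ids:
        raise AlignmentError(
            "profile feature labels do not match network node labels "
            f"({X.feature_ids[:3]}... vs {net.node_ids[:3]}...)"
        )
    if X.n < 2:
        raise DegenerateInputError(f"need at least 2 subjects, got {X.n}")
    lap = build_laplacian(net)
    if not np.any(lap.matrix != 0):
        raise DegenerateTopologyError(
            "network has no edges; X @ L is identically zero"
        )
    Xstar = X.values @ lap.matrix
    scores, loadings, mu = _first_pcs(Xstar, n_components)
    return SummaryResult(
        method="netshy",
        scores=scores[:, 0],
        loading=loadings[0],
        centering=mu,
        extra_scores=scores if n_components > 1 else None,
        extra_loadings=loadings if n_components > 1 else None,
    )


def summarize_hub(X: ProfileMatrix, net: WeightedNetwork) -> SummaryResult:
    """Profile of the most highly connected node as the module summary."""
    if X.feature_ids != net.node_ids:
        raise AlignmentError("profile feature labels do not match network node labels")
    hub = find_hub(net)
    return SummaryResult(
        method="hub",
        scores=X.values[:, hub].copy(),
        loading=None,
        centering=np.zeros(X.p),
    )


def inverse_normal_transform(z: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform of a score vector.

    Maps value with rank ``r`` (average ranks on ties) to
    ``Phi^{-1}((r - c) / (n - 2 c + 1))``.  The default offset
    ``c = 3/8`` is the Blom constant, the common choice for Gaussianizing
    scores ahead of linear-model association testing.  Monotone in the
    input; tied inputs map to identical outputs.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 2:
        raise DegenerateInputError("need at least 2 values to rank")
    if np.all(z == z[0]):
        raise DegenerateInputError("all values identical; ranks are undefined")
    r = stats.rankdata(z, method="average")
    return stats.norm.ppf((r - c) / (n - 2.0 * c + 1.0))


# ---------------------------------------------------------------------------
# plain-text I/O


def write_profiles(X: ProfileMatrix, path: str | Path) -> None:
    """CSV with subjects as rows; first column subject ID, header = feature IDs."""
    df = pd.DataFrame(X.values, index=X.subject_ids, columns=X.feature_ids)
    df.index.name = "subject_id"
    df.to_csv(path)


def read_profiles(path: str | Path) -> ProfileMatrix:
    df = pd.read_csv(path, index_col=0)
    return ProfileMatrix(
        subject_ids=tuple(str(s) for s in df.index),
        feature_ids=tuple(str(f) for f in df.columns),
        values=df.to_numpy(dtype=float),
    )


def write_scores(
    subject_ids: Sequence[str], scores: np.ndarray, path: str | Path
) -> None:
    """Two-column TSV: subject_id, score."""
    pd.DataFrame({"subject_id": list(subject_ids), "score": np.asarray(scores)}).to_csv(
        path, sep="\t", index=False
    )


def read_scores(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return tuple(df["subject_id"]), df["score"].to_numpy(dtype=float)


def write_loadings(
    feature_ids: Sequence[str], loading: np.ndarray, path: str | Path
) -> None:
    """Two-column TSV: feature_id, loading."""
    pd.DataFrame(
        {"feature_id": list(feature_ids), "loading": np.asarray(loading)}
    ).to_csv(path, sep="\t", index=False)
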