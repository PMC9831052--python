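"""Synthetic data generation for benchmarking module summarizations.

The generative model is a Gaussian graphical model seeded by the network:
the adjacency matrix ``A`` is turned into a positive-definite precision
matrix by diagonal loading, its inverse is rescaled to correlation form
``Sigma``, true profiles are drawn ``X0 ~ N(0, Sigma)``, and a continuous
phenotype is a linear signal through the network's weighted degrees,

    Y0 = beta0 + X0 @ beta + eps,   beta[k] = weighted degree of node k,

so highly connected nodes influence the phenotype most.  Observed
profiles are measurement-noise perturbations ``X = X0 + E`` with
``E[i, j] ~ N(0, sigma_e^2)``: summarizers see only ``X`` (and ``A``),
while evaluation criteria compare against the noise-free ``X0``/``Y0``.

Two entry points compose the pipeline: :func:`run_scenario1` generates
the network itself (weighted Erdős–Rényi), while
:func:`run_scenario2_like` starts from a caller-supplied adjacency —
e.g. the synthetic stand-in for an empirically derived
metabolite–protein module from :func:`synthetic_mp_network` — optionally
hard-thresholded to a target sparsity first.

All randomness derives deterministically from a single configuration
seed via named substreams, so end-to-end datasets are bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import AlignmentError, ConfigError
from .network import (
    WeightedNetwork,
    generate_er_network,
    hard_threshold,
    node_degrees,
    read_adjacency,
    write_adjacency,
)
from .summarize import ProfileMatrix, read_profiles, write_profiles

__all__ = [
    "DEFAULT_SIGMA_EPS",
    "DEFAULT_SIGMA_E",
    "DEFAULT_PD_DELTA",
    "SimulationConfig",
    "PrecisionModel",
    "SimulatedDataset",
    "child_seed",
    "make_precision",
    "simulate_true_profiles",
    "simulate_phenotype",
    "perturb_profiles",
    "run_scenario1",
    "run_scenario2_like",
    "synthetic_mp_network",
    "save_dataset",
    "load_dataset",
]

# Default benchmark conditions.  sigma_e is measurement noise on profiles
# whose marginal variance is 1 (Sigma is in correlation form), so the
# default is a deliberately low-signal regime in which the noise-free
# profiles carry most of their variance along one module factor whose
# strength is set by DEFAULT_PD_DELTA; sigma_eps is phenotype noise on the
# degree-weighted signal X0 @ beta.  See docs/methods.md for how these
# were fixed.
DEFAULT_SIGMA_EPS: float = 1.0
DEFAULT_SIGMA_E: float = 2.8
DEFAULT_PD_DELTA: float = 0.03


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated benchmark dataset.

    Parameters
    ----------
    p
        Number of network nodes (features).
    alpha0
        Edge probability of the Erdős–Rényi generator (scenario 1).
    n_master
        Master sample size from which subsamples are drawn.
    sigma_eps
        Standard deviation of the phenotype noise ``eps``.
    sigma_e
        Standard deviation of the elementwise measurement noise ``E``.
    pd_delta
        Diagonal-loading constant added beyond ``|lambda_min(A)|`` to make
        the precision matrix positive definite.  Smaller values put the
        loaded precision closer to singular along one direction, i.e. a
        stronger dominant module factor in the covariance.
    w_low, w_high
        Edge-weight bounds of the uniform weight distribution.
    seed
        Master seed; every substream is derived from it.
    """

    p: int = 30
    alpha0: float = 0.3
    n_master: int = 1000
    sigma_eps: float = DEFAULT_SIGMA_EPS
    sigma_e: float = DEFAULT_SIGMA_E
    pd_delta: float = DEFAULT_PD_DELTA
    w_low: float = 0.1
    w_high: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ConfigError(f"p must be >= 2, got {self.p}")
        if not 0.0 <= self.alpha0 <= 1.0:
            raise ConfigError(f"alpha0 must lie in [0, 1], got {self.alpha0}")
        if self.n_master < 2:
            raise ConfigError(f"n_master must be >= 2, got {self.n_master}")
        if self.sigma_eps < 0 or self.sigma_e < 0:
            raise ConfigError("noise scales must be non-negative")
        if self.pd_delta <= 0:
            raise ConfigError(f"pd_delta must be positive, got {self.pd_delta}")
        if not self.w_low < self.w_high:
            raise ConfigError(
                f"need w_low < w_high, got [{self.w_low}, {self.w_high}]"
            )


@dataclass(frozen=True)
class PrecisionModel:
    """Positive-definite precision matrix and its correlation-form inverse.

    ``precision`` is the diagonally loaded adjacency (sparsity pattern of
    ``A`` preserved off the diagonal); ``covariance`` is its inverse
    rescaled to unit diagonal, the covariance actually used to draw
    profiles.
    """

    precision: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SimulatedDataset:
    """Bundle of everything one benchmark replicate needs."""

    net: WeightedNetwork
    model: PrecisionModel
    X0: ProfileMatrix
    X: ProfileMatrix
    Y0: np.ndarray = field(repr=False)
    beta0: float = 0.0
    beta: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    config: SimulationConfig = field(default_factory=SimulationConfig)


def child_seed(seed: int, name: str) -> int:
    """Derive a named substream seed from a master seed.

    Uses ``SeedSequence([seed, crc32(name)])`` so streams for different
    pipeline stages are statistically independent and the derivation is
    stable across platforms and sessions.  The result is kept below 2**31.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def make_precision(net: WeightedNetwork, pd_delta: float = DEFAULT_PD_DELTA) -> PrecisionModel:
    """Turn an adjacency matrix into a Gaussian graphical model.

    The precision matrix is ``Omega = A + (max(0, -lambda_min(A)) +
    pd_delta) * I``: loading the diagonal just past the most negative
    eigenvalue guarantees positive definiteness while leaving the
    off-diagonal sparsity pattern of ``A`` intact.  The covariance is
    ``Omega^{-1}`` rescaled to unit diagonal (correlation form), so every
    feature has marginal variance 1 and noise scales are comparable
    across features.
    """
    A = net.adjacency
    lam_min = float(np.linalg.eigvalsh(A)[0])
    shift = max(0.0, -lam_min) + pd_delta
    omega = A + shift * np.eye(net.p)
    cov = np.linalg.inv(omega)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    cov = (cov + cov.T) / 2.0  # keep exact symmetry after the rescale
    return PrecisionModel(precision=omega, covariance=cov)


def simulate_true_profiles(
    model: PrecisionModel,
    n: int,
    seed: int | np.random.Generator = 0,
    node_ids: tuple[str, ...] | None = None,
) -> ProfileMatrix:
    """Draw ``n`` iid profiles from ``N(0, Sigma)``.

    Sampling goes through the Cholesky factor of the covariance, so a
    non-positive-definite covariance fails loudly at factorization.
    """
    if n < 2:
        raise ConfigError(f"need n >= 2 subjects, got {n}")
    rng = np.random.default_rng(seed)
    p = model.covariance.shape[0]
    chol = np.linalg.cholesky(model.covariance)
    V = rng.standard_normal((n, p)) @ chol.T
    if node_ids is None:
        node_ids = tuple(f"v{k}" for k in range(p))
    subjects = tuple(f"s{i}" for i in range(n))
    return ProfileMatrix(subject_ids=subjects, feature_ids=node_ids, values=V)


def simulate_phenotype(
    X0: ProfileMatrix,
    net: WeightedNetwork,
    sigma_eps: float = DEFAULT_SIGMA_EPS,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Generate ``Y0 = beta0 + X0 @ beta + eps`` with degree coefficients.

    ``beta[k]`` is the weighted degree of node ``k`` — hubs drive the
    phenotype hardest; ``beta0 ~ N(0, 1)`` is a scalar intercept drawn
    once; ``eps[i] ~ N(0, sigma_eps^2)`` iid.  Returns ``(Y0, beta0,
    beta)``.
    """
    if X0.feature_ids != net.node_ids:
        raise AlignmentError("profile feature labels do not match network node labels")
    rng = np.random.default_rng(seed)
    beta = node_degrees(net)
    beta0 = float(rng.standard_normal())
    eps = rng.normal(0.0, sigma_eps, size=X0.n)
    Y0 = beta0 + X0.values @ beta + eps
    return Y0, beta0, beta


def perturb_profiles(
    X0: ProfileMatrix,
    sigma_e: float = DEFAULT_SIGMA_E,
    seed: int | np.random.Generator = 0,
) -> ProfileMatrix:
    """Add iid ``N(0, sigma_e^2)`` measurement noise elementwise."""
    if sigma_e < 0:
        raise ConfigError(f"sigma_e must be non-negative, got {sigma_e}")
    rng = np.random.default_rng(seed)
    E = rng.normal(0.0, sigma_e, size=X0.values.shape)
    return ProfileMatrix(
        subject_ids=X0.subject_ids, feature_ids=X0.feature_ids, values=X0.values + E
    )


def _finish_dataset(net: WeightedNetwork, config: SimulationConfig) -> SimulatedDataset:
    """Shared downstream pipeline: precision -> X0 -> Y0 -> X."""
    model = make_precision(net, config.pd_delta)
    X0 = simulate_true_profiles(
        model,
        config.n_master,
        seed=child_seed(config.seed, "profiles"),
        node_ids=net.node_ids,
    )
    Y0, beta0, beta = simulate_phenotype(
        X0, net, config.sigma_eps, seed=child_seed(config.seed, "phenotype")
    )
    X = perturb_profiles(X0, config.sigma_e, seed=child_seed(config.seed, "noise"))
    return SimulatedDataset(
        net=net, model=model, X0=X0, X=X, Y0=Y0, beta0=beta0, beta=beta, config=config
    )


def run_scenario1(config: SimulationConfig) -> SimulatedDataset:
    """Random-network benchmark: weighted ER graph, then the GGM pipeline."""
    net = generate_er_network(
        config.p,
        config.alpha0,
        w_low=config.w_low,
        w_high=config.w_high,
        seed=child_seed(config.seed, "network"),
    )
    return _finish_dataset(net, config)


def run_scenario2_like(
    adjacency_source: WeightedNetwork,
    config: SimulationConfig,
    threshold: float | None = None,
) -> SimulatedDataset:
    """Fixed-network benchmark: a supplied adjacency, then the GGM pipeline.

    ``threshold``, if given, hard-thresholds the network first — the
    device used to study the same module at a lower sparsity.  Downstream
    substreams are derived exactly as in :func:`run_scenario1`, so
    feeding an ER network reproduces scenario 1 bit for bit.
    """
    net = adjacency_source
    if threshold is not None:
        net = hard_threshold(net, threshold)
    if net.p != config.p:
        raise ConfigError(
            f"config.p = {config.p} but supplied network has {net.p} nodes"
        )
    return _finish_dataset(net, config)


def synthetic_mp_network(seed: int = 0) -> WeightedNetwork:
    """Synthetic stand-in for an empirically derived metabolite–protein module.

    A 20-node weighted network (7 metabolite nodes ``M1..M7``, 13 protein
    nodes ``P1..P13``) with edge probability 0.51 and Uniform(0.1, 0.8)
    weights, matching the size and sparsity of the multi-omics module the
    benchmark emulates.  The weights are synthetic: no real metabolite or
    protein data enter this package.
    """
    net = generate_er_network(20, 0.51, seed=seed)
    labels = tuple(f"M{k + 1}" for k in range(7)) + tuple(
        f"P{k + 1}" for k in range(13)
    )
    return WeightedNetwork(node_ids=labels, adjacency=net.adjacency)


# ---------------------------------------------------------------------------
# dataset bundle I/O


def save_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Materialize a dataset to a directory of plain-text files.

    Layout: ``adjacency.csv`` (labeled matrix), ``X0.csv`` / ``X.csv``
    (profile CSVs), ``phenotype.tsv`` (subject_id, Y0), ``beta.tsv``
    (node_id, beta; beta0 in the header comment is avoided — beta0 lives
    in config.yaml), and ``config.yaml`` echoing the generating
    configuration for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_adjacency(ds.net, out / "adjacency.csv")
    write_profiles(ds.X0, out / "X0.csv")
    write_profiles(ds.X, out / "X.csv")
    import pandas as pd

    pd.DataFrame({"subject_id": ds.X0.subject_ids, "Y0": ds.Y0}).to_csv(
        out / "phenotype.tsv", sep="\t", index=False
    )
    pd.DataFrame({"node_id": ds.net.node_ids, "beta": ds.beta}).to_csv(
        out / "beta.tsv", sep="\t", index=False
    )
    doc = {"config": asdict(ds.config), "beta0": ds.beta0}
    (out / "config.yaml").write_text(yaml.safe_dump(doc, sort_keys=True))


def load_dataset(in_dir: str | Path) -> SimulatedDataset:
    """Reload a dataset bundle written by :func:`save_dataset`.

    The precision model is rebuilt deterministically from the stored
    adjacency and ``pd_delta``, so the reloaded dataset reproduces the
    in-memory original exactly.
    """
    import pandas as pd

    src = Path(in_dir)
    doc = yaml.safe_load((src / "config.yaml").read_text())
    config = SimulationConfig(**doc["config"])
    net = read_adjacency(src / "adjacency.csv")
    model = make_precision(net, config.pd_delta)
    X0 = read_profiles(src / "X0.csv")
    X = read_profiles(src / "X.csv")
    pheno = pd.read_csv(src / "phenotype.tsv", sep="\t")
    beta = pd.read_csv(src / "beta.tsv", sep="\t")["beta"].to_numpy(dtype=float)
    return SimulatedDataset(
        net=net,
        model=model,
        X0=X0,
        X=X,
        Y0=pheno["Y0"].to_numpy(dtype=float),
        beta0=float(doc["beta0"]),
        beta=beta,
        config=config,
    )


def config_to_json(config: SimulationConfig) -> str:
    """Stable JSON echo of a configuration (provenance records)."""
    return json.dumps(asdict(config), sort_keys=True)
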