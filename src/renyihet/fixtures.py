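"""Seeded synthetic generators for every input class the library consumes.

All generators are pure functions of their arguments (seed included), so
every test and demo runs reproducibly with no external data.  The Gaussian
cluster generator emulates the structure of per-observation posteriors
produced by a probabilistic encoder (mean + covariance per observation);
the beta-mixture sampler performs ancestral sampling from the benchmark's
generative model.
"""

from __future__ import annotations

import math

import numpy as np

from .beta_mixture import BetaMixtureParams, _params
from .core import CategoricalDistribution, SubsystemEnsemble
from .representational import DEFAULT_SEED, GaussianComponentSet

__all__ = [
    "DEFAULT_SEED",
    "random_distribution",
    "disjoint_replication_ensemble",
    "gaussian_cluster_set",
    "bmm_sample",
]


def random_distribution(
    n: int, concentration: float = 1.0, seed: int = DEFAULT_SEED
) -> CategoricalDistribution:
    """Symmetric-Dirichlet draw over n states.

    Large concentration → near-uniform (Π_1 → n); small → near-one-hot.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    return CategoricalDistribution(rng.dirichlet(np.full(n, concentration)))


def disjoint_replication_ensemble(
    N: int,
    block_distribution=None,
    seed: int = DEFAULT_SEED,
) -> SubsystemEnsemble:
    """N equally weighted subsystems on disjoint column blocks.

    Each subsystem carries the same within-block distribution (a Dirichlet
    draw by default), permuted onto its own block of states, so the pooled
    system satisfies the replication principle exactly: between = N.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if block_distribution is None:
        block = random_distribution(4, 2.0, seed).p
    else:
        block = np.asarray(
            block_distribution.p
            if isinstance(block_distribution, CategoricalDistribution)
            else block_distribution,
            dtype=float,
        )
    k = block.size
    P = np.zeros((N, N * k))
    for i in range(N):
        P[i, i * k : (i + 1) * k] = block
    return SubsystemEnsemble(P, np.full(N, 1.0 / N))


def gaussian_cluster_set(
    N: int,
    nz: int,
    separation: float = 1.0,
    covariance_scale: float = 1.0,
    seed: int = DEFAULT_SEED,
    identical_covariances: bool = False,
) -> GaussianComponentSet:
    """N Gaussian components with means on a seeded sphere/lattice.

    ``separation`` scales the spread of the means (latent units);
    ``covariance_scale`` scales random positive-definite covariances
    (latent units²).  separation ≫ covariance_scale gives well-separated
    clusters whose between-heterogeneity approaches N at q=1.
    """
    if N < 1 or nz < 1:
        raise ValueError("N and nz must be >= 1")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((N, nz))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    mu = separation * dirs / norms
    if separation == 0:
        mu = np.zeros((N, nz))

    def random_psd():
        A = rng.standard_normal((nz, nz))
        S = A @ A.T / nz + 0.25 * np.eye(nz)  # bounded away from singular
        return covariance_scale * S

    if identical_covariances:
        S0 = random_psd()
        Sigma = np.stack([S0] * N)
    else:
        Sigma = np.stack([random_psd() for _ in range(N)])
    return GaussianComponentSet(mu, Sigma, np.full(N, 1.0 / N))


def bmm_sample(theta, n: int, seed: int = DEFAULT_SEED):
    """Ancestral draws from the beta mixture: latent labels z then x | z.

    Returns (x, z) with z ∈ {1, 2}; component 2 (weight θ1) has shapes
    (θ3, θ2).
    """
    t = _params(theta)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = np.where(rng.random(n) < t.theta1, 2, 1)
    x = np.empty(n)
    m1 = z == 1
    x[m1] = rng.beta(t.theta2, t.theta3, size=int(m1.sum()))
    x[~m1] = rng.beta(t.theta3, t.theta2, size=int((~m1).sum()))
    return x, z
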