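"""Distance/similarity-sensitive (functional) diversity indices.

Three established numbers-equivalent indices that account for pairwise
dissimilarity between states, not just their probabilities:

* ``numbers_equivalent_qe`` — Ricotta–Szeidl numbers-equivalent quadratic
  entropy, Q̂e = (1 − Q1(D̃, p))⁻¹ with D̃ rescaled to [0, 1];
* ``functional_hill`` — Chiu–Chao functional Hill numbers,
  Fq = [Qq(D,p)/Q1(D,p)]^(1/(2(1−q)));
* ``leinster_cobbold`` — Leinster–Cobbold similarity-sensitive diversity,
  Lq = [Σ_i p_i ((Sp)_i)^(q−1)]^(1/(1−q)).

All three reduce to the categorical Rényi heterogeneity Π_q(p) when the
pairwise structure is categorical (0/1 distances, identity similarity) at
their respective consistency orders.  The module also ships the 3-state
triangle toy family (probability skew κ, triangle height h / base b) that
exposes each comparator's failure modes, and metric / ultrametric checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    CategoricalDistribution,
    ValidationError,
    _Q_ONE_TOL,
    _as_probability_vector,
    _check_order,
    renyi_heterogeneity,
)

__all__ = [
    "DistanceMatrix",
    "SimilarityMatrix",
    "rao_quadratic_entropy",
    "rescale_distance",
    "numbers_equivalent_qe",
    "generalized_rqe",
    "functional_hill",
    "similarity_from_distance",
    "leinster_cobbold",
    "is_metric",
    "is_ultrametric",
    "toy_probability",
    "toy_distance",
]

_SYM_TOL = 1e-9
_TRIANGLE_TOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=_SYM_TOL):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > _SYM_TOL):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(D < 0):
            raise ValidationError("distances must be non-negative")
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarities with unit diagonal."""

    S: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if not np.allclose(S, S.T, atol=_SYM_TOL):
            raise ValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=_SYM_TOL):
            raise ValidationError("similarity matrix diagonal must be 1")
        if np.any(S < 0):
            raise ValidationError("similarities must be non-negative")
        object.__setattr__(self, "S", 0.5 * (S + S.T))

    @property
    def n(self) -> int:
        return self.S.shape[0]


def _dist(D) -> np.ndarray:
    return D.D if isinstance(D, DistanceMatrix) else DistanceMatrix(D).D


def _probs(p) -> np.ndarray:
    return p.p if isinstance(p, CategoricalDistribution) else _as_probability_vector(p)


def rao_quadratic_entropy(D, p) -> float:
    """Rao's quadratic entropy Q1 = Σ_ij D_ij p_i p_j (expected pairwise distance)."""
    D, p = _dist(D), _probs(p)
    if D.shape[0] != p.size:
        raise ValidationError("distance matrix and distribution sizes differ")
    return float(p @ D @ p)


def rescale_distance(D) -> DistanceMatrix:
    """Affine rescale of all entries onto [0, 1] (min over the full matrix)."""
    D = _dist(D)
    lo, hi = D.min(), D.max()
    if hi == lo:
        raise ValidationError("cannot rescale a constant distance matrix")
    return DistanceMatrix((D - lo) / (hi - lo))


def generalized_rqe(D, p, q) -> float:
    """Generalized quadratic entropy Qq = Σ_ij D_ij (p_i p_j)^q.

    At q=0 the 0^0 = 0 convention restricts the sum to pairs with
    p_i p_j > 0, matching the categorical richness convention.
    """
    D, p = _dist(D), _probs(p)
    q = _check_order(q)
    if D.shape[0] != p.size:
        raise ValidationError("distance matrix and distribution sizes differ")
    pp = np.outer(p, p)
    mask = pp > 0
    out = np.zeros_like(pp)
    if q == 0:
        out[mask] = 1.0
    else:
        out[mask] = pp[mask] ** q
    return float((D * out).sum())


def numbers_equivalent_qe(D, p, rescale: bool = True) -> float:
    """Ricotta–Szeidl numbers-equivalent quadratic entropy Q̂e = (1 − Q1)⁻¹.

    By default the distance matrix is first affinely rescaled onto [0, 1]
    (the Ricotta–Szeidl convention that 1 means maximal dissimilarity);
    pass ``rescale=False`` when distances already live on the intended
    [0, 1] scale.  Reduces to the inverse Simpson concentration Π_2(p)
    when D̃ is categorical.
    """
    Dm = _dist(D)
    if rescale:
        Dm = rescale_distance(Dm).D
    q1 = rao_quadratic_entropy(Dm, p)
    if q1 >= 1.0:
        raise ValueError(
            f"Q1 = {q1} >= 1: numbers-equivalent quadratic entropy undefined"
        )
    return 1.0 / (1.0 - q1)


def functional_hill(D, p, q) -> float:
    """Chiu–Chao functional Hill number Fq = [Qq/Q1]^(1/(2(1−q))).

    The q→1 limit is the closed form
    exp(−Σ_ij D_ij p_i p_j log(p_i p_j) / (2 Q1)), obtained by
    differentiating log Qq at q=1.
    """
    Dm, pv = _dist(D), _probs(p)
    q = _check_order(q)
    q1 = rao_quadratic_entropy(Dm, pv)
    if q1 <= 0:
        raise ValueError("Q1 = 0 (degenerate p or zero distances): Fq undefined")
    if math.isinf(q):
        # limit of [Qq/Q1]^{1/(2(1-q))}: dominated by the largest p_i p_j term
        pp = np.outer(pv, pv)
        m = pp[(Dm > 0) & (pp > 0)].max()
        return float(1.0 / math.sqrt(m))
    if abs(q - 1.0) < 1e-9:
        pp = np.outer(pv, pv)
        mask = (pp > 0)
        deriv = (Dm[mask] * pp[mask] * np.log(pp[mask])).sum()
        return float(math.exp(-deriv / (2.0 * q1)))
    qq = generalized_rqe(Dm, pv, q)
    return float((qq / q1) ** (1.0 / (2.0 * (1.0 - q))))


def similarity_from_distance(D, u: float) -> SimilarityMatrix:
    """Exponential-decay transform S_ij = exp(−u D_ij), u >= 0.

    u = 0 gives the all-ones matrix (every state alike); u → ∞ approaches
    the identity (categorical states).
    """
    if u < 0:
        raise ValueError(f"scaling u must be >= 0, got {u}")
    return SimilarityMatrix(np.exp(-u * _dist(D)))


def leinster_cobbold(S, p, q) -> float:
    """Leinster–Cobbold similarity-sensitive diversity of order q.

    Lq = [Σ_i p_i ((Sp)_i)^(q−1)]^(1/(1−q)); q=1 and q=∞ via their
    analytic limits.  With S = I this is exactly Π_q(p).
    """
    S = S.S if isinstance(S, SimilarityMatrix) else SimilarityMatrix(S).S
    p = _probs(p)
    q = _check_order(q)
    if S.shape[0] != p.size:
        raise ValidationError("similarity matrix and distribution sizes differ")
    sp = S @ p
    sup = p > 0
    if math.isinf(q):
        return float(1.0 / sp[sup].max())
    if abs(q - 1.0) < _Q_ONE_TOL:
        return float(math.exp(-(p[sup] * np.log(sp[sup])).sum()))
    return float((p[sup] * sp[sup] ** (q - 1.0)).sum() ** (1.0 / (1.0 - q)))


def is_metric(D, tol: float = _TRIANGLE_TOL) -> bool:
    """True when D satisfies the triangle inequality and identity of indiscernibles."""
    D = _dist(D)
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    if off.size and np.any(off <= tol):
        return False  # distinct states at zero distance
    # d(i,k) <= d(i,j) + d(j,k) for all ordered triples
    bound = (D[:, :, None] + D[None, :, :]).min(axis=1)
    return bool(np.all(D <= bound + tol))


def is_ultrametric(D, tol: float = _TRIANGLE_TOL) -> bool:
    """True when D is a metric also satisfying d(i,k) <= max(d(i,j), d(j,k))."""
    D = _dist(D)
    if not is_metric(D, tol):
        return False
    n = D.shape[0]
    strengthened = np.maximum(D[:, :, None], D[None, :, :])
    # exclude j == i and j == k from the max-bound minimization
    for j in range(n):
        strengthened[j, j, :] = np.inf
        strengthened[:, j, j] = np.inf
    bound = strengthened.min(axis=1)
    return bool(np.all(D <= bound + tol))


def toy_probability(kappa: float) -> CategoricalDistribution:
    """Three-state skew family p(κ) = (1, √κ, κ)/(1 + √κ + κ).

    κ=0 is degenerate on state 1, κ=1 perfectly even, κ→∞ degenerate on
    state 3.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if math.isinf(kappa):
        return CategoricalDistribution(np.array([0.0, 0.0, 1.0]))
    raw = np.array([1.0, math.sqrt(kappa), kappa])
    return CategoricalDistribution(raw / raw.sum())


def toy_distance(h: float, b: float = 1.0) -> DistanceMatrix:
    """Isosceles-triangle distance matrix: base b between states 1–2, apex
    state 3 at height h above the base midpoint.

    Ultrametric iff h >= b√3/2 (apex at least as far as the equilateral
    height), otherwise merely metric.
    """
    if h <= 0 or b <= 0:
        raise ValueError("h and b must be positive")
    side = math.sqrt(b * b / 4.0 + h * h)
    return DistanceMatrix(
        np.array([[0.0, b, side], [b, 0.0, side], [side, side, 0.0]])
    )
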