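"""Categorical Rényi heterogeneity (Hill numbers) and its decomposition.

The Rényi heterogeneity of order ``q`` of a probability vector ``p`` over
``n`` discrete states is

    Pi_q(p) = (sum_i p_i^q)^(1/(1-q)),

the exponential of Rényi entropy.  Its units are the *numbers equivalent*:
the number of states of an idealized uniform system with the same
heterogeneity.  Special orders recover classical indices: observed richness
(q=0), perplexity (q=1, as a limit), inverse Simpson concentration (q=2) and
the Berger–Parker diversity (q=∞).

A weighted collection of subsystems (rows of a row-stochastic matrix P with
weights w) decomposes multiplicatively as pooled = within × between, where
"between" is the effective number of completely distinct subsystems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CategoricalDistribution",
    "SubsystemEnsemble",
    "HeterogeneityDecomposition",
    "renyi_heterogeneity",
    "derived_indices",
    "pooled_heterogeneity",
    "within_heterogeneity",
    "between_heterogeneity",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9
_WEIGHT_TOL = 1e-6
#: |q - 1| below this is treated as the q -> 1 (perplexity) limit.
_Q_ONE_TOL = 1e-10


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _as_probability_vector(p, tol: float = _PROB_TOL) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size < 1:
        raise ValidationError("probability vector must have at least one state")
    if np.any(p < 0):
        raise ValidationError("probabilities must be non-negative")
    s = p.sum()
    if abs(s - 1.0) > tol:
        raise ValidationError(f"probabilities must sum to 1 (got {s!r})")
    return p


def _check_order(q: float) -> float:
    q = float(q)
    if math.isnan(q) or q < 0:
        raise ValueError(f"order q must be >= 0, got {q}")
    return q


@dataclass(frozen=True)
class CategoricalDistribution:
    """Probability vector over ``n`` discrete states."""

    p: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p", _as_probability_vector(self.p))

    @property
    def n(self) -> int:
        return self.p.size


@dataclass(frozen=True)
class SubsystemEnsemble:
    """N subsystems over a shared event space: row-stochastic P and weights w.

    Weights summing to within 1e-6 of one are renormalized (file round-off);
    anything further off is rejected.
    """

    P: np.ndarray
    w: np.ndarray | None = None

    def __post_init__(self):
        P = np.atleast_2d(np.asarray(self.P, dtype=float))
        if P.ndim != 2:
            raise ValidationError("P must be a 2-D matrix")
        for i, row in enumerate(P):
            try:
                _as_probability_vector(row)
            except ValidationError as exc:
                raise ValidationError(f"row {i} of P invalid: {exc}") from exc
        if self.w is None:
            w = np.full(P.shape[0], 1.0 / P.shape[0])
        else:
            w = np.asarray(self.w, dtype=float).ravel()
            if w.size != P.shape[0]:
                raise ValidationError("weights length must match number of rows")
            if np.any(w < 0):
                raise ValidationError("weights must be non-negative")
            s = w.sum()
            if abs(s - 1.0) > _WEIGHT_TOL:
                raise ValidationError(f"weights must sum to 1 (got {s!r})")
            w = w / s
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "w", w)

    @property
    def N(self) -> int:
        return self.P.shape[0]

    @property
    def n(self) -> int:
        return self.P.shape[1]

    def pooled_distribution(self) -> CategoricalDistribution:
        """Mixture p̄ = Σ_i w_i p_i."""
        return CategoricalDistribution(self.w @ self.P)


@dataclass(frozen=True)
class HeterogeneityDecomposition:
    """Multiplicative decomposition pooled = within × between at order q."""

    q: float
    pooled: float
    within: float
    between: float = field(default=math.nan)

    def __post_init__(self):
        if math.isnan(self.between):
            object.__setattr__(self, "between", self.pooled / self.within)

    def as_dict(self) -> dict:
        return {
            "q": self.q,
            "pooled": self.pooled,
            "within": self.within,
            "between": self.between,
        }


def _log_power_sum(p: np.ndarray, q: float) -> float:
    """log(sum_i p_i^q) over the support of p, in log space.

    The 0^0 = 0 convention makes the q=0 case the observed richness.
    """
    support = p[p > 0]
    if support.size == 0:
        raise ValidationError("distribution has empty support")
    if q == 0:
        return math.log(support.size)
    logs = q * np.log(support)
    m = logs.max()
    return m + math.log(np.exp(logs - m).sum())


def renyi_heterogeneity(p, q) -> float:
    """Rényi heterogeneity (Hill number) of order q, in numbers equivalent.

    Parameters
    ----------
    p : array-like or CategoricalDistribution
        Probability vector over discrete states.
    q : float
        Elasticity order, q >= 0.  ``numpy.inf`` gives the Berger–Parker
        limit 1/max(p); |q-1| < 1e-10 is evaluated as the perplexity limit.

    Returns
    -------
    float in [1, n].
    """
    if isinstance(p, CategoricalDistribution):
        p = p.p
    else:
        p = _as_probability_vector(p)
    q = _check_order(q)
    if math.isinf(q):
        return 1.0 / p.max()
    if abs(q - 1.0) < _Q_ONE_TOL:
        support = p[p > 0]
        return float(math.exp(-(support * np.log(support)).sum()))
    return float(math.exp(_log_power_sum(p, q) / (1.0 - q)))


def derived_indices(p, q) -> dict:
    """Classical diversity/inequality indices derived from Pi_q.

    Returns a dict with the fixed-order indices (richness, perplexity,
    inverse Simpson, Berger–Parker, Simpson concentration, Gini–Simpson,
    Shannon entropy) and the q-dependent ones (Rényi entropy, Tsallis
    entropy, generalized entropy index) evaluated at the given order.
    Tsallis and the GEI at q=1 are the analytic limits (Shannon entropy and
    the Theil index respectively); the GEI requires q > 0.
    """
    if isinstance(p, CategoricalDistribution):
        p = p.p
    else:
        p = _as_probability_vector(p)
    q = _check_order(q)
    n = p.size
    pi_q = renyi_heterogeneity(p, q)
    pi_1 = renyi_heterogeneity(p, 1.0)
    pi_2 = renyi_heterogeneity(p, 2.0)
    shannon = math.log(pi_1)
    out = {
        "richness": renyi_heterogeneity(p, 0.0),
        "perplexity": pi_1,
        "inverse_simpson": pi_2,
        "berger_parker": renyi_heterogeneity(p, math.inf),
        "renyi_entropy": math.log(pi_q),
        "shannon_entropy": shannon,
        "simpson_concentration": 1.0 / pi_2,
        "gini_simpson": 1.0 - 1.0 / pi_2,
    }
    if abs(q - 1.0) < _Q_ONE_TOL:
        out["tsallis_entropy"] = shannon
        out["generalized_entropy_index"] = math.log(n) - shannon
    else:
        out["tsallis_entropy"] = (1.0 - pi_q ** (1.0 - q)) / (q - 1.0)
        if q > 0 and not math.isinf(q):
            out["generalized_entropy_index"] = (
                ((pi_q / n) ** (1.0 - q) - 1.0) / (q * (q - 1.0))
            )
        else:
            out["generalized_entropy_index"] = math.nan
    return out


def pooled_heterogeneity(e: SubsystemEnsemble, q) -> float:
    """Pi_q of the weighted mixture p̄ = Σ w_i p_i (effective pooled states)."""
    return renyi_heterogeneity(e.pooled_distribution(), q)


def within_heterogeneity(e: SubsystemEnsemble, q) -> float:
    """Effective number of unique states contributed per subsystem (Jost).

    General q:  [ Σ_i w_i^q (Σ_j p_ij^q) / Σ_k w_k^q ]^(1/(1-q)).
    q=1 is the limit exp(Σ_i w_i H(p_i)); q=∞ the direct limit of the
    formula, max_k w_k / max_{i,j} (w_i p_ij).  Zero-weight subsystems are
    excluded throughout (0^0 = 0 for weights at q=0).
    """
    q = _check_order(q)
    keep = e.w > 0
    w, P = e.w[keep], e.P[keep]
    if math.isinf(q):
        return float(w.max() / (P * w[:, None]).max())
    if abs(q - 1.0) < _Q_ONE_TOL:
        ent = np.array(
            [-(row[row > 0] * np.log(row[row > 0])).sum() for row in P]
        )
        return float(math.exp((w * ent).sum()))
    # log-space: log Σ_i exp(q log w_i + log Σ_j p_ij^q), minus log Σ w_k^q
    row_logs = np.array([_log_power_sum(row, q) for row in P])
    num_logs = q * np.log(w) + row_logs
    m = num_logs.max()
    log_num = m + math.log(np.exp(num_logs - m).sum())
    log_den = _log_power_sum(w, q)
    return float(math.exp((log_num - log_den) / (1.0 - q)))


def between_heterogeneity(e: SubsystemEnsemble, q) -> HeterogeneityDecomposition:
    """Full pooled/within/between decomposition at order q.

    Between = pooled / within is the effective number of completely
    distinct subsystems.  With unequal weights the decomposition is only
    guaranteed to satisfy within <= pooled at q=0 and q=1 (Jost's
    condition); a log warning is emitted outside that regime.
    """
    q = _check_order(q)
    if not np.allclose(e.w, e.w[0]) and q not in (0.0, 1.0):
        logger.warning(
            "between-heterogeneity with unequal weights is only guaranteed "
            ">= 1 at q=0 or q=1 (got q=%s)", q,
        )
    pooled = pooled_heterogeneity(e, q)
    within = within_heterogeneity(e, q)
    return HeterogeneityDecomposition(q=q, pooled=pooled, within=within)
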