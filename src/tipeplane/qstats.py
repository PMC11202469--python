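"""Tsallis q-entropy, q-deformed Jensen-Shannon disequilibrium, and
statistical complexity.

The entropy is the Tsallis form ``S_q = sum_j P_j ln_q(1/P_j)`` with the
q-logarithm ``ln_q x = (x**(1-q) - 1) / (1-q)`` (natural log at ``q = 1``),
normalized by its maximum ``ln_q(n)`` over ``n`` states.  The disequilibrium
is a q-deformed Jensen-Shannon divergence between the pattern distribution
``P`` and the uniform reference ``U``:

    D_q(P, U) = 1/2 K_q(P || M) + 1/2 K_q(U || M),   M = (P + U) / 2,
    K_q(A || B) = -sum_{A_j > 0} A_j ln_q(B_j / A_j),

normalized by its maximum over distributions, attained when all mass sits on
a single state.  At ``q = 1`` this is exactly the classical Jensen-Shannon
divergence.  Statistical complexity is the product ``C_q = Delta_q * H_q``;
it vanishes both for the uniform distribution (no structure) and for a point
mass (no uncertainty).

All power terms are evaluated as ``exp((1-q) * log(x))``.  Every ratio fed to
the q-logarithm inside ``K_q`` is at least 1/2 (the midpoint ``M`` dominates
half of either argument), so the largest magnitude ever exponentiated is
``2**(q-1)`` -- finite in float64 for the whole supported range ``q <= 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .symbolize import PatternDistribution

__all__ = [
    "QCurve",
    "EntropyComplexityPoint",
    "q_log",
    "tsallis_entropy",
    "max_tsallis_entropy",
    "normalized_tipe",
    "q_jsd",
    "max_q_jsd",
    "disequilibrium",
    "statistical_complexity",
    "entropy_complexity_curve",
]

#: |q - 1| below which the Shannon (logarithmic) limit branch is used.
_Q_ONE_TOL = 1e-9


def _check_q(q: float) -> float:
    q = float(q)
    if q < 0:
        raise ValueError(f"q must be nonnegative, got {q}")
    return q


def q_log(x, q: float):
    """q-deformed logarithm ``(x**(1-q) - 1) / (1-q)``, natural log at q=1.

    Accepts a scalar or array ``x``; all entries must be strictly positive.
    Within ``1e-9`` of ``q = 1`` the logarithmic limit is used for numerical
    continuity.
    """
    q = _check_q(q)
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("q_log is defined for positive arguments only")
    if abs(q - 1.0) < _Q_ONE_TOL:
        out = np.log(arr)
    else:
        out = np.expm1((1.0 - q) * np.log(arr)) / (1.0 - q)
    return out if arr.ndim else float(out)


def _probs(P) -> np.ndarray:
    if isinstance(P, PatternDistribution):
        return P.probabilities
    arr = np.asarray(P, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D probability vector")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    return arr


def tsallis_entropy(P, q: float) -> float:
    """Tsallis entropy ``S_q = sum_{P_j > 0} P_j ln_q(1/P_j)``.

    Zero-probability states contribute nothing (limit convention).  Equals
    Shannon entropy ``-sum P_j ln P_j`` at ``q = 1`` and is maximized, at
    ``ln_q(n)``, by the uniform distribution over ``n`` states.
    """
    p = _probs(P)
    nz = p[p > 0]
    return float(np.sum(nz * q_log(1.0 / nz, q)))


def max_tsallis_entropy(state_count: int, q: float) -> float:
    """Maximum of the Tsallis entropy over ``state_count`` states: ``ln_q(n)``."""
    if state_count < 2:
        raise ValueError("need at least 2 states for a nonzero entropy range")
    return float(q_log(float(state_count), q))


def normalized_tipe(P, q: float) -> float:
    """Normalized Tsallis improved-permutation entropy ``H_q = S_q / ln_q(n)``.

    Lies in [0, 1]: 0 for a point mass, 1 for the uniform distribution.
    """
    p = _probs(P)
    return tsallis_entropy(p, q) / max_tsallis_entropy(p.size, q)


def _q_kullback(A: np.ndarray, B: np.ndarray, q: float) -> float:
    """K_q(A || B) = -sum_{A_j > 0} A_j ln_q(B_j / A_j)."""
    mask = A > 0
    return float(-np.sum(A[mask] * q_log(B[mask] / A[mask], q)))


def q_jsd(P, Q_dist, q: float) -> float:
    """q-deformed Jensen-Shannon divergence between two distributions.

    Symmetrized q-Kullback divergence of each argument against their midpoint
    ``M = (P + Q) / 2``.  Reduces to the classical Jensen-Shannon divergence
    at ``q = 1``; symmetric and nonnegative for all ``q >= 0``.

    The q-deformation of the Jensen-Shannon divergence is not unique; this
    kernel orientation is isolated here so it can be swapped wholesale.
    """
    p = _probs(P)
    u = _probs(Q_dist)
    if p.size != u.size:
        raise ValueError(f"state counts differ: {p.size} vs {u.size}")
    m = 0.5 * (p + u)
    d = 0.5 * _q_kullback(p, m, q) + 0.5 * _q_kullback(u, m, q)
    return max(d, 0.0)  # clamp roundoff-negative zeros


def max_q_jsd(state_count: int, q: float) -> float:
    """Maximum q-JSD against the uniform reference over ``state_count`` states.

    Attained by a point-mass distribution (any state, by symmetry of the
    uniform reference); strictly positive.
    """
    if state_count < 2:
        raise ValueError("need at least 2 states")
    n = state_count
    u = 1.0 / n
    # K_q(delta || M): single term, A=1, B=(1+u)/2.
    k_delta = -float(q_log((1.0 + u) / 2.0, q))
    # K_q(U || M): one state with B=(1+u)/2, the other n-1 with B=u/2.
    k_unif = -(u * float(q_log((1.0 + u) / (2.0 * u), q))
               + (n - 1) * u * float(q_log(0.5, q)))
    return 0.5 * k_delta + 0.5 * k_unif


def disequilibrium(P, q: float) -> float:
    """Normalized distance from the uniform distribution, in [0, 1].

    ``Delta_q = D_q(P, U) / D_q*`` where ``D_q*`` is the point-mass maximum.
    0 for the uniform distribution, 1 for a point mass.
    """
    p = _probs(P)
    return q_jsd(p, np.full(p.size, 1.0 / p.size), q) / max_q_jsd(p.size, q)


@dataclass(frozen=True)
class EntropyComplexityPoint:
    """All q-statistics of one distribution at one value of q."""

    q: float
    Sq: float          # raw Tsallis entropy
    Hq: float          # normalized entropy, in [0, 1]
    Dq: float          # q-JSD between P and the uniform reference
    Dq_star: float     # maximum q-JSD (point-mass value), the normalizer
    delta_q: float     # disequilibrium Dq / Dq_star, in [0, 1]
    Cq: float          # statistical complexity delta_q * Hq


def statistical_complexity(P, q: float) -> EntropyComplexityPoint:
    """Statistical complexity ``C_q = Delta_q * H_q`` with all intermediates."""
    p = _probs(P)
    q = _check_q(q)
    Sq = tsallis_entropy(p, q)
    Hq = Sq / max_tsallis_entropy(p.size, q)
    Dq = q_jsd(p, np.full(p.size, 1.0 / p.size), q)
    Dstar = max_q_jsd(p.size, q)
    delta = Dq / Dstar
    return EntropyComplexityPoint(q=q, Sq=Sq, Hq=Hq, Dq=Dq, Dq_star=Dstar,
                                  delta_q=delta, Cq=delta * Hq)


@dataclass(frozen=True)
class QCurve:
    """Vectorized q-statistics of one distribution over a q grid."""

    q: np.ndarray
    Hq: np.ndarray
    Cq: np.ndarray
    delta_q: np.ndarray


def _q_log_grid(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    """q_log of positive values ``x`` (k,) at every grid point ``q`` (Q,) -> (Q, k)."""
    one_minus_q = (1.0 - q)[:, None]
    log_x = np.log(x)[None, :]
    near_one = np.abs(one_minus_q) < _Q_ONE_TOL
    denom = np.where(near_one, 1.0, one_minus_q)
    return np.where(near_one, log_x, np.expm1(one_minus_q * log_x) / denom)


def entropy_complexity_curve(P, q_values: np.ndarray) -> QCurve:
    """Compute ``H_q`` and ``C_q`` for one distribution over a whole q grid.

    Equivalent to calling :func:`statistical_complexity` at every grid point,
    but aggregated over the distinct probability values of ``P`` (symbol
    frequencies take few distinct values) and vectorized over q, which makes
    dense grids such as 0..100 in steps of 0.001 cheap.
    """
    p = _probs(P)
    q = np.asarray(q_values, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q grid must be a nonempty 1-D array")
    if np.any(q < 0):
        raise ValueError("q grid must be nonnegative")
    n = p.size
    u = 1.0 / n
    vals, counts = np.unique(p[p > 0], return_counts=True)
    n_zero = n - counts.sum()

    Sq = (counts * vals * _q_log_grid(1.0 / vals, q)).sum(axis=1)
    Smax = _q_log_grid(np.array([float(n)]), q)[:, 0]
    Hq = Sq / Smax

    mid = 0.5 * (vals + u)
    k_pm = -(counts * vals * _q_log_grid(mid / vals, q)).sum(axis=1)
    k_um = -(counts * u * _q_log_grid(mid / u, q)).sum(axis=1)
    if n_zero > 0:
        k_um -= n_zero * u * _q_log_grid(np.array([0.5]), q)[:, 0]
    Dq = np.maximum(0.5 * k_pm + 0.5 * k_um, 0.0)

    k_delta = -_q_log_grid(np.array([(1.0 + u) / 2.0]), q)[:, 0]
    k_unif = -(u * _q_log_grid(np.array([(1.0 + u) / (2.0 * u)]), q)[:, 0]
               + (n - 1) * u * _q_log_grid(np.array([0.5]), q)[:, 0])
    Dstar = 0.5 * k_delta + 0.5 * k_unif

    delta = Dq / Dstar
    return QCurve(q=q, Hq=Hq, Cq=delta * Hq, delta_q=delta)
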