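"""Tamura-92-type substitution process parameterized by equilibrium GC.

The branch-level model has two parameters: theta, the equilibrium GC
content the branch evolves toward (theta is exactly the GC* of that
branch: the AT->GC substitution rate over the sum of both directional
rates), and kappa, the transition/transversion rate ratio.  Rate
heterogeneity across sites uses the discrete-gamma approximation with
equal-weight categories whose rates are the category means, normalized
to mean 1.

The process on a single branch is time-reversible with respect to its
own equilibrium; non-stationarity and non-homogeneity enter at the tree
level, through a free root composition and branch-class-specific theta.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

# state order used throughout
A, C, G, T = 0, 1, 2, 3
TRANSITIONS = {(A, G), (G, A), (C, T), (T, C)}


def stationary_distribution(theta: float) -> np.ndarray:
    """T92 equilibrium base frequencies (A, C, G, T) for GC content theta."""
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0,1), got {theta}")
    return np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])


def rate_matrix(theta: float, kappa: float) -> np.ndarray:
    """4x4 generator Q with equilibrium GC theta and Ts/Tv ratio kappa.

    q(i->j) is proportional to kappa*pi_j for transitions and pi_j for
    transversions; rows sum to zero.  Q is scaled so the expected
    substitution rate at its own equilibrium is 1 per site, which keeps
    branch lengths comparable across branches with different theta.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    pi = stationary_distribution(theta)
    q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = (kappa if (i, j) in TRANSITIONS else 1.0) * pi[j]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ np.diag(q))
    return q / mu


def gc_star_from_rates(q: np.ndarray) -> float:
    """Equilibrium GC frequency of a generator: AT->GC / (AT->GC + GC->AT).

    Rates are per-site directional substitution rates: from an AT state
    into {C,G}, and from a GC state into {A,T}.  For the T92 generator
    this equals theta exactly.
    """
    at_to_gc = q[A, C] + q[A, G]  # == q[T, C] + q[T, G] by symmetry
    gc_to_at = q[C, A] + q[C, T]  # == q[G, A] + q[G, T]
    return gc_star(at_to_gc, gc_to_at)


def gc_star(rate_at_to_gc: float, rate_gc_to_at: float) -> float:
    """GC* from the two directional substitution rates."""
    if rate_at_to_gc < 0 or rate_gc_to_at < 0:
        raise ValueError("substitution rates must be non-negative")
    total = rate_at_to_gc + rate_gc_to_at
    if total == 0:
        raise ValueError("GC* undefined: both directional rates are zero")
    return rate_at_to_gc / total


def transition_probabilities(theta: float, kappa: float, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the T92 generator, via symmetric eigendecomposition.

    The generator is reversible, so D^{1/2} Q D^{-1/2} is symmetric
    (D = diag(pi)) and the exponential is numerically exact and stable.
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    q = rate_matrix(theta, kappa)
    return _expm_reversible(q, stationary_distribution(theta), t)


def _expm_reversible(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    d = np.sqrt(pi)
    sym = (q * d[:, None]) / d[None, :]
    w, v = np.linalg.eigh((sym + sym.T) / 2)
    p = (v * np.exp(w * t)) @ v.T
    p = (p / d[:, None]) * d[None, :]
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


class BranchProcess:
    """Cached eigendecomposition for repeated P(t) evaluation at fixed (theta, kappa)."""

    def __init__(self, theta: float, kappa: float):
        self.theta = theta
        self.kappa = kappa
        self.pi = stationary_distribution(theta)
        self.q = rate_matrix(theta, kappa)
        d = np.sqrt(self.pi)
        sym = (self.q * d[:, None]) / d[None, :]
        self._w, self._v = np.linalg.eigh((sym + sym.T) / 2)
        self._d = d

    def p_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        p = (self._v * np.exp(self._w * t)) @ self._v.T
        p = (p / self._d[:, None]) * self._d[None, :]
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)


def discrete_gamma_rates(alpha: float, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight discrete-gamma category rates (category means), mean 1.

    Categories are the k equal-probability quantile bands of a
    Gamma(alpha, mean 1) distribution; each category's rate is the
    conditional mean over its band, renormalized so the weighted mean is
    exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1), np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], edges * alpha, [np.inf]])
    # E[X; band] for X ~ Gamma(alpha, rate alpha) via the alpha+1 CDF identity
    upper = np.where(np.isinf(cuts), 1.0, gammainc(alpha + 1, cuts))
    rates = k * np.diff(upper)
    weights = np.full(k, 1.0 / k)
    rates = rates / (rates @ weights)
    return rates, weights
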