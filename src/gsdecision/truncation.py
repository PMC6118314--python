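"""Truncated-normal and truncated-multivariate-normal selection theory.

Upper-tail truncation selection keeps the individuals whose (phenotypic or
predicted) value exceeds a threshold ``yc``.  The selected group then follows
a left-truncated normal distribution, and the classic quantities of selection
theory — the truncation probability ``z``, the selected-parent mean ``muS``,
the selection differential ``S = muS - mu1`` and the selection intensity
``i = S / sigma`` — are simple functions of the base-population mean and
variance.  This module computes those quantities in one and several
dimensions; everything downstream (the loss functions, the expected-loss
ranking, the breeding simulator) builds on it.

For several traits the selected group follows a truncated multivariate
normal (TMVN) over the upper orthant ``{y : y >= yc}``.  The orthant
probability is evaluated with scipy's Genz quasi-Monte-Carlo quadrature, and
the TMVN mean with the Tallis moment reduction, which expresses each
first moment through univariate densities and (t-1)-dimensional orthant
probabilities; a seeded rejection-sampling estimator is provided as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    CovarianceError,
    DegenerateTruncationError,
    InvalidPressureError,
)

#: below this truncation probability the selected-tail moments are treated
#: as numerically undefined
DEGENERATE_Z = 1e-12


@dataclass(frozen=True)
class TruncationSummary:
    """Base-population and selected-tail summary for one trait.

    Attributes
    ----------
    mu1 : base-population mean
    sigma2 : base-population (phenotypic) variance, > 0
    yc : truncation threshold (may be ``-inf`` for "no truncation")
    z : truncation probability ``Pr(Y > yc)`` in (0, 1]
    muS : mean of the selected parents, ``E[Y | Y >= yc]``
    S : selection differential ``muS - mu1``
    i : selection intensity ``S / sigma``
    """

    mu1: float
    sigma2: float
    yc: float
    z: float
    muS: float
    S: float
    i: float

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))


@dataclass(frozen=True)
class MvTruncationSummary:
    """Multi-trait analog of :class:`TruncationSummary`.

    ``P`` is the phenotypic covariance of the base population, ``z`` the
    orthant probability ``Pr(Y >= yc)``, ``muS`` the TMVN mean and
    ``S = muS - mu1`` the selection-differential vector.  When a genotypic
    covariance ``G`` is supplied, the response vector follows the matrix
    breeder's equation ``R = G P^-1 S`` (so ``R = S`` when ``G = P``).
    """

    mu1: np.ndarray
    P: np.ndarray
    yc: np.ndarray
    z: float
    muS: np.ndarray
    S: np.ndarray
    G: np.ndarray | None = None
    R: np.ndarray | None = None


def _validate_cov(P: np.ndarray, name: str = "P") -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise CovarianceError(f"{name} must be a square matrix, got shape {P.shape}")
    if not np.allclose(P, P.T, atol=1e-10):
        raise CovarianceError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(P)
    except np.linalg.LinAlgError as exc:
        raise CovarianceError(f"{name} is not positive definite") from exc
    return P


def truncation_point_from_pressure(mu1: float, sigma2: float, q: float) -> float:
    """Threshold ``yc`` with ``Pr(Y > yc) = q`` under ``N(mu1, sigma2)``.

    ``q`` is the selection pressure: the fraction of the base population
    retained above the threshold.
    """
    if not 0.0 < q < 1.0:
        raise InvalidPressureError(f"selection pressure must be in (0, 1), got {q}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    return float(mu1 + np.sqrt(sigma2) * stats.norm.isf(q))


def truncated_normal_summary(mu1: float, sigma2: float, yc: float) -> TruncationSummary:
    """Selected-tail moments for left truncation at ``yc``.

    ``z = 1 - Phi(d)`` and ``muS = mu1 + sigma * phi(d) / (1 - Phi(d))`` with
    ``d = (yc - mu1) / sigma``; the intensity ``i = phi(d)/(1 - Phi(d))`` is
    the inverse Mills ratio.  ``yc = -inf`` gives the untruncated limit
    ``z = 1, muS = mu1, i = 0``.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    sigma = float(np.sqrt(sigma2))
    d = (yc - mu1) / sigma
    z = float(stats.norm.sf(d))
    if z < DEGENERATE_Z:
        raise DegenerateTruncationError(
            f"truncation probability {z:.3e} below {DEGENERATE_Z:.0e}; "
            f"threshold {yc} is too far in the upper tail"
        )
    i = float(stats.norm.pdf(d)) / z
    muS = mu1 + sigma * i
    return TruncationSummary(
        mu1=float(mu1), sigma2=float(sigma2), yc=float(yc),
        z=z, muS=float(muS), S=float(muS - mu1), i=i,
    )


def summary_from_pressure(mu1: float, sigma2: float, q: float) -> TruncationSummary:
    """Convenience: derive ``yc`` from the pressure, then summarize."""
    return truncated_normal_summary(mu1, sigma2, truncation_point_from_pressure(mu1, sigma2, q))


def mvn_orthant_probability(
    mu1: np.ndarray,
    P: np.ndarray,
    yc: np.ndarray,
    *,
    method: str = "quadrature",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> float:
    """``Pr(Y >= yc)`` for ``Y ~ MVN(mu1, P)``.

    ``method="quadrature"`` (default) uses scipy's Genz algorithm through the
    identity ``Pr(Y >= yc) = Phi_P(mu1 - yc)`` for the centered, sign-flipped
    vector; ``method="mc"`` uses plain seeded Monte Carlo with ``n_samples``
    draws.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    yc = np.atleast_1d(np.asarray(yc, dtype=float))
    P = _validate_cov(np.atleast_2d(P))
    if not (mu1.shape[0] == yc.shape[0] == P.shape[0]):
        raise CovarianceError("mu1, yc and P dimensions disagree")
    t = mu1.shape[0]
    if t == 1:
        return float(stats.norm.sf(yc[0], loc=mu1[0], scale=np.sqrt(P[0, 0])))
    if method == "mc":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(mu1, P, size=n_samples)
        return float(np.mean(np.all(draws >= yc, axis=1)))
    # -Y + mu1 ~ MVN(0, P); {Y >= yc} = {-(Y - mu1) <= mu1 - yc}
    dist = stats.multivariate_normal(mean=np.zeros(t), cov=P, allow_singular=False)
    return float(np.clip(dist.cdf(mu1 - yc), 0.0, 1.0))


def _tallis_q(mu1: np.ndarray, P: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Tallis reduction vector q with E[Y] = mu1 + P q / z for Y >= yc."""
    t = mu1.shape[0]
    q = np.zeros(t)
    for k in range(t):
        if not np.isfinite(yc[k]):
            continue  # no truncation on trait k contributes nothing
        s_k = np.sqrt(P[k, k])
        f_k = stats.norm.pdf(yc[k], loc=mu1[k], scale=s_k)
        if t == 1:
            q[k] = f_k
            continue
        rest = [j for j in range(t) if j != k]
        # conditional law of the remaining traits given Y_k = yc_k
        b = P[rest, k] / P[k, k]
        mu_c = mu1[rest] + b * (yc[k] - mu1[k])
        P_c = P[np.ix_(rest, rest)] - np.outer(b, P[k, rest])
        P_c = 0.5 * (P_c + P_c.T)
        p_k = mvn_orthant_probability(mu_c, P_c, yc[rest])
        q[k] = f_k * p_k
    return q


def tmvn_mean(
    mu1: np.ndarray,
    P: np.ndarray,
    yc: np.ndarray,
    *,
    method: str = "tallis",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """Mean of ``Y ~ MVN(mu1, P)`` restricted to the orthant ``Y >= yc``.

    The default evaluates the Tallis moment identity exactly (up to the
    orthant quadrature); ``method="mc"`` uses seeded rejection sampling,
    drawing batches until ``n_samples`` accepted vectors are collected.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    yc = np.atleast_1d(np.asarray(yc, dtype=float))
    P = _validate_cov(np.atleast_2d(P))
    z = mvn_orthant_probability(mu1, P, yc)
    if z < DEGENERATE_Z:
        raise DegenerateTruncationError(
            f"orthant probability {z:.3e} below {DEGENERATE_Z:.0e}"
        )
    if method == "mc":
        rng = np.random.default_rng(seed)
        accepted: list[np.ndarray] = []
        n_acc = 0
        # batch size adapted to the acceptance rate
        batch = int(min(2_000_000, max(10_000, 4 * n_samples / max(z, 1e-6))))
        while n_acc < n_samples:
            draws = rng.multivariate_normal(mu1, P, size=batch)
            keep = draws[np.all(draws >= yc, axis=1)]
            accepted.append(keep)
            n_acc += keep.shape[0]
        return np.concatenate(accepted)[:n_samples].mean(axis=0)
    return mu1 + P @ _tallis_q(mu1, P, yc) / z


def mv_truncation_summary(
    mu1: np.ndarray,
    P: np.ndarray,
    yc: np.ndarray,
    G: np.ndarray | None = None,
) -> MvTruncationSummary:
    """Orthant probability, TMVN mean, differential and (optional) response.

    With a genotypic covariance ``G``, the response vector is the matrix
    breeder's equation ``R = G P^-1 S``.
    """
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    yc = np.atleast_1d(np.asarray(yc, dtype=float))
    P = _validate_cov(np.atleast_2d(P))
    z = mvn_orthant_probability(mu1, P, yc)
    if z < DEGENERATE_Z:
        raise DegenerateTruncationError(
            f"orthant probability {z:.3e} below {DEGENERATE_Z:.0e}"
        )
    muS = mu1 + P @ _tallis_q(mu1, P, yc) / z
    S = muS - mu1
    R = None
    if G is not None:
        G = np.atleast_2d(np.asarray(G, dtype=float))
        R = G @ np.linalg.solve(P, S)
    return MvTruncationSummary(mu1=mu1, P=P, yc=yc, z=float(z), muS=muS, S=S, G=G, R=R)
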