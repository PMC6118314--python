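"""Loss functions over predictive breeding-value distributions.

Six losses score a selection candidate against the truncated distribution of
the selected parents.  Writing ``mu1, sigma2`` for the base population,
``muS`` for the selected-parent mean, ``mu2`` for the candidate mean,
``S = muS - mu1``, ``R = mu2 - mu1`` and ``e = muS - mu2 = S - R``:

* ``kl_univariate`` — Kullback-Leibler divergence between the candidate
  normal and the left-truncated parent normal,
  ``-log z + [(muS - mu2)^2 - (muS - mu1)^2] / (2 sigma^2)``.
* ``kl_univariate_h2`` — the same loss written through the selection
  intensity and heritability, ``-log z + i^2 h2 (h2 - 2) / 2`` (using
  ``R = h2 S``); a strictly decreasing function of ``h2``.
* ``crps_univariate`` — continuous ranked probability score of the candidate
  normal against the point target ``muS``.
* ``linlin`` — the pinball (quantile) loss ``(alpha - 1[e < 0]) e``,
  asymmetric for ``alpha != 0.5``.
* ``kl_multivariate`` — multivariate KL against the orthant-truncated MVN.
* ``energy_score`` — sample-based Energy Score (the multivariate CRPS).
* ``malf`` — multivariate asymmetric loss, L2 form ``(||e|| + tau'e) ||e||``
  or L1 form ``sum|e_k| + tau'e``; univariately, the L1 form with
  ``tau = 2 alpha - 1`` equals twice the LinLin loss.

All functions are pure and deterministic given their inputs; Monte-Carlo
averaging over posterior draws lives in :mod:`gsdecision.ranking`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .exceptions import DegenerateTruncationError
from .truncation import MvTruncationSummary, TruncationSummary

_SQRT_PI = float(np.sqrt(np.pi))

#: CRPS additive constant: "paper" uses 1/pi, "standard" the usual 1/sqrt(pi).
#: Candidate rankings at common sigma are identical under either choice.
CRPS_CONSTANTS = {"paper": 1.0 / np.pi, "standard": 1.0 / _SQRT_PI}


def _check_z(z: float) -> None:
    if not z > 0.0:
        raise DegenerateTruncationError(f"truncation probability must be positive, got {z}")


# ---------------------------------------------------------------------------
# univariate losses
# ---------------------------------------------------------------------------

def kl_univariate(trunc: TruncationSummary, mu2: float) -> float:
    """KL divergence of the candidate ``N(mu2, sigma2)`` from the truncated parent law."""
    _check_z(trunc.z)
    d2 = (trunc.muS - mu2) ** 2 - (trunc.muS - trunc.mu1) ** 2
    return float(-np.log(trunc.z) + d2 / (2.0 * trunc.sigma2))


def kl_univariate_sr(S: float, R: float, sigma2: float, z: float) -> float:
    """Selection-differential/response form: ``-log z + [(S-R)^2/sigma^2 - i^2]/2``."""
    _check_z(z)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    i2 = (S / np.sqrt(sigma2)) ** 2
    return float(-np.log(z) + 0.5 * ((S - R) ** 2 / sigma2 - i2))


def kl_univariate_h2(i: float, h2: float, z: float) -> float:
    """Heritability form: ``-log z + i^2 h2 (h2 - 2) / 2``."""
    _check_z(z)
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"heritability must be in [0, 1], got {h2}")
    return float(-np.log(z) + 0.5 * i**2 * h2 * (h2 - 2.0))


def _crps_core(w, sigma, constant: str):
    """CRPS of ``N(mu2, sigma^2)`` vs the point ``muS``; ``w = (muS - mu2)/sigma``."""
    try:
        c = CRPS_CONSTANTS[constant]
    except KeyError:
        raise ValueError(f"constant must be one of {sorted(CRPS_CONSTANTS)}") from None
    return -sigma * (c - 2.0 * stats.norm.pdf(w) - w * (2.0 * stats.norm.cdf(w) - 1.0))


def crps_univariate(trunc: TruncationSummary, mu2: float, *, constant: str = "paper") -> float:
    """CRPS of the candidate normal against the selected-parent mean ``muS``."""
    sigma = trunc.sigma
    return float(_crps_core((trunc.muS - mu2) / sigma, sigma, constant))


def crps_univariate_h2(
    i: float, h2: float, sigma: float = 1.0, *, constant: str = "paper"
) -> float:
    """Heritability form of the CRPS, with standardized deviation ``i (1 - h2)``."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"heritability must be in [0, 1], got {h2}")
    return float(_crps_core(i * (1.0 - h2), sigma, constant))


def linlin(e, alpha: float):
    """Pinball loss ``(alpha - 1[e < 0]) e``; symmetric-linear at ``alpha = 0.5``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    e = np.asarray(e, dtype=float)
    out = (alpha - (e < 0.0)) * e
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# multivariate losses
# ---------------------------------------------------------------------------

def kl_multivariate(trunc: MvTruncationSummary, mu2: np.ndarray) -> float:
    """Multivariate KL of the candidate ``MVN(mu2, P)`` from the orthant-truncated parent law.

    ``-log z + [(muS - mu2)' P^-1 (muS - mu2) - S' P^-1 S] / 2`` — the direct
    multi-trait analog of the univariate closed form.
    """
    _check_z(trunc.z)
    e = trunc.muS - np.atleast_1d(np.asarray(mu2, dtype=float))
    quad_e = float(e @ np.linalg.solve(trunc.P, e))
    quad_S = float(trunc.S @ np.linalg.solve(trunc.P, trunc.S))
    return float(-np.log(trunc.z) + 0.5 * (quad_e - quad_S))


def kl_multivariate_h2(S: np.ndarray, P: np.ndarray, G: np.ndarray, z: float) -> float:
    """Heritability (breeder's-equation) form of the multivariate KL.

    ``-log z + S' [(I - GP^-1)' P^-1 (I - GP^-1) - P^-1] S / 2``, i.e. the
    general form with the candidate mean set by ``R = G P^-1 S``.  ``G P^-1``
    plays the role of a matrix heritability: at ``G = P`` the quadratic
    term reduces to ``-S'P^-1 S / 2``.
    """
    _check_z(z)
    S = np.atleast_1d(np.asarray(S, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    G = np.atleast_2d(np.asarray(G, dtype=float))
    t = S.shape[0]
    A = np.eye(t) - G @ np.linalg.inv(P)
    M = A.T @ np.linalg.inv(P) @ A - np.linalg.inv(P)
    return float(-np.log(z) + 0.5 * S @ M @ S)


def energy_score(draws: np.ndarray, muS: np.ndarray) -> float:
    """Sample Energy Score of a predictive draw set against the target ``muS``.

    ``E||Yo - muS|| - E||Yo - Yo'|| / 2`` with the two independent copies
    realized by splitting the draw stream into disjoint halves.  Requires at
    least two draws.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 2:
        raise ValueError(f"energy score needs at least 2 draws, got {draws.shape[0]}")
    muS = np.atleast_1d(np.asarray(muS, dtype=float))
    term1 = np.mean(np.linalg.norm(draws - muS, axis=1))
    half = draws.shape[0] // 2
    a, b = draws[:half], draws[half:2 * half]
    term2 = np.mean(np.linalg.norm(a - b, axis=1))
    return float(term1 - 0.5 * term2)


def malf(e: np.ndarray, tau: np.ndarray, norm: str = "l2") -> float:
    """Multivariate asymmetric loss of the deviation vector ``e = muS - mu2``.

    L2 form ``(||e||_2 + tau'e) ||e||_2``; L1 form ``sum|e_k| + tau'e``.
    Positivity holds for ``||tau|| <= 1`` (L2) / ``max|tau_k| <= 1`` (L1);
    larger asymmetry parameters are allowed but trigger a warning.
    """
    e = np.atleast_1d(np.asarray(e, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if e.shape != tau.shape:
        raise ValueError(f"e and tau dimensions disagree: {e.shape} vs {tau.shape}")
    if norm == "l2":
        if np.linalg.norm(tau) > 1.0 + 1e-12:
            warnings.warn("||tau||_2 > 1: MALF L2 loss may be negative", stacklevel=2)
        n2 = float(np.linalg.norm(e))
        return float((n2 + tau @ e) * n2)
    if norm == "l1":
        if np.max(np.abs(tau)) > 1.0 + 1e-12:
            warnings.warn("max|tau_k| > 1: MALF L1 loss may be negative", stacklevel=2)
        return float(np.sum(np.abs(e)) + tau @ e)
    raise ValueError(f"norm must be 'l2' or 'l1', got {norm!r}")
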