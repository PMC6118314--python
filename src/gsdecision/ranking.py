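"""Posterior expected loss per candidate, ranking and selection.

The posterior expected loss of candidate *o* is the Monte-Carlo average of
the loss over the retained chain: for each posterior draw the base-population
parameters (mean, variance or covariance), the truncation threshold, the
selected-parent mean and the candidate mean are all recomputed from that
draw, the loss is evaluated, and the per-draw losses are averaged.
Candidates are then ranked ascending in expected loss and the top fraction
``q`` is selected.  The ``Std`` baseline ranks by posterior-mean predicted
breeding value instead (descending) and uses no loss function.

Thresholds are pressure-specified: per draw, ``yc`` is set so that the
upper-tail probability of the base population equals ``q`` (marginally per
trait in the multivariate case), matching truncation selection at a fixed
selected fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidPressureError
from . import losses
from .truncation import DEGENERATE_Z, _tallis_q, mvn_orthant_probability

UNIVARIATE_CRITERIA = ("KL", "CRPS", "LinLin")
MULTIVARIATE_CRITERIA = ("mKL", "EnergyS", "MALF")
CRITERIA = UNIVARIATE_CRITERIA + MULTIVARIATE_CRITERIA + ("Std",)


def expected_losses_univariate(
    mu2_draws: np.ndarray,
    mu1_draws: np.ndarray,
    sigma2_draws: np.ndarray,
    q: float,
    criterion: str,
    *,
    alpha: float | None = None,
    crps_constant: str = "paper",
) -> np.ndarray:
    """Posterior expected loss per candidate for a single trait.

    Parameters
    ----------
    mu2_draws : (n_cand, m) candidate means, one column per posterior draw.
    mu1_draws, sigma2_draws : (m,) base-population mean and phenotypic
        variance per posterior draw.
    q : selection pressure; the per-draw threshold satisfies
        ``Pr(Y > yc) = q``, hence ``z = q`` and the intensity is the constant
        ``phi(Phi^{-1}(1-q)) / q``.
    criterion : "KL", "CRPS" or "LinLin".
    """
    if not 0.0 < q < 1.0:
        raise InvalidPressureError(f"selection pressure must be in (0, 1), got {q}")
    mu2_draws = np.atleast_2d(np.asarray(mu2_draws, dtype=float))
    mu1 = np.asarray(mu1_draws, dtype=float)
    sigma2 = np.asarray(sigma2_draws, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 draws must be positive")
    sigma = np.sqrt(sigma2)
    i = float(stats.norm.pdf(stats.norm.isf(q)) / q)  # intensity at pressure q
    muS = mu1 + sigma * i                              # per-draw parent mean

    if criterion == "KL":
        per_draw = -np.log(q) + ((muS - mu2_draws) ** 2 - (sigma * i) ** 2) / (2.0 * sigma2)
    elif criterion == "CRPS":
        w = (muS - mu2_draws) / sigma
        c = losses.CRPS_CONSTANTS[crps_constant]
        per_draw = -sigma * (c - 2.0 * stats.norm.pdf(w) - w * (2.0 * stats.norm.cdf(w) - 1.0))
    elif criterion == "LinLin":
        if alpha is None:
            raise ValueError("LinLin requires alpha")
        per_draw = losses.linlin(muS - mu2_draws, alpha)
    else:
        raise ValueError(f"unknown univariate criterion {criterion!r}")
    return per_draw.mean(axis=1)


def _mv_truncation_per_draw(mu1_s: np.ndarray, P_s: np.ndarray, q: float):
    """Per-draw threshold (marginal pressure q per trait), orthant z and TMVN mean."""
    sig = np.sqrt(np.diag(P_s))
    yc = mu1_s + sig * stats.norm.isf(q)
    z = max(mvn_orthant_probability(mu1_s, P_s, yc), DEGENERATE_Z)
    muS = mu1_s + P_s @ _tallis_q(mu1_s, P_s, yc) / z
    return yc, z, muS


def expected_losses_multivariate(
    mu2_draws: np.ndarray,
    mu1_draws: np.ndarray,
    P_draws: np.ndarray,
    q: float,
    criterion: str,
    *,
    tau: np.ndarray | None = None,
    malf_norm: str = "l2",
    yo_draws: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior expected loss per candidate for several traits.

    Parameters
    ----------
    mu2_draws : (n_cand, m, t) candidate mean vectors per posterior draw.
    mu1_draws : (m, t) base-population means; P_draws : (m, t, t) phenotypic
        covariances per draw.
    criterion : "mKL", "MALF" or "EnergyS".
    yo_draws : (n_cand, m, t) predictive phenotype draws, required for the
        Energy Score; its two independent copies are the two halves of the
        draw stream.
    """
    if not 0.0 < q < 1.0:
        raise InvalidPressureError(f"selection pressure must be in (0, 1), got {q}")
    mu2_draws = np.asarray(mu2_draws, dtype=float)
    mu1_draws = np.asarray(mu1_draws, dtype=float)
    P_draws = np.asarray(P_draws, dtype=float)
    n_cand, m, t = mu2_draws.shape

    # truncation context depends only on the draw, shared by all candidates
    zs = np.empty(m)
    muS = np.empty((m, t))
    for s in range(m):
        _, zs[s], muS[s] = _mv_truncation_per_draw(mu1_draws[s], P_draws[s], q)

    if criterion == "mKL":
        out = np.empty((n_cand, m))
        for s in range(m):
            Pinv = np.linalg.inv(P_draws[s])
            e = muS[s] - mu2_draws[:, s, :]
            S = muS[s] - mu1_draws[s]
            quad_e = np.einsum("ci,ij,cj->c", e, Pinv, e)
            out[:, s] = -np.log(zs[s]) + 0.5 * (quad_e - S @ Pinv @ S)
        return out.mean(axis=1)

    if criterion == "MALF":
        if tau is None:
            raise ValueError("MALF requires tau")
        tau = np.asarray(tau, dtype=float)
        if tau.shape != (t,):
            raise ValueError(f"tau must have length {t}, got shape {tau.shape}")
        e = muS[None, :, :] - mu2_draws  # (n_cand, m, t)
        if malf_norm == "l2":
            n2 = np.linalg.norm(e, axis=2)
            per_draw = (n2 + e @ tau) * n2
        elif malf_norm == "l1":
            per_draw = np.abs(e).sum(axis=2) + e @ tau
        else:
            raise ValueError(f"malf_norm must be 'l2' or 'l1', got {malf_norm!r}")
        return per_draw.mean(axis=1)

    if criterion == "EnergyS":
        if yo_draws is None:
            raise ValueError("EnergyS requires predictive phenotype draws (yo_draws)")
        yo_draws = np.asarray(yo_draws, dtype=float)
        term1 = np.linalg.norm(yo_draws - muS[None, :, :], axis=2).mean(axis=1)
        half = m // 2
        a, b = yo_draws[:, :half, :], yo_draws[:, half:2 * half, :]
        term2 = np.linalg.norm(a - b, axis=2).mean(axis=1)
        return term1 - 0.5 * term2

    raise ValueError(f"unknown multivariate criterion {criterion!r}")


def rank_candidates(scores: pd.Series, *, ascending: bool = True) -> pd.DataFrame:
    """Rank candidates by score with stable identifier tie-breaking.

    ``scores`` is indexed by candidate identifier.  Returns a DataFrame with
    columns ``expected_loss`` and ``rank`` (1 = best); ties are broken by
    identifier order so selections are deterministic.
    """
    if scores.index.has_duplicates:
        raise ValueError("duplicate candidate identifiers")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("non-finite expected losses")
    order = scores.sort_index().sort_values(ascending=ascending, kind="stable")
    out = pd.DataFrame({"expected_loss": order})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_top(ranked: pd.DataFrame, q: float) -> list:
    """Identifiers of the best ``round(q * n)`` candidates of a ranked table."""
    if not 0.0 < q < 1.0:
        raise InvalidPressureError(f"selection pressure must be in (0, 1), got {q}")
    n = len(ranked)
    k = int(round(q * n))
    if k == 0:
        raise ValueError(f"pressure {q} selects zero of {n} candidates")
    return ranked.index[:k].tolist()


def std_selection(mu2_draws: np.ndarray, ids, q: float) -> list:
    """Baseline: select the top ``round(q n)`` by posterior-mean predicted BV."""
    mu2_draws = np.asarray(mu2_draws, dtype=float)
    means = mu2_draws.mean(axis=1) if mu2_draws.ndim == 2 else mu2_draws.reshape(
        mu2_draws.shape[0], -1).mean(axis=1)
    scores = pd.Series(means, index=pd.Index(ids))
    ranked = rank_candidates(scores, ascending=False)
    return select_top(ranked, q)
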