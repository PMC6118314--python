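"""Whole-genome regression models fitted by Gibbs sampling.

Two prediction models produce the posterior and predictive draws that the
expected-loss ranking averages over:

* :class:`BayesianRidgeRegression` — single trait, ``y = 1 mu + X beta + e``
  with an iid Gaussian prior on the marker effects, scaled-inverse-chi^2
  priors on the two variances and a flat prior on the intercept.
* :class:`MultiTraitModel` — ``Y = 1 m' + U + E`` with per-trait fixed
  intercepts, line genetic values with covariance ``K (x) G`` (genomic
  relationship times trait genetic covariance) and iid residual rows with
  covariance ``R``; inverse-Wishart priors on ``G`` and ``R``.

Both are scikit-learn style estimators: hyperparameters in ``__init__``,
chains produced by ``fit`` and stored in trailing-underscore attributes,
posterior-mean point predictions from ``predict``, and full per-draw
predictive streams from ``predictive_draws`` / ``bv_draws``.  Chains are
bit-reproducible given ``seed``.

The BRR update for the marker-effect block uses a one-time eigendecomposition
of ``X'X`` so each sweep costs two dense matrix-vector products; the MTM
whitens the line dimension with the eigenvectors of ``K`` and the trait
dimension with a generalized eigenbasis of ``(G, R)``, making the genetic
value update fully vectorized.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import CovarianceError, SamplerError


# ---------------------------------------------------------------------------
# marker preparation
# ---------------------------------------------------------------------------

def prepare_markers(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-center a marker matrix.

    Accepts -1/+1 homozygote coding or arbitrary numeric dosages.  Returns
    ``(centered, column_means, monomorphic)`` where ``monomorphic`` flags
    zero-variance columns (kept in place, centered to zero).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("marker matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("marker matrix contains non-finite entries")
    means = X.mean(axis=0)
    centered = X - means
    monomorphic = centered.var(axis=0) == 0.0
    return centered, means, monomorphic


def genomic_relationship(X) -> np.ndarray:
    """Genomic relationship matrix ``K = W W' / c`` from centered markers.

    ``c`` is chosen so the diagonal of ``K`` averages exactly one
    (trace normalization), the usual scaling for a VanRaden-style GRM.
    """
    W, _, mono = prepare_markers(X)
    if np.all(mono):
        raise CovarianceError("no polymorphic markers; GRM is degenerate")
    WWt = W @ W.T
    c = np.trace(WWt) / W.shape[0]
    return WWt / c


def _sample_scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    """One draw of sigma^2 ~ scaled-inv-chi^2(df, scale) = df*scale / chi2_df."""
    return df * scale / rng.chisquare(df)


class BayesianRidgeRegression(BaseEstimator, RegressorMixin):
    """Bayesian ridge regression on markers, fitted by Gibbs sampling.

    Parameters
    ----------
    n_iter : retained post-burn-in sweeps before thinning is applied.
    burn_in : discarded initial sweeps.
    thin : keep every ``thin``-th post-burn-in sweep.
    df_prior : degrees of freedom of both scaled-inverse-chi^2 priors.
    r2 : prior proportion of phenotypic variance attributed to markers; the
        prior modes of the two variances split ``var(y)`` as ``r2 : 1 - r2``.
    seed : RNG seed; identical seeds give bit-identical chains.

    Attributes (after ``fit``)
    --------------------------
    mu_draws_, beta_draws_, sigma2_beta_draws_, sigma2_e_draws_ : chains,
        one row per retained draw.
    n_draws_ : retained chain length, ``n_iter // thin``.
    x_mean_ : training marker column means (re-used to center candidates).
    """

    def __init__(self, n_iter: int = 10_000, burn_in: int = 30_000, thin: int = 1,
                 df_prior: float = 5.0, r2: float = 0.5, seed: int = 0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df_prior = df_prior
        self.r2 = r2
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y row counts disagree")
        if min(self.n_iter, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("chain settings must be positive")
        rng = np.random.default_rng(self.seed)

        Xc, self.x_mean_, _ = prepare_markers(X)
        vy = float(np.var(y))
        if vy == 0.0:
            vy = 1.0
        msx = float(np.sum(Xc.var(axis=0)))
        df = self.df_prior
        # scale set so the prior mode matches the r2 : 1-r2 variance split
        s_b = self.r2 * vy / max(msx, 1e-12) * (df + 2.0) / df
        s_e = (1.0 - self.r2) * vy * (df + 2.0) / df

        # one-time eigendecomposition of X'X; because Xc is column-centered,
        # X'(y - mu 1) = X'y for every mu, so the projection is fixed
        D, V = np.linalg.eigh(Xc.T @ Xc)
        D = np.clip(D, 0.0, None)
        b_proj = V.T @ (Xc.T @ y)

        mu = float(np.mean(y))
        beta = np.zeros(p)
        xbeta = np.zeros(n)
        sigma2_e = 0.5 * vy
        sigma2_b = s_b * df / (df + 2.0)

        n_keep = self.n_iter // self.thin
        self.mu_draws_ = np.empty(n_keep)
        self.beta_draws_ = np.empty((n_keep, p))
        self.sigma2_beta_draws_ = np.empty(n_keep)
        self.sigma2_e_draws_ = np.empty(n_keep)

        kept = 0
        total = self.burn_in + self.n_iter
        for it in range(total):
            # mu | beta, sigma2_e
            mu = rng.normal(np.mean(y - xbeta), np.sqrt(sigma2_e / n))
            # beta | rest, in the eigenbasis of X'X
            lam = sigma2_e / sigma2_b
            denom = D + lam
            coef = b_proj / denom + np.sqrt(sigma2_e / denom) * rng.standard_normal(p)
            beta = V @ coef
            xbeta = Xc @ beta
            # variances | rest
            sigma2_b = _sample_scaled_inv_chi2(rng, df + p, (df * s_b + coef @ coef) / (df + p))
            resid = y - mu - xbeta
            sigma2_e = _sample_scaled_inv_chi2(rng, df + n, (df * s_e + resid @ resid) / (df + n))

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and kept < n_keep:
                self.mu_draws_[kept] = mu
                self.beta_draws_[kept] = beta
                self.sigma2_beta_draws_[kept] = sigma2_b
                self.sigma2_e_draws_[kept] = sigma2_e
                kept += 1

        self.n_draws_ = kept
        if not (np.all(np.isfinite(self.beta_draws_))
                and np.all(self.sigma2_e_draws_ > 0)
                and np.all(self.sigma2_beta_draws_ > 0)):
            raise SamplerError("BRR chain produced non-finite or non-positive draws")
        return self

    def bv_draws(self, X) -> np.ndarray:
        """Per-draw genetic values ``x' beta`` for candidate marker rows.

        Returns an ``(n_candidates, n_draws)`` array aligned with the chain.
        """
        Xc = np.asarray(X, dtype=float) - self.x_mean_
        return Xc @ self.beta_draws_.T

    def predictive_draws(self, X, *, include_residual: bool = False,
                         seed: int | None = None) -> np.ndarray:
        """Per-draw predictive values ``mu + x' beta`` (+ residual noise if asked)."""
        out = self.bv_draws(X) + self.mu_draws_
        if include_residual:
            rng = np.random.default_rng(seed)
            out = out + rng.standard_normal(out.shape) * np.sqrt(self.sigma2_e_draws_)
        return out

    def predict(self, X) -> np.ndarray:
        """Posterior-mean prediction for candidate marker rows."""
        return self.predictive_draws(X).mean(axis=1)


class MultiTraitModel(BaseEstimator):
    """Multi-trait genomic mixed model fitted by Gibbs sampling.

    ``Y (n x t) = 1 m' + U + E`` with ``vec(U) ~ N(0, G (x) K)`` (trait
    genetic covariance ``G``, line relationship ``K``) and iid residual rows
    ``N(0, R)``.  Inverse-Wishart(df = t + 3, scale = sample_cov / 2) priors
    on ``G`` and ``R``; flat prior on the intercepts.

    Attributes (after ``fit``)
    --------------------------
    intercept_draws_ : (n_draws, t)
    u_draws_ : (n_draws, n, t) genetic values of the training lines
    genetic_cov_draws_, residual_cov_draws_ : (n_draws, t, t)
    """

    def __init__(self, n_iter: int = 10_000, burn_in: int = 30_000, thin: int = 1,
                 df_prior_offset: float = 3.0, seed: int = 0, jitter: float = 1e-8):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df_prior_offset = df_prior_offset
        self.seed = seed
        self.jitter = jitter

    def fit(self, Y, K):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise ValueError("Y must be an (n_lines, n_traits) matrix")
        n, t = Y.shape
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise CovarianceError(f"K must be {n}x{n}, got {K.shape}")
        if min(self.n_iter, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("chain settings must be positive")
        rng = np.random.default_rng(self.seed)

        lam, Q = np.linalg.eigh(K + self.jitter * np.eye(n))
        if lam[-1] <= 0:
            raise CovarianceError("K is singular beyond jitter tolerance")
        lam = np.clip(lam, self.jitter, None)

        nu0 = t + self.df_prior_offset
        S0 = 0.5 * np.cov(Y, rowvar=False) + 1e-8 * np.eye(t)

        Ystar = Q.T @ Y
        ones_star = Q.T @ np.ones(n)

        m = Y.mean(axis=0).copy()
        G = 0.5 * np.cov(Y, rowvar=False) + 1e-6 * np.eye(t)
        R = G.copy()
        Ustar = np.zeros((n, t))

        n_keep = self.n_iter // self.thin
        self.intercept_draws_ = np.empty((n_keep, t))
        self.u_draws_ = np.empty((n_keep, n, t))
        self.genetic_cov_draws_ = np.empty((n_keep, t, t))
        self.residual_cov_draws_ = np.empty((n_keep, t, t))

        kept = 0
        for it in range(self.burn_in + self.n_iter):
            # intercepts | U, R  (original space: colmean(Y - U), cov R/n)
            U = Q @ Ustar
            m = rng.multivariate_normal((Y - U).mean(axis=0), R / n)

            # genetic values | rest: whiten traits with the generalized
            # eigenbasis B of (G, R): B'RB = I, B'GB = diag(delta)
            delta, B = sla.eigh(G, R)
            delta = np.clip(delta, 1e-12, None)
            Rstar = Ystar - np.outer(ones_star, m)
            Ytil = Rstar @ B                       # iid unit noise per entry
            shrink = lam[:, None] * delta[None, :]
            shrink = shrink / (1.0 + shrink)       # posterior variance factor
            mean_til = shrink * Ytil
            sd_til = np.sqrt(shrink)
            Util = mean_til + sd_til * rng.standard_normal((n, t))
            Binv = np.linalg.inv(B.T)
            Ustar = Util @ Binv.T                  # back to trait space

            # G | U: scatter of whitened-line genetic values
            SG = Ustar.T @ (Ustar / lam[:, None])
            G = stats.invwishart.rvs(df=nu0 + n, scale=S0 + SG, random_state=rng)
            G = np.atleast_2d(G)

            # R | residuals (Q is orthogonal so E*'E* = E'E)
            E = Rstar - Ustar
            R = stats.invwishart.rvs(df=nu0 + n, scale=S0 + E.T @ E, random_state=rng)
            R = np.atleast_2d(R)

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and kept < n_keep:
                self.intercept_draws_[kept] = m
                self.u_draws_[kept] = Q @ Ustar
                self.genetic_cov_draws_[kept] = G
                self.residual_cov_draws_[kept] = R
                kept += 1

        self.n_draws_ = kept
        self.n_lines_ = n
        self.n_traits_ = t
        self._K_train = K
        if not np.all(np.isfinite(self.u_draws_)):
            raise SamplerError("MTM chain produced non-finite draws")
        return self

    def bv_draws(self, K_cross, K_cand=None, *, sample: bool = True,
                 seed: int | None = None) -> np.ndarray:
        """Per-draw genetic values for unobserved candidate lines.

        Candidates are connected to the training lines through the
        relationship blocks: ``K_cross`` is (n_cand, n_train) and ``K_cand``
        (n_cand, n_cand).  Per retained draw, the candidate genetic values
        are drawn from (``sample=True``) or set to the mean of
        (``sample=False``) the conditional Gaussian given the training
        values.  Returns (n_cand, n_draws, t).
        """
        K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
        A = np.linalg.solve(self._K_train + self.jitter * np.eye(self.n_lines_), K_cross.T).T
        n_cand = K_cross.shape[0]
        out = np.empty((n_cand, self.n_draws_, self.n_traits_))
        L = None
        if sample:
            if K_cand is None:
                raise ValueError("K_cand is required when sample=True")
            C = np.asarray(K_cand, dtype=float) - A @ K_cross.T
            C = 0.5 * (C + C.T) + self.jitter * np.eye(n_cand)
            L = np.linalg.cholesky(C)
            rng = np.random.default_rng(seed)
        for s in range(self.n_draws_):
            mean_s = A @ self.u_draws_[s]
            if sample:
                Gl = np.linalg.cholesky(
                    self.genetic_cov_draws_[s] + self.jitter * np.eye(self.n_traits_))
                mean_s = mean_s + L @ rng.standard_normal((n_cand, self.n_traits_)) @ Gl.T
            out[:, s, :] = mean_s
        return out

    def predict(self, K_cross) -> np.ndarray:
        """Posterior-mean trait values (intercept + conditional-mean BV), (n_cand, t)."""
        bv = self.bv_draws(K_cross, sample=False)
        return bv.mean(axis=1) + self.intercept_draws_.mean(axis=0)
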