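"""Forward-in-time recurrent genomic selection.

The simulator runs the benchmark breeding program: fully homozygous founder
lines at biallelic loci (genotypes coded -1/+1), additive trait
architectures (single trait with gamma-distributed gene effects, or three
pleiotropic traits with per-locus effect vectors drawn from a correlated
multivariate normal), phenotypes generated at a target narrow-sense
heritability, genomic prediction on a 70/30 train/candidate split,
selection of the top fraction of candidates by posterior expected loss (or
by posterior-mean breeding value, the ``Std`` baseline), and doubled-haploid
crossing of the selected parents to recover the population size — repeated
for a configured number of cycles and replicates.

Residual variances are calibrated once from the founder genetic variance,
``sigma_e^2 = sigma_g^2 (1 - h2) / h2``, and held fixed across cycles, so
realized heritability drifts downward as selection erodes genetic variance;
a per-cycle recalibration switch restores a constant realized h2.  The
degenerate target ``h2 = 0`` keeps the gene effects (so true breeding
values remain defined) but generates phenotypes as pure noise with
``sigma_e^2 = sigma_g^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import BayesianRidgeRegression, MultiTraitModel, genomic_relationship
from .ranking import (
    MULTIVARIATE_CRITERIA,
    UNIVARIATE_CRITERIA,
    expected_losses_multivariate,
    expected_losses_univariate,
    rank_candidates,
    select_top,
    std_selection,
)
from .exceptions import CovarianceError


def default_asymmetry(q: float) -> float:
    """Default LinLin alpha / MALF tau component: 0.9 at 10% pressure, 0.7 at 30%."""
    return 0.9 if q <= 0.2 else 0.7


@dataclass
class TraitArchitecture:
    """Additive genetic architecture shared by all cycles of one replicate."""

    effects: np.ndarray          # (p, t) per-locus additive effects
    h2: np.ndarray               # (t,) target narrow-sense heritabilities
    sigma2_e: np.ndarray         # (t,) residual variances, calibrated at founders

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]


@dataclass
class Population:
    """One generation of fully homozygous lines."""

    genotypes: np.ndarray        # (n, p) entries in {-1, +1}
    tbv: np.ndarray | None = None         # (n, t) true breeding values
    phenotypes: np.ndarray | None = None  # (n, t)
    cycle: int = 1


@dataclass
class ProgramConfig:
    """Configuration of a recurrent-selection run.

    Defaults follow the benchmark design: 10 cycles, 70/30 train/candidate
    split, 20 replicates, pressure-dependent asymmetry (alpha or tau of 0.9
    at 10% pressure, 0.7 at 30%), and the long MCMC profile (10,000 retained
    draws after 30,000 burn-in).  Founder size and locus count are the
    package's own defaults (the design leaves them open).
    """

    n_founders: int = 500
    n_loci: int = 1000
    n_traits: int = 1
    h2: float | tuple = 0.5
    genetic_correlations: np.ndarray | None = None
    n_cycles: int = 10
    pressure: float = 0.10
    criterion: str = "Std"
    train_fraction: float = 0.70
    n_replicates: int = 20
    alpha: float | None = None           # LinLin; defaults from pressure
    tau: np.ndarray | None = None        # MALF; defaults from pressure
    crps_constant: str = "paper"
    malf_norm: str = "l2"
    mcmc_iter: int = 10_000
    mcmc_burn_in: int = 30_000
    mcmc_thin: int = 1
    recalibrate_residual: bool = False
    effect_signs: str = "random"         # "random" or "positive" (univariate)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.pressure < 1.0:
            raise ValueError("pressure must be in (0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if self.h2.shape[0] == 1 and self.n_traits > 1:
            self.h2 = np.repeat(self.h2, self.n_traits)
        if np.any((self.h2 < 0) | (self.h2 > 1)):
            raise ValueError("heritabilities must be in [0, 1]")
        if self.alpha is None:
            self.alpha = default_asymmetry(self.pressure)
        if self.tau is None:
            self.tau = np.full(self.n_traits, default_asymmetry(self.pressure))
        else:
            self.tau = np.asarray(self.tau, dtype=float)


#: the benchmark three-trait genetic correlation targets
DEFAULT_CORRELATIONS = np.array([
    [1.00, -0.37, -0.02],
    [-0.37, 1.00, 0.34],
    [-0.02, 0.34, 1.00],
])


# ---------------------------------------------------------------------------
# founders, effects, phenotypes, crossing
# ---------------------------------------------------------------------------

def simulate_founders(n: int, p: int, rng: np.random.Generator,
                      freqs: np.ndarray | None = None) -> np.ndarray:
    """Founder genotypes: per-locus allele frequency uniform on [0.05, 0.95],
    each fully homozygous line sampled iid as -1/+1."""
    if n < 2 or p < 2:
        raise ValueError("need at least 2 lines and 2 loci")
    if freqs is None:
        freqs = rng.uniform(0.05, 0.95, size=p)
    geno = np.where(rng.random((n, p)) < freqs, 1, -1).astype(np.int8)
    return geno


def sample_effects_univariate(p: int, rng: np.random.Generator, *,
                              shape: float = 2.0, scale: float = 2.0,
                              signs: str = "random") -> np.ndarray:
    """Single-trait gene effects: magnitudes iid Gamma(shape=2, scale=2).

    The gamma is one-sided; by default each effect gets an independent
    random sign so the trait is not driven toward fixation of one allele,
    with ``signs="positive"`` keeping the raw one-sided draw.
    """
    mags = rng.gamma(shape, scale, size=p)
    if signs == "random":
        return mags * rng.choice([-1.0, 1.0], size=p)
    if signs == "positive":
        return mags
    raise ValueError(f"signs must be 'random' or 'positive', got {signs!r}")


def sample_effects_multitrait(p: int, correlations: np.ndarray,
                              rng: np.random.Generator, *,
                              exact: bool = True,
                              genotypes: np.ndarray | None = None) -> np.ndarray:
    """Pleiotropic gene effects: per-locus t-vectors from MVN(0, Sigma_b).

    ``Sigma_b`` has unit variances and the target correlations.  With
    ``exact=True`` (default) the drawn effect matrix is re-whitened so its
    sample covariance equals ``Sigma_b`` exactly; passing the founder
    ``genotypes`` additionally calibrates the effects against the realized
    genotype covariance so the first-generation TBV correlations equal the
    targets exactly — the sampler's reading of "ensuring" stated
    first-generation genetic correlations.  ``exact=False`` keeps the raw
    iid draw.
    """
    C = np.asarray(correlations, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise CovarianceError("target correlation matrix is not positive definite") from exc
    t = C.shape[0]
    if p <= t:
        raise ValueError(f"need more loci than traits, got p={p}, t={t}")
    Z = rng.standard_normal((p, t))
    if exact:
        Z = Z - Z.mean(axis=0)
        Lz = np.linalg.cholesky(np.cov(Z, rowvar=False, ddof=0))
        Z = np.linalg.solve(Lz, Z.T).T  # sample covariance now the identity
    B = Z @ L.T
    if genotypes is not None:
        tbv = genotypes.astype(float) @ B
        S = np.cov(tbv, rowvar=False, ddof=0)
        Ls = np.linalg.cholesky(S)
        # M with M' S M = C: realized TBV covariance becomes exactly C
        M = np.linalg.solve(Ls.T, L.T)
        B = B @ M
    return B


def true_breeding_values(genotypes: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """TBV = X b, (n, t)."""
    return genotypes.astype(float) @ np.atleast_2d(effects.T).T


def calibrate_residual_variance(tbv: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Per-trait residual variance ``sigma_g^2 (1 - h2) / h2`` from realized
    genetic variance (``sigma_g^2`` itself at h2 = 0, zero at h2 = 1)."""
    var_g = np.var(tbv, axis=0)
    h2 = np.atleast_1d(h2)
    if np.any((var_g == 0) & (h2 > 0)):
        raise ValueError("zero realized genetic variance with positive target h2")
    out = np.empty_like(var_g)
    pos = h2 > 0
    out[pos] = var_g[pos] * (1.0 - h2[pos]) / h2[pos]
    out[~pos] = var_g[~pos]
    return out


def simulate_phenotypes(population: Population, arch: TraitArchitecture,
                        rng: np.random.Generator) -> Population:
    """Attach TBV and phenotypes ``y = TBV + e`` (pure noise where h2 = 0)."""
    tbv = true_breeding_values(population.genotypes, arch.effects)
    noise = rng.standard_normal(tbv.shape) * np.sqrt(arch.sigma2_e)
    signal = (arch.h2 > 0).astype(float)
    population.tbv = tbv
    population.phenotypes = tbv * signal + noise
    return population


def make_crosses(parents: np.ndarray, n_offspring: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Doubled-haploid progeny from random distinct parent pairs.

    Parents are homozygous, so each offspring locus carries one of the two
    parental alleles with probability 1/2, rendered homozygous (the coding
    stays in {-1, +1}); loci assort independently.
    """
    n_par = parents.shape[0]
    if n_par < 2:
        raise ValueError("need at least 2 selected parents to cross")
    p1 = rng.integers(0, n_par, size=n_offspring)
    shift = rng.integers(1, n_par, size=n_offspring)
    p2 = (p1 + shift) % n_par  # distinct mate, uniform over the others
    pick = rng.random((n_offspring, parents.shape[1])) < 0.5
    return np.where(pick, parents[p1], parents[p2]).astype(np.int8)


# ---------------------------------------------------------------------------
# one replicate of the program
# ---------------------------------------------------------------------------

def _fit_and_select_univariate(pop: Population, cfg: ProgramConfig,
                               rng: np.random.Generator) -> np.ndarray:
    n = pop.genotypes.shape[0]
    perm = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train, cand = perm[:n_train], perm[n_train:]
    X = pop.genotypes.astype(float)
    y = pop.phenotypes[:, 0]

    model = BayesianRidgeRegression(
        n_iter=cfg.mcmc_iter, burn_in=cfg.mcmc_burn_in, thin=cfg.mcmc_thin,
        seed=int(rng.integers(2**31)),
    ).fit(X[train], y[train])

    bv_all = model.bv_draws(X)                       # (n, m)
    mu1_draws = model.mu_draws_ + bv_all.mean(axis=0)
    sigma2_draws = bv_all.var(axis=0) + model.sigma2_e_draws_
    mu2_draws = model.mu_draws_ + bv_all[cand]       # (n_cand, m)

    if cfg.criterion == "Std":
        selected = std_selection(mu2_draws, cand, cfg.pressure)
    elif cfg.criterion in UNIVARIATE_CRITERIA:
        scores = expected_losses_univariate(
            mu2_draws, mu1_draws, sigma2_draws, cfg.pressure, cfg.criterion,
            alpha=cfg.alpha, crps_constant=cfg.crps_constant)
        ranked = rank_candidates(pd.Series(scores, index=pd.Index(cand)))
        selected = select_top(ranked, cfg.pressure)
    else:
        raise ValueError(f"criterion {cfg.criterion!r} is not univariate")
    return pop.genotypes[np.asarray(selected, dtype=int)]


def _fit_and_select_multivariate(pop: Population, cfg: ProgramConfig,
                                 rng: np.random.Generator) -> np.ndarray:
    n = pop.genotypes.shape[0]
    perm = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train, cand = perm[:n_train], perm[n_train:]
    K = genomic_relationship(pop.genotypes.astype(float))

    model = MultiTraitModel(
        n_iter=cfg.mcmc_iter, burn_in=cfg.mcmc_burn_in, thin=cfg.mcmc_thin,
        seed=int(rng.integers(2**31)),
    ).fit(pop.phenotypes[train], K[np.ix_(train, train)])

    bv_cand = model.bv_draws(K[np.ix_(cand, train)], K[np.ix_(cand, cand)],
                             sample=True, seed=int(rng.integers(2**31)))
    mu2_draws = bv_cand + model.intercept_draws_[None, :, :]
    m, t = model.n_draws_, model.n_traits_
    # base population from the full current generation
    u_full_mean = (model.u_draws_.mean(axis=1) * len(train)
                   + bv_cand.mean(axis=0) * len(cand)) / n
    mu1_draws = model.intercept_draws_ + u_full_mean
    P_draws = model.genetic_cov_draws_ + model.residual_cov_draws_

    if cfg.criterion == "Std":
        selected = std_selection(mu2_draws, cand, cfg.pressure)
    elif cfg.criterion in MULTIVARIATE_CRITERIA:
        yo_draws = None
        if cfg.criterion == "EnergyS":
            yo_draws = np.empty_like(mu2_draws)
            for s in range(m):
                Lr = np.linalg.cholesky(model.residual_cov_draws_[s])
                yo_draws[:, s, :] = (mu2_draws[:, s, :]
                                     + rng.standard_normal((len(cand), t)) @ Lr.T)
        scores = expected_losses_multivariate(
            mu2_draws, mu1_draws, P_draws, cfg.pressure, cfg.criterion,
            tau=cfg.tau, malf_norm=cfg.malf_norm, yo_draws=yo_draws)
        ranked = rank_candidates(pd.Series(scores, index=pd.Index(cand)))
        selected = select_top(ranked, cfg.pressure)
    else:
        raise ValueError(f"criterion {cfg.criterion!r} is not multivariate")
    return pop.genotypes[np.asarray(selected, dtype=int)]


def run_replicate(cfg: ProgramConfig, seed: int) -> pd.DataFrame:
    """One full recurrent-selection trajectory; returns per-cycle records."""
    rng = np.random.default_rng(seed)
    geno = simulate_founders(cfg.n_founders, cfg.n_loci, rng)
    if cfg.n_traits == 1:
        effects = sample_effects_univariate(cfg.n_loci, rng, signs=cfg.effect_signs)[:, None]
    else:
        corr = cfg.genetic_correlations
        if corr is None:
            corr = DEFAULT_CORRELATIONS[:cfg.n_traits, :cfg.n_traits]
        effects = sample_effects_multitrait(cfg.n_loci, corr, rng, genotypes=geno)
    tbv0 = true_breeding_values(geno, effects)
    arch = TraitArchitecture(effects=effects, h2=cfg.h2,
                             sigma2_e=calibrate_residual_variance(tbv0, cfg.h2))

    records = []
    pop = Population(genotypes=geno, cycle=1)
    for cycle in range(1, cfg.n_cycles + 1):
        pop.cycle = cycle
        if cfg.recalibrate_residual and cycle > 1:
            arch.sigma2_e = calibrate_residual_variance(
                true_breeding_values(pop.genotypes, arch.effects), cfg.h2)
        simulate_phenotypes(pop, arch, rng)
        for k in range(arch.n_traits):
            records.append({
                "cycle": cycle, "trait": k + 1,
                "mean_tbv": float(pop.tbv[:, k].mean()),
                "var_tbv": float(pop.tbv[:, k].var()),
                "mean_phen": float(pop.phenotypes[:, k].mean()),
                "var_phen": float(pop.phenotypes[:, k].var()),
            })
        if cycle == cfg.n_cycles:
            break
        if cfg.n_traits == 1:
            parents = _fit_and_select_univariate(pop, cfg, rng)
        else:
            parents = _fit_and_select_multivariate(pop, cfg, rng)
        pop = Population(genotypes=make_crosses(parents, cfg.n_founders, rng),
                         cycle=cycle + 1)

    df = pd.DataFrame.from_records(records)
    # standardize against cycle 1, per trait
    base = df[df["cycle"] == 1].set_index("trait")
    for col_src, sd_src, col_out in [
        ("mean_tbv", "var_tbv", "std_response"),
        ("mean_phen", "var_phen", "std_response_phen"),
    ]:
        mu1 = df["trait"].map(base[col_src])
        s1 = np.sqrt(df["trait"].map(base[sd_src]))
        df[col_out] = (df[col_src] - mu1) / s1
    df["scaled_var"] = df["var_tbv"] / df["trait"].map(base["var_tbv"])
    df["scaled_var_phen"] = df["var_phen"] / df["trait"].map(base["var_phen"])
    return df


def run_program(cfg: ProgramConfig) -> pd.DataFrame:
    """All replicates of the configured program, as one tidy table.

    Replicate seeds are spawned deterministically from ``cfg.seed``; the
    master seed fixes every trajectory completely.
    """
    rng = np.random.default_rng(cfg.seed)
    rep_seeds = rng.integers(0, 2**31, size=cfg.n_replicates)
    frames = []
    for r, s in enumerate(rep_seeds, start=1):
        df = run_replicate(cfg, int(s))
        df.insert(0, "replicate", r)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_program(results: pd.DataFrame,
                      value: str = "std_response") -> pd.DataFrame:
    """Replicate means and standard errors per cycle and trait."""
    g = results.groupby(["cycle", "trait"])[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def percent_differences(results: pd.DataFrame, value: str = "mean_tbv",
                        first_cycle: int | None = None,
                        last_cycle: int | None = None) -> pd.DataFrame:
    """Per-trait mean (and SE) of 100 (v_last - v_first) / v_first across replicates."""
    first_cycle = first_cycle or int(results["cycle"].min())
    last_cycle = last_cycle or int(results["cycle"].max())
    wide = results.pivot_table(index=["replicate", "trait"], columns="cycle",
                               values=value)
    v1, vL = wide[first_cycle], wide[last_cycle]
    if np.any(np.abs(v1) < 1e-12):
        raise ZeroDivisionError("first-cycle value is zero; percent difference undefined")
    pct = (100.0 * (vL - v1) / v1).rename("pct").reset_index()
    g = pct.groupby("trait")["pct"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    if (out["n"] < 2).any():
        out.loc[out["n"] < 2, "se"] = np.nan
    return out.drop(columns="sd")
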