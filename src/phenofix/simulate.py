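"""Liability-threshold case/control simulator with differential label noise.

Two study designs are supported:

* **strategy 1** — no population structure: MAF drawn uniformly from
  {0.1, 0.2, 0.4}, strong SNP effects beta ~ N(2, 0.3) (variance 0.3),
  liability L = X beta + eps thresholded at its median to give a balanced
  1000/1000 case/control phenotype;
* **strategy 2** — structured: MAF ~ Uniform(0, 0.5), MAF-dependent effects
  beta_j ~ N(0, sigma_g^2 [2 f_j (1 - f_j)]^a) with sigma_g^2 = 0.1 and
  a = -0.38 (rarer alleles get larger effects), polygenic random effects
  u ~ MVN(0, sigma_u^2 A) with sigma_u^2 = 2 over the realized GRM, a
  population prevalence drawn from (0.1, 0.5) imposed by empirical liability
  quantile, and a 1000-case / 3000-control study sampled from the population.

Differential misclassification is injected by flipping a fixed fraction of
randomly chosen controls to cases (cases are never flipped), with the flipped
set recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import compute_grm
from .types import GenotypeMatrix, KinshipMatrix, PhenotypeVector

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "draw_effect_sizes",
    "simulate_random_effects",
    "simulate_population_phenotype",
    "sample_case_control",
    "inject_misclassification",
    "variance_explained",
    "simulate_study",
]

STRATEGY1_MAF_CHOICES = (0.1, 0.2, 0.4)


@dataclass
class SimulationConfig:
    """Generative settings; defaults are the structured (strategy-2) design."""

    strategy: int = 2
    n_population: int = 10_000
    m_snps: int = 100_000
    n_causal: int = 300
    sigma_g2: float = 0.1
    maf_exponent: float = -0.38
    effect_mean_s1: float = 2.0
    effect_var_s1: float = 0.3
    sigma_u2_true: float = 2.0
    prevalence_range: tuple[float, float] = (0.1, 0.5)
    n_cases_sampled: int = 1000
    n_controls_sampled: int = 3000
    misclassification_fraction: float = 0.0
    grm_maf_min: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in (1, 2):
            raise ValueError("strategy must be 1 or 2")
        if self.n_causal > self.m_snps:
            raise ValueError("n_causal cannot exceed m_snps")
        if not (0.0 <= self.misclassification_fraction < 1.0):
            raise ValueError("misclassification_fraction must lie in [0, 1)")
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("prevalence bounds must lie in (0, 1)")


@dataclass
class SimulatedDataset:
    """A simulated study with full ground truth."""

    X: GenotypeMatrix
    Y_true: PhenotypeVector
    Y_observed: PhenotypeVector
    causal_indices: np.ndarray
    beta_true: np.ndarray
    u_true: np.ndarray
    liability: np.ndarray
    misclassified_mask: np.ndarray
    realized_prevalence: float
    variance_explained_per_snp: np.ndarray = field(default=None)
    heritability_snp: float = np.nan
    heritability_snp_plus_u: float = np.nan


def simulate_genotypes(n: int, m: int, maf_model: str = "uniform",
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Independent HWE genotypes: per-SNP f from the MAF model, counts
    Binomial(2, f).

    ``maf_model`` is ``"uniform"`` (Uniform(0, 0.5), strategy 2) or
    ``"categorical"`` (uniform over {0.1, 0.2, 0.4}, strategy 1).
    """
    rng = np.random.default_rng() if rng is None else rng
    if maf_model == "uniform":
        f = rng.uniform(0.0, 0.5, size=m)
    elif maf_model == "categorical":
        f = rng.choice(STRATEGY1_MAF_CHOICES, size=m)
    else:
        raise ValueError(f"unknown maf_model {maf_model!r}")
    # avoid monomorphic columns: resample degenerate draws
    values = rng.binomial(2, f, size=(n, m)).astype(float)
    mono = values.std(axis=0) == 0.0
    while mono.any():
        f[mono] = (rng.uniform(0.05, 0.5, size=int(mono.sum()))
                   if maf_model == "uniform"
                   else rng.choice(STRATEGY1_MAF_CHOICES, size=int(mono.sum())))
        values[:, mono] = rng.binomial(2, f[mono], size=(n, int(mono.sum())))
        mono = values.std(axis=0) == 0.0
    return GenotypeMatrix.from_counts(values)


def draw_effect_sizes(config: SimulationConfig, maf_of_causal: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Causal effect sizes under the configured strategy.

    Strategy 1: i.i.d. N(2, 0.3) (variance 0.3).  Strategy 2:
    beta_j ~ N(0, sigma_g^2 [2 f_j (1 - f_j)]^a); the negative exponent gives
    rarer variants larger effects.
    """
    f = np.asarray(maf_of_causal, dtype=float)
    if config.strategy == 1:
        return rng.normal(config.effect_mean_s1,
                          np.sqrt(config.effect_var_s1), size=f.size)
    if np.any(f <= 0.0):
        raise ValueError("monomorphic causal SNP (f = 0) has infinite effect variance")
    var = config.sigma_g2 * (2.0 * f * (1.0 - f)) ** config.maf_exponent
    return rng.normal(0.0, np.sqrt(var))


def simulate_random_effects(A: KinshipMatrix, sigma_u2: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Polygenic random effects u ~ MVN(0, sigma_u2 * A) via the Cholesky
    factor of the jittered kinship."""
    z = rng.standard_normal(A.n)
    return np.sqrt(sigma_u2) * (A.cholesky @ z)


def simulate_population_phenotype(X: GenotypeMatrix, beta_true: np.ndarray,
                                  causal_indices: np.ndarray,
                                  u_true: np.ndarray, prevalence: float,
                                  rng: np.random.Generator):
    """Threshold the liability L = X_c beta + u + eps at its empirical
    (1 - prevalence) quantile; prevalence = 0.5 gives the balanced
    median-split design of strategy 1.

    Returns ``(y_true, liability)``.
    """
    eps = rng.standard_normal(X.n_samples)
    liability = X.values[:, causal_indices] @ beta_true + u_true + eps
    if np.ptp(liability) == 0.0:
        raise ValueError("degenerate liabilities: all samples identical")
    cutoff = np.quantile(liability, 1.0 - prevalence)
    y = (liability > cutoff).astype(np.int64)
    # quantile ties can starve one class; enforce by rank if needed
    if y.sum() == 0 or y.sum() == y.size:
        order = np.argsort(liability, kind="stable")
        y = np.zeros(X.n_samples, dtype=np.int64)
        y[order[int(round((1.0 - prevalence) * y.size)):]] = 1
    return y, liability


def sample_case_control(y_true: np.ndarray, n_cases: int, n_controls: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Indices of a case/control study drawn without replacement per class."""
    cases = np.flatnonzero(y_true == 1)
    controls = np.flatnonzero(y_true == 0)
    if cases.size < n_cases or controls.size < n_controls:
        prev = y_true.mean()
        raise ValueError(
            f"population has {cases.size} cases / {controls.size} controls "
            f"(prevalence {prev:.3f}); cannot sample {n_cases}/{n_controls}"
        )
    pick_cases = rng.choice(cases, size=n_cases, replace=False)
    pick_controls = rng.choice(controls, size=n_controls, replace=False)
    return np.sort(np.concatenate([pick_cases, pick_controls]))


def inject_misclassification(y_true: np.ndarray, fraction: float,
                             rng: np.random.Generator):
    """Flip round(fraction * #controls) random controls to cases.

    Returns ``(y_observed, misclassified_mask)``; cases are never flipped
    (differential, false-positive-only noise).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    if fraction >= 1.0:
        raise ValueError("misclassification fraction must be < 1")
    mask = np.zeros(y_true.size, dtype=bool)
    if fraction > 0.0:
        controls = np.flatnonzero(y_true == 0)
        n_flip = int(round(fraction * controls.size))
        if n_flip < 1:
            raise ValueError(
                f"fraction {fraction} flips no control among {controls.size}"
            )
        mask[rng.choice(controls, size=n_flip, replace=False)] = True
    y_obs = y_true.copy()
    y_obs[mask] = 1
    return y_obs, mask


def variance_explained(X: GenotypeMatrix, beta_true: np.ndarray,
                       causal_indices: np.ndarray, u_true: np.ndarray,
                       eps: np.ndarray | None = None):
    """Per-causal-SNP fraction Var(X_l beta_l) / Var(sum_j X_j beta_j + u + eps)
    from empirical variances, plus realized liability heritability under two
    numerators (SNP-only and SNP + u, both labelled in the return).

    Returns ``(per_snp, {"snp_only": h2, "snp_plus_u": h2})``.
    """
    G = X.values[:, causal_indices]
    genetic = G @ beta_true
    if eps is None:
        # theoretical unit-variance noise when realized eps is unavailable
        total = float(np.var(genetic + u_true)) + 1.0
    else:
        total = float(np.var(genetic + u_true + eps))
    if total == 0.0:
        raise ValueError("zero total liability variance")
    per_snp = np.var(G * beta_true, axis=0) / total
    h2 = {
        "snp_only": float(np.var(genetic)) / total,
        "snp_plus_u": float(np.var(genetic + u_true)) / total,
    }
    return per_snp, h2


def simulate_study(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   u_population: np.ndarray | None = None,
                   population: GenotypeMatrix | None = None) -> SimulatedDataset:
    """Run the full generative recipe for one replicate.

    ``population`` and ``u_population`` allow the structured design to reuse
    one genotype pool and one random-effects vector across replicates (the
    per-replicate randomness is then the effect sizes, prevalence, phenotype
    noise, sampling, and label flips).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng

    if config.strategy == 1:
        X = population if population is not None else simulate_genotypes(
            config.n_population, config.m_snps, "categorical", rng)
        u = np.zeros(X.n_samples)
        causal = np.sort(rng.choice(X.n_snps, size=config.n_causal, replace=False))
        beta = draw_effect_sizes(config, X.maf[causal], rng)
        y_pop, liab = simulate_population_phenotype(X, beta, causal, u, 0.5, rng)
        n_cases = min(config.n_cases_sampled, int(y_pop.sum()))
        n_controls = min(config.n_controls_sampled, int((1 - y_pop).sum()))
        idx = sample_case_control(y_pop, n_cases, n_controls, rng)
    else:
        X = population if population is not None else simulate_genotypes(
            config.n_population, config.m_snps, "uniform", rng)
        if u_population is None:
            A = compute_grm(X, maf_min=config.grm_maf_min)
            u_population = simulate_random_effects(A, config.sigma_u2_true, rng)
        u = u_population
        causal = np.sort(rng.choice(X.n_snps, size=config.n_causal, replace=False))
        beta = draw_effect_sizes(config, X.maf[causal], rng)
        prevalence = rng.uniform(*config.prevalence_range)
        y_pop, liab = simulate_population_phenotype(X, beta, causal, u, prevalence, rng)
        idx = sample_case_control(y_pop, config.n_cases_sampled,
                                  config.n_controls_sampled, rng)

    X_study = X.subset_samples(idx)
    y_true = y_pop[idx]
    u_study = u[idx]
    liab_study = liab[idx]
    y_obs, mask = inject_misclassification(
        y_true, config.misclassification_fraction, rng)
    eps_pop = liab - (X.values[:, causal] @ beta + u)
    per_snp, h2 = variance_explained(X, beta, causal, u, eps=eps_pop)
    return SimulatedDataset(
        X=X_study,
        Y_true=PhenotypeVector(y_true),
        Y_observed=PhenotypeVector(y_obs),
        causal_indices=causal,
        beta_true=beta,
        u_true=u_study,
        liability=liab_study,
        misclassified_mask=mask,
        realized_prevalence=float(y_pop.mean()),
        variance_explained_per_snp=per_snp,
        heritability_snp=h2["snp_only"],
        heritability_snp_plus_u=h2["snp_plus_u"],
    )
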