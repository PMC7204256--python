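"""Adaptive Metropolis-Hastings-within-Gibbs sampler.

One iteration of the chain:

1. joint MH proposal for (alpha, lambda, beta) with truncated-normal
   proposals for the probabilities (Hastings-corrected) and normal proposals
   for the effects, accepted against the observed-data posterior;
2. Bernoulli misclassification indicators for every sample from the Bayes
   posteriors of the latent label, flipping the working latent phenotype;
3. latent liabilities from the truncated normal (Albert-Chib augmentation)
   conditioned on the working latent phenotype;
4. a sequential Gibbs scan over the random effects u given the liabilities
   and the inverse kinship matrix;
5. a draw of sigma_u^2 from its flat-prior conditional, a truncated
   inverse-gamma.

Proposal scales adapt multiplicatively toward a target acceptance rate
during burn-in only (diminishing gain), and post-burn-in iterations in the
label-switched mode (alpha < lambda) are excluded from the misclassification
averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import (
    gammaincc,
    gammainccinv,
    log_ndtr,
    ndtr,
    ndtri,
    ndtri_exp,
)

from .model import (
    case_misclassification_probability,
    control_misclassification_probability,
    log_posterior,
    probit_case_probability,
)
from .types import ModelParams, PhenotypeVector, PriorSpec, KinshipMatrix

__all__ = [
    "MCMCConfig",
    "ChainTrace",
    "MisclassificationResult",
    "initialize_state",
    "mh_update_params",
    "sample_misclassification_indicators",
    "sample_latent_liability",
    "gibbs_update_u",
    "gibbs_update_sigma_u2",
    "adapt_proposal_scales",
    "detect_and_filter_label_switch",
    "geweke_z",
    "run_chain",
    "aggregate_and_flag",
    "correct_phenotype",
]


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the full-scale analysis protocol."""

    n_iter: int = 100_000
    burn_in: int = 20_000
    target_acceptance: float = 0.2
    adapt_interval: int = 100
    initial_scale_alpha: float = 0.05
    initial_scale_lambda: float = 0.05
    initial_scale_beta: float = 0.1
    n_chains: int = 1
    seed: int | None = None
    t_percentile: float = 99.0
    intercept: bool = True
    center_genotypes: bool = False
    strict_paper_mode: bool = False
    disable_mixed_model: bool = False
    disable_adaptation: bool = False
    thin_trace: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")
        if not (0.0 < self.target_acceptance < 1.0):
            raise ValueError("target_acceptance must lie in (0, 1)")
        if not (0.0 < self.t_percentile < 100.0):
            raise ValueError("t_percentile must lie in (0, 100)")
        if self.strict_paper_mode:
            # strict mode: no intercept column, fixed proposal scales off
            self.intercept = False


@dataclass
class ChainTrace:
    """Per-iteration scalar records of one chain plus bookkeeping."""

    alpha: np.ndarray
    lambda_: np.ndarray
    sigma_u2: np.ndarray
    log_post: np.ndarray
    beta_mean: np.ndarray
    accepted: np.ndarray  # boolean per iteration (joint block)
    burn_in: int
    mark_counts: np.ndarray
    denominator: int
    discarded_switch_iterations: int
    geweke_scores: dict = field(default_factory=dict)
    converged: bool = False
    acceptance_rate: float = np.nan
    final_scales: dict = field(default_factory=dict)
    usable: bool = True

    @property
    def n_iter(self) -> int:
        return self.alpha.size

    def avg_misclassification_prob(self) -> np.ndarray:
        """Marks divided by retained post-burn-in iterations."""
        if self.denominator == 0:
            return np.zeros_like(self.mark_counts, dtype=float)
        return self.mark_counts / float(self.denominator)

    def to_dataframe(self, thin: int = 1):
        import pandas as pd

        idx = np.arange(0, self.n_iter, thin)
        return pd.DataFrame(
            {
                "iteration": idx,
                "alpha": self.alpha[idx],
                "lambda": self.lambda_[idx],
                "sigma_u2": self.sigma_u2[idx],
                "log_posterior": self.log_post[idx],
                "beta_mean": self.beta_mean[idx],
                "accepted": self.accepted[idx].astype(int),
            }
        )


@dataclass
class MisclassificationResult:
    """Aggregated per-sample misclassification probabilities and flags."""

    avg_prob: np.ndarray
    flagged: np.ndarray
    threshold_value: float
    chains_used: int
    sample_ids: np.ndarray | None = None


def initialize_state(priors: PriorSpec, n: int, m: int, rng: np.random.Generator) -> ModelParams:
    """Random starting state: alpha, lambda, beta from their priors; u = 0,
    sigma_u2 = 0.1."""
    if n < 1 or m < 1:
        raise ValueError("need n >= 1 samples and m >= 1 effect columns")
    a0, b0 = priors.alpha_prior
    a1, b1 = priors.lambda_prior
    mu, sd = priors.beta_prior
    return ModelParams(
        alpha=float(rng.beta(a0, b0)),
        lambda_=float(rng.beta(a1, b1)),
        beta=rng.normal(mu, sd, size=m),
        u=np.zeros(n),
        sigma_u2=0.1,
    )


def _truncnorm_draw(rng: np.random.Generator, loc: float, scale: float,
                    lo: float, hi: float) -> float:
    # inverse-CDF draw; the centre always lies inside (lo, hi) here, so the
    # plain Phi/Phi^-1 form is numerically safe
    a, b = (lo - loc) / scale, (hi - loc) / scale
    fa, fb = ndtr(a), ndtr(b)
    x = loc + scale * ndtri(fa + rng.uniform() * (fb - fa))
    return float(min(max(x, lo + 1e-12), hi - 1e-12))


def _truncnorm_lognorm(loc: float, scale: float, lo: float, hi: float) -> float:
    """log of the (0,1)-truncation normalising constant of N(loc, scale^2)."""
    z = ndtr((hi - loc) / scale) - ndtr((lo - loc) / scale)
    return float(np.log(max(z, np.finfo(float).tiny)))


def mh_update_params(current: ModelParams, Y, X, priors: PriorSpec, scales: dict,
                     rng: np.random.Generator,
                     current_log_post: float | None = None):
    """One joint Metropolis-Hastings update of (alpha, lambda, beta).

    alpha and lambda are proposed from normals truncated to (0, 1) centred at
    the current values (with the asymmetric-proposal Hastings correction);
    beta is proposed from independent normals.  The whole block is accepted
    or rejected with a single ratio of the observed-data posterior.

    Returns ``(params, accepted, log_post_of_returned_state)``.
    """
    if current_log_post is None:
        current_log_post = log_posterior(current, Y, X, priors)
    s_a, s_l = scales["alpha"], scales["lambda"]
    s_b = np.broadcast_to(np.atleast_1d(scales["beta"]), current.beta.shape)

    alpha_p = _truncnorm_draw(rng, current.alpha, s_a, 0.0, 1.0)
    lambda_p = _truncnorm_draw(rng, current.lambda_, s_l, 0.0, 1.0)
    beta_p = current.beta + s_b * rng.standard_normal(current.beta.size)
    proposal = ModelParams(
        alpha=alpha_p, lambda_=lambda_p, beta=beta_p,
        u=current.u, sigma_u2=current.sigma_u2,
    )
    prop_log_post = log_posterior(proposal, Y, X, priors)

    # Hastings correction: the truncation constant depends on the centre.
    correction = (
        _truncnorm_lognorm(current.alpha, s_a, 0.0, 1.0)
        - _truncnorm_lognorm(alpha_p, s_a, 0.0, 1.0)
        + _truncnorm_lognorm(current.lambda_, s_l, 0.0, 1.0)
        - _truncnorm_lognorm(lambda_p, s_l, 0.0, 1.0)
    )
    log_ratio = prop_log_post - current_log_post + correction
    if np.isfinite(prop_log_post) and np.log(rng.uniform()) < log_ratio:
        return proposal, True, prop_log_post
    return current, False, current_log_post


def sample_misclassification_indicators(params: ModelParams, Y, sigma: np.ndarray,
                                        rng: np.random.Generator):
    """Bernoulli misclassification marks and the implied latent phenotype.

    Each observed case is marked with the case posterior Pr(Y'=0 | Y=1) and
    each control with Pr(Y'=1 | Y=0); marked samples have their working
    latent label flipped for this iteration.
    """
    y = np.asarray(getattr(Y, "values", Y), dtype=np.int64)
    p_case = case_misclassification_probability(params.alpha, params.lambda_, sigma)
    p_ctrl = control_misclassification_probability(params.alpha, params.lambda_, sigma)
    p_mark = np.where(y == 1, p_case, p_ctrl)
    marked = rng.uniform(size=y.size) < p_mark
    y_latent = np.where(marked, 1 - y, y)
    return marked, y_latent


def sample_latent_liability(y_latent, X, beta, u, rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal liabilities: l_i ~ N(X_i beta + u_i, 1), positive for
    latent cases and non-positive for latent controls (inverse-CDF draw, safe
    far into the truncated tail)."""
    y_latent = np.asarray(y_latent, dtype=np.int64)
    Xmat = np.asarray(getattr(X, "values", X), dtype=float)
    mean = Xmat @ np.atleast_1d(beta) + np.atleast_1d(u)
    # one-sided truncation at 0 via the upper-tail inverse CDF in log space:
    # for Z ~ N(0,1) truncated to (a, inf), P(Z > z) = U * Phi(-a) gives
    # z = -ndtri_exp(log U + log_ndtr(-a)), stable however deep the tail.
    log_u = np.log(rng.uniform(size=mean.size))
    pos = y_latent == 1
    # positive part: a = -mean; negative part by symmetry with mean -> -mean
    sgn = np.where(pos, 1.0, -1.0)
    z = -ndtri_exp(log_u + log_ndtr(sgn * mean))
    return mean + sgn * z


@njit(cache=False)
def _u_scan(resid, A_inv, gamma, u, z):  # pragma: no cover - compiled
    n = resid.shape[0]
    for i in range(n):
        cii = A_inv[i, i]
        dot = -cii * u[i]
        for j in range(n):
            dot += A_inv[i, j] * u[j]
        var = 1.0 / (1.0 + cii * gamma)
        u[i] = var * (resid[i] - gamma * dot) + np.sqrt(var) * z[i]
    return u


def gibbs_update_u(l, X, beta, u, A_inv, sigma_u2, rng: np.random.Generator) -> np.ndarray:
    """Sequential single-site Gibbs scan over the random effects.

    Conditional for each component: u_i ~ N(u_hat_i, (1 + c_ii * gamma)^-1)
    with u_hat_i = (1 + c_ii*gamma)^-1 * ((l_i - X_i beta) - gamma * c_{i,-i} u_{-i}),
    where c are entries of A^-1 and gamma = 1/sigma_u2.  Components later in
    the scan condition on the already-updated earlier components.
    """
    Xmat = np.asarray(getattr(X, "values", X), dtype=float)
    resid = np.asarray(l, dtype=float) - Xmat @ np.atleast_1d(beta)
    u = np.array(u, dtype=float, copy=True)
    z = rng.standard_normal(u.size)
    return _u_scan(resid, np.ascontiguousarray(A_inv, dtype=float),
                   1.0 / float(sigma_u2), u, z)


def gibbs_update_sigma_u2(u, A_inv, n: int, sigma_u2_max: float,
                          rng: np.random.Generator,
                          current: float | None = None) -> float:
    """Draw sigma_u2 from its flat-prior conditional.

    Density proportional to (s2)^(-q/2) exp(-S / (2 s2)) on (0, sigma_u2_max]
    with S = u' A^-1 u and q = n, i.e. an inverse-gamma(q/2 - 1, S/2)
    truncated at the upper bound, sampled by inverse CDF.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    S = float(u @ (A_inv @ u))
    if S <= 0.0:
        # degenerate (u all zero, e.g. right after initialisation)
        return float(current) if current is not None else 0.1
    shape = n / 2.0 - 1.0
    if shape > 0.0:
        # inverse-gamma CDF F(x) = Q(shape, (S/2)/x) with Q the regularised
        # upper incomplete gamma; truncated inverse-CDF draw via gammainccinv
        s2 = S / 2.0
        f_hi = float(gammaincc(shape, s2 / sigma_u2_max))
        if f_hi <= 0.0:
            return float(sigma_u2_max)
        return float(s2 / gammainccinv(shape, rng.uniform() * f_hi))
    # q <= 2: not inverse-gamma-normalisable in shape; numeric inverse CDF
    grid = np.geomspace(1e-8, sigma_u2_max, 4096)
    logpdf = -(n / 2.0) * np.log(grid) - S / (2.0 * grid)
    pdf = np.exp(logpdf - logpdf.max())
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return float(np.interp(rng.uniform(), cdf, grid))


def adapt_proposal_scales(scales: dict, acceptance_rate: float, target: float = 0.2,
                          batch: int = 1) -> dict:
    """Multiplicative log-scale adaptation with diminishing gain 1/batch."""
    kappa = 1.0 / max(1, batch)
    factor = float(np.exp(kappa * (acceptance_rate - target)))
    out = {}
    for key, val in scales.items():
        out[key] = np.asarray(val) * factor if isinstance(val, np.ndarray) else val * factor
    return out


def detect_and_filter_label_switch(alpha: np.ndarray, lambda_: np.ndarray,
                                   burn_in: int = 0):
    """Mask of post-burn-in iterations in the identifiable mode (alpha > lambda).

    Returns ``(keep_mask, discarded_count, usable)``; a chain discarding more
    than half of its post-burn-in iterations to the switched mode is flagged
    not usable.
    """
    alpha = np.asarray(alpha, dtype=float)
    lambda_ = np.asarray(lambda_, dtype=float)
    keep = alpha > lambda_
    keep[:burn_in] = False
    post = alpha.size - burn_in
    discarded = int(post - keep[burn_in:].sum())
    usable = post > 0 and discarded <= 0.5 * post
    return keep, discarded, usable


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Yule-Walker AR fit."""
    x = np.asarray(x, dtype=float)
    n = x.size
    var = x.var(ddof=1)
    if var == 0.0 or n < 8:
        return var
    order = int(min(10, max(1, n // 50)))
    from statsmodels.regression.linear_model import yule_walker

    rho, sigma = yule_walker(x - x.mean(), order=order, method="mle")
    denom = 1.0 - rho.sum()
    if abs(denom) < 1e-8:
        return var
    return float(sigma**2 / denom**2)


def geweke_z(series, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means.

    z = (mean_first - mean_last) / sqrt(se_first^2 + se_last^2) with
    spectral-density-at-zero standard errors; |z| < 1.96 indicates the two
    segments agree (convergence at the 95% level).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 100:
        raise ValueError("series too short for the Geweke diagnostic (need >= 100)")
    n1 = int(first_frac * x.size)
    n2 = int(last_frac * x.size)
    a, b = x[:n1], x[x.size - n2:]
    if a.var() == 0.0 and b.var() == 0.0:
        if a.mean() == b.mean():
            return 0.0
        return np.inf if a.mean() > b.mean() else -np.inf
    se2 = _spectral_density_zero(a) / n1 + _spectral_density_zero(b) / n2
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def _design_matrix(X, intercept: bool, center: bool) -> np.ndarray:
    D = np.asarray(getattr(X, "values", X), dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    if center:
        D = D - D.mean(axis=0)
    if intercept:
        D = np.column_stack([np.ones(D.shape[0]), D])
    return D


def run_chain(Y, X_train, A, priors: PriorSpec | None, config: MCMCConfig,
              rng: np.random.Generator | None = None) -> ChainTrace:
    """Run one MCMC chain and accumulate per-sample misclassification marks.

    Parameters
    ----------
    Y : PhenotypeVector or 0/1 array of observed labels.
    X_train : training-SNP genotype matrix (filtered upstream).
    A : KinshipMatrix (ignored when ``config.disable_mixed_model``).
    priors : PriorSpec (defaults to PriorSpec()).
    config : MCMCConfig.
    rng : numpy Generator; defaults to one seeded from ``config.seed``.
    """
    if priors is None:
        priors = PriorSpec()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = np.asarray(getattr(Y, "values", Y), dtype=np.int64)
    n = y.size
    D = _design_matrix(X_train, config.intercept, config.center_genotypes)
    if D.shape[0] != n:
        raise ValueError("genotype rows must match phenotype length")
    k = D.shape[1]

    mixed = not config.disable_mixed_model
    if mixed:
        if A is None:
            raise ValueError("kinship matrix required unless disable_mixed_model")
        if not isinstance(A, KinshipMatrix):
            A = KinshipMatrix(np.asarray(A, dtype=float))
        A_inv = np.ascontiguousarray(A.inverse)

    params = initialize_state(priors, n, k, rng)
    scales = {
        "alpha": config.initial_scale_alpha,
        "lambda": config.initial_scale_lambda,
        "beta": np.full(k, config.initial_scale_beta),
    }
    clp = log_posterior(params, y, D, priors)

    n_iter, burn_in = config.n_iter, config.burn_in
    tr_alpha = np.empty(n_iter)
    tr_lambda = np.empty(n_iter)
    tr_s2 = np.empty(n_iter)
    tr_lp = np.empty(n_iter)
    tr_bmean = np.empty(n_iter)
    tr_acc = np.zeros(n_iter, dtype=bool)
    marks = np.zeros(n, dtype=np.int64)
    denominator = 0
    acc_window = 0
    batch = 0
    post_acc = 0

    for it in range(n_iter):
        params, accepted, clp = mh_update_params(params, y, D, priors, scales, rng, clp)
        sigma = probit_case_probability(D, params.beta, params.u)
        marked, y_latent = sample_misclassification_indicators(params, y, sigma, rng)

        if mixed:
            l = sample_latent_liability(y_latent, D, params.beta, params.u, rng)
            params.u = gibbs_update_u(l, D, params.beta, params.u, A_inv,
                                      params.sigma_u2, rng)
            params.sigma_u2 = gibbs_update_sigma_u2(
                params.u, A_inv, n, priors.sigma_u2_max, rng, current=params.sigma_u2
            )
            clp = log_posterior(params, y, D, priors)

        tr_alpha[it] = params.alpha
        tr_lambda[it] = params.lambda_
        tr_s2[it] = params.sigma_u2
        tr_lp[it] = clp
        tr_bmean[it] = params.beta.mean()
        tr_acc[it] = accepted
        acc_window += accepted

        if not np.isfinite(clp) or not np.all(np.isfinite(params.u)):
            raise FloatingPointError(f"non-finite sampler state at iteration {it}")

        if it >= burn_in:
            post_acc += accepted
            if params.alpha > params.lambda_:
                marks += marked
                denominator += 1
        elif (not config.disable_adaptation) and (it + 1) % config.adapt_interval == 0:
            batch += 1
            rate = acc_window / config.adapt_interval
            scales = adapt_proposal_scales(scales, rate, config.target_acceptance, batch)
            acc_window = 0
        if (it + 1) % config.adapt_interval == 0:
            acc_window = 0

    keep, discarded, usable = detect_and_filter_label_switch(tr_alpha, tr_lambda, burn_in)
    geweke = {}
    post = slice(burn_in, n_iter)
    for name, series in (("alpha", tr_alpha[post]), ("lambda", tr_lambda[post]),
                         ("sigma_u2", tr_s2[post])):
        if name == "sigma_u2" and not mixed:
            continue
        try:
            geweke[name] = geweke_z(series)
        except ValueError:
            geweke[name] = np.nan
    converged = all(np.isfinite(z) and abs(z) < 1.96 for z in geweke.values())

    return ChainTrace(
        alpha=tr_alpha, lambda_=tr_lambda, sigma_u2=tr_s2, log_post=tr_lp,
        beta_mean=tr_bmean, accepted=tr_acc, burn_in=burn_in,
        mark_counts=marks, denominator=denominator,
        discarded_switch_iterations=discarded,
        geweke_scores=geweke, converged=converged,
        acceptance_rate=float(tr_acc[post].mean()),
        final_scales={"alpha": scales["alpha"], "lambda": scales["lambda"],
                      "beta": np.asarray(scales["beta"]).copy()},
        usable=usable,
    )


def aggregate_and_flag(prob_sources, Y, t_percentile: float = 99.0,
                       sample_ids=None) -> MisclassificationResult:
    """Average misclassification probabilities across runs and flag cases.

    ``prob_sources`` is a list of per-sample probability vectors (one per
    usable chain/run) or ChainTrace objects.  The threshold t is the given
    percentile of the averaged probabilities over *cases*; cases strictly
    above t are flagged.
    """
    y = np.asarray(getattr(Y, "values", Y), dtype=np.int64)
    vecs = []
    for src in prob_sources:
        if isinstance(src, ChainTrace):
            if not src.usable:
                continue
            vecs.append(src.avg_misclassification_prob())
        else:
            vecs.append(np.asarray(src, dtype=float))
    if not vecs:
        raise RuntimeError(
            "no usable converged chains; run more chains (multi-chain policy) "
            "and keep those passing the Geweke diagnostic"
        )
    avg = np.mean(vecs, axis=0)
    if avg.shape != y.shape:
        raise ValueError("probability vectors must match phenotype length")
    case_probs = avg[y == 1]
    threshold = float(np.percentile(case_probs, t_percentile))
    flagged = (y == 1) & (avg > threshold)
    return MisclassificationResult(
        avg_prob=avg, flagged=flagged, threshold_value=threshold,
        chains_used=len(vecs), sample_ids=sample_ids,
    )


def correct_phenotype(Y, flags) -> PhenotypeVector:
    """Switch flagged cases to controls; controls must never be flagged."""
    pv = Y if isinstance(Y, PhenotypeVector) else PhenotypeVector(np.asarray(Y))
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != pv.values.shape:
        raise ValueError("flags must match phenotype length")
    if np.any(flags & (pv.values == 0)):
        raise ValueError("flag set on a control; only cases may be switched")
    corrected = pv.values.copy()
    corrected[flags] = 0
    return PhenotypeVector(values=corrected, sample_ids=pv.sample_ids)
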