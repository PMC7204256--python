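"""Probability kernel of the misclassification model.

The model: a latent true phenotype Y' follows a probit mixed model,
Pr(Y'_i = 1 | beta, u) = Phi(X_i beta + u_i), and the observed label Y is a
noisy copy of Y' with true-positive probability alpha = P(Y=1 | Y'=1) and
false-positive probability lambda = P(Y=1 | Y'=0).  Marginalising Y' gives
the observed-data likelihood

    Pr(Y | alpha, lambda, beta, u) =
        prod_i [lambda (1-s_i) + alpha s_i]^{Y_i}
               [(1-lambda)(1-s_i) + (1-alpha) s_i]^{1-Y_i},

with s_i = Phi(X_i beta + u_i).  Bayes' rule on the (Y', Y) joint yields the
per-sample misclassification posteriors used to mark samples each MCMC
iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, ndtr

from .types import ModelParams, PriorSpec

__all__ = [
    "SIGMA_CLIP",
    "probit_case_probability",
    "case_misclassification_probability",
    "control_misclassification_probability",
    "log_likelihood_observed",
    "log_prior",
    "log_posterior",
]

#: probabilities from the probit link are clipped to [SIGMA_CLIP, 1-SIGMA_CLIP]
#: before entering logs or odds ratios.
SIGMA_CLIP = 1e-10


def probit_case_probability(X, beta, u) -> np.ndarray:
    """Per-sample latent case probability s_i = Phi(X_i beta + u_i).

    Parameters
    ----------
    X : (n, k) design matrix over training SNPs (plus intercept column when
        used); may also be a bare array.
    beta : (k,) effect vector.
    u : (n,) random-effect vector.

    Returns
    -------
    (n,) array of probabilities strictly inside (0, 1).
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] != beta.size:
        raise ValueError(f"beta length {beta.size} != {X.shape[1]} columns of X")
    if X.shape[0] != u.size:
        raise ValueError(f"u length {u.size} != {X.shape[0]} rows of X")
    eta = X @ beta + u
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return np.clip(ndtr(eta), SIGMA_CLIP, 1.0 - SIGMA_CLIP)


def case_misclassification_probability(alpha, lambda_, sigma_i):
    """Pr(Y' = 0 | Y = 1): posterior that an observed case is a true control.

    Bayes' rule over the latent state: lambda (1-s) / (lambda (1-s) + alpha s).
    Vectorised over ``sigma_i``.
    """
    sigma_i = np.clip(np.asarray(sigma_i, dtype=float), SIGMA_CLIP, 1.0 - SIGMA_CLIP)
    num = lambda_ * (1.0 - sigma_i)
    den = num + alpha * sigma_i
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0.0, num / np.maximum(den, np.finfo(float).tiny), 1.0)
    return out if out.ndim else float(out)


def control_misclassification_probability(alpha, lambda_, sigma_i):
    """Pr(Y' = 1 | Y = 0): posterior that an observed control is a true case.

    Bayes' rule: (1-alpha) s / ((1-alpha) s + (1-lambda)(1-s)).
    """
    sigma_i = np.clip(np.asarray(sigma_i, dtype=float), SIGMA_CLIP, 1.0 - SIGMA_CLIP)
    num = (1.0 - alpha) * sigma_i
    den = num + (1.0 - lambda_) * (1.0 - sigma_i)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0.0, num / np.maximum(den, np.finfo(float).tiny), 0.0)
    return out if out.ndim else float(out)


def log_likelihood_observed(Y, sigma, alpha, lambda_) -> float:
    """Observed-data log-likelihood of the two-component label mixture."""
    y = np.asarray(getattr(Y, "values", Y), dtype=float)
    sigma = np.clip(np.asarray(sigma, dtype=float), SIGMA_CLIP, 1.0 - SIGMA_CLIP)
    if y.shape != sigma.shape:
        raise ValueError("Y and sigma must have matching lengths")
    p_case = lambda_ * (1.0 - sigma) + alpha * sigma
    p_ctrl = (1.0 - lambda_) * (1.0 - sigma) + (1.0 - alpha) * sigma
    p_case = np.clip(p_case, np.finfo(float).tiny, None)
    p_ctrl = np.clip(p_ctrl, np.finfo(float).tiny, None)
    return float(np.sum(y * np.log(p_case) + (1.0 - y) * np.log(p_ctrl)))


def log_prior(params: ModelParams, priors: PriorSpec) -> float:
    """Log prior density over (alpha, lambda, beta); flat truncated sigma_u2.

    Returns -inf when sigma_u2 falls outside (0, sigma_u2_max]."""
    if not (0.0 < params.sigma_u2 <= priors.sigma_u2_max):
        return -np.inf
    a0, b0 = priors.alpha_prior
    a1, b1 = priors.lambda_prior
    mu, sd = priors.beta_prior
    lp = _beta_logpdf(params.alpha, a0, b0)
    lp += _beta_logpdf(params.lambda_, a1, b1)
    z = (params.beta - mu) / sd
    lp += float(-0.5 * np.sum(z * z) - params.beta.size
                * (np.log(sd) + 0.5 * np.log(2.0 * np.pi)))
    return float(lp)


def _beta_logpdf(x: float, a: float, b: float) -> float:
    if not (0.0 < x < 1.0):
        return -np.inf
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def log_posterior(params: ModelParams, Y, X, priors: PriorSpec) -> float:
    """Unnormalised log posterior used by the Metropolis-Hastings block.

    Likelihood of the observed labels plus the priors on alpha, lambda and
    beta; the flat sigma_u2 prior contributes 0 inside its support and -inf
    outside (the state is then rejected rather than raising).
    """
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    sigma = probit_case_probability(X, params.beta, params.u)
    return lp + log_likelihood_observed(Y, sigma, params.alpha, params.lambda_)
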