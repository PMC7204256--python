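"""GWAS utilities: GRM, linear mixed-model association, multiple testing,
training-SNP selection, LD metrics and discovery identification.

The association scan treats the binary phenotype as quantitative and uses the
standard two-step mixed-model approximation: variance components are fitted
once on the null model by REML against the eigendecomposition of the GRM,
after which every SNP is tested by a Wald test in the whitened coordinates.
With an identity GRM this reduces exactly to per-SNP ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .types import GenotypeMatrix, KinshipMatrix

__all__ = [
    "AssociationResult",
    "TrainingSet",
    "compute_grm",
    "lmm_association",
    "bonferroni_threshold",
    "benjamini_hochberg",
    "select_training_snps",
    "ld_r2",
    "ld_prune",
    "identify_discoveries",
]


@dataclass
class TrainingSet:
    """SNP indices passing the association p-value filter."""

    indices: np.ndarray
    p_filter: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class AssociationResult:
    """Per-SNP association table."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, p, p_bh [, flags]

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def p_bh(self) -> np.ndarray:
        return self.table["p_bh"].to_numpy()


def compute_grm(X: GenotypeMatrix, maf_min: float = 0.05) -> KinshipMatrix:
    """Standardized genomic relatedness matrix A = Z Z' / m*.

    Columns with MAF > ``maf_min`` are centred at 2f and scaled by
    sqrt(2 f (1 - f)); the resulting matrix has mean diagonal ~ 1.
    """
    keep = X.maf > maf_min
    m_star = int(keep.sum())
    if m_star < 2:
        raise ValueError(f"need >= 2 SNPs with MAF > {maf_min}; got {m_star}")
    G = X.values[:, keep]
    f = G.mean(axis=0) / 2.0
    Z = (G - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    return KinshipMatrix((Z @ Z.T) / m_star)


def _reml_delta(y: np.ndarray, C: np.ndarray, eigvals: np.ndarray,
                eigvecs: np.ndarray) -> float:
    """REML estimate of delta = sigma_e^2 / sigma_g^2 on the null model.

    Works in the rotated basis of the GRM eigendecomposition; the profile
    REML log-likelihood is maximised over log10(delta) in [-6, 6].
    """
    n, p = C.shape
    yr = eigvecs.T @ y
    Cr = eigvecs.T @ C

    def neg_reml(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        v = eigvals + delta
        w = 1.0 / v
        CtWC = (Cr * w[:, None]).T @ Cr
        CtWy = (Cr * w[:, None]).T @ yr
        try:
            bhat = np.linalg.solve(CtWC, CtWy)
        except np.linalg.LinAlgError:
            return np.inf
        resid = yr - Cr @ bhat
        rss = float(resid @ (w * resid))
        df = n - p
        sign, logdet_CtWC = np.linalg.slogdet(CtWC)
        if sign <= 0:
            return np.inf
        # profile REML (up to constants): df*log(rss) + sum log v + log|C'V^-1C|
        return df * np.log(rss) + float(np.sum(np.log(v))) + logdet_CtWC

    grid = np.linspace(-6.0, 6.0, 25)
    vals = [neg_reml(g) for g in grid]
    i0 = int(np.argmin(vals))
    lo, hi = grid[max(0, i0 - 1)], grid[min(grid.size - 1, i0 + 1)]
    res = minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(10.0 ** res.x)


def lmm_association(Y, X: GenotypeMatrix, A: KinshipMatrix | None = None,
                    covariates: np.ndarray | None = None) -> AssociationResult:
    """Per-SNP mixed-model association scan.

    The phenotype (binary, analysed on the quantitative scale) is modelled as
    y = C b + g beta + e with cov = sigma_g^2 A + sigma_e^2 I.  delta is
    fitted once on the null model (intercept + covariates) by REML; each SNP
    is then tested by a Wald t-test in the whitened coordinates with the
    residual variance re-estimated per SNP, so A = I reproduces OLS exactly.
    """
    y = np.asarray(getattr(Y, "values", Y), dtype=float)
    n = y.size
    if X.n_samples != n:
        raise ValueError("genotype rows must match phenotype length")
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([C, cov])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        r = np.linalg.matrix_rank(C)
        raise ValueError(
            f"singular covariate design: rank {r} < {C.shape[1]} columns "
            "(collinear covariate columns, including the intercept)"
        )

    if A is None:
        w = np.ones(n)
        yr, Cr, Gr = y, C, X.values
    else:
        eigvals, eigvecs = np.linalg.eigh(A.jittered)
        eigvals = np.maximum(eigvals, 0.0)
        delta = _reml_delta(y, C, eigvals, eigvecs)
        w = 1.0 / np.sqrt(eigvals + delta)
        yr = w * (eigvecs.T @ y)
        Cr = w[:, None] * (eigvecs.T @ C)
        Gr = w[:, None] * (eigvecs.T @ X.values)

    # residualise y and all SNPs against the covariate block (Frisch-Waugh)
    Q, _ = np.linalg.qr(Cr)
    y_res = yr - Q @ (Q.T @ yr)
    G_res = Gr - Q @ (Q.T @ Gr)

    gtg = np.einsum("ij,ij->j", G_res, G_res)
    gty = G_res.T @ y_res
    yty = float(y_res @ y_res)
    dof = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gtg > 0, gty / np.where(gtg > 0, gtg, 1.0), 0.0)
        rss = np.maximum(yty - beta * gty, 0.0)
        se = np.sqrt(rss / dof / np.where(gtg > 0, gtg, np.inf))
        tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "snp_id": X.snp_ids,
            "chrom": X.chrom,
            "pos": X.pos,
            "beta": beta,
            "p": p,
            "p_bh": benjamini_hochberg(p),
        }
    )
    return AssociationResult(table=table)


def bonferroni_threshold(m: int, family_alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / m (e.g. 0.05 / 100,000 = 10^-6.3)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def select_training_snps(results: AssociationResult, p_filter: float) -> TrainingSet:
    """SNPs with unadjusted p below the filter; empty selections warn."""
    idx = np.flatnonzero(results.p < p_filter)
    if idx.size == 0:
        warnings.warn(
            f"no SNP passes the training filter p < {p_filter:g}; the "
            "misclassification model cannot run without informative SNPs",
            stacklevel=2,
        )
    return TrainingSet(indices=idx, p_filter=p_filter)


def ld_r2(x_i, x_j) -> float:
    """Squared Pearson correlation of genotype dosages; NaN for constants."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("genotype vectors must have equal length")
    if np.std(x_i) == 0.0 or np.std(x_j) == 0.0:
        return float("nan")
    r = np.corrcoef(x_i, x_j)[0, 1]
    return float(r * r)


def _max_r2_with(X: GenotypeMatrix, training_idx: np.ndarray) -> np.ndarray:
    """Max r^2 of every SNP with any training SNP (NaN-safe, 0 when empty)."""
    if training_idx.size == 0:
        return np.zeros(X.n_snps)
    G = X.values
    sd = G.std(axis=0)
    T = G[:, training_idx]
    sd_t = sd[training_idx]
    Gc = G - G.mean(axis=0)
    Tc = T - T.mean(axis=0)
    n = G.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Gc.T @ Tc) / n / np.outer(sd, sd_t)
    r2 = np.nan_to_num(corr**2, nan=0.0)
    return r2.max(axis=1)


def ld_prune(X: GenotypeMatrix, window_kb: float = 50.0, step: int = 5,
             r2_threshold: float = 0.20) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Within each window (SNPs of one chromosome whose positions fall in
    [pos_w, pos_w + window_kb * 1000)), pairs with r^2 above the threshold are
    resolved by removing the lower-MAF member (position breaks ties); the
    window start advances by ``step`` SNPs.
    """
    removed = np.zeros(X.n_snps, dtype=bool)
    order = np.arange(X.n_snps)
    for chrom in pd.unique(X.chrom):
        idx = order[X.chrom == chrom]
        pos = X.pos[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted within chromosome {chrom}")
        start = 0
        while start < idx.size:
            lo_pos = pos[start]
            in_win = idx[(pos >= lo_pos) & (pos < lo_pos + window_kb * 1000.0)]
            in_win = in_win[~removed[in_win]]
            if in_win.size >= 2:
                G = X.values[:, in_win]
                sd = G.std(axis=0)
                Gc = G - G.mean(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    corr = (Gc.T @ Gc) / G.shape[0] / np.outer(sd, sd)
                r2 = np.nan_to_num(corr**2, nan=0.0)
                np.fill_diagonal(r2, 0.0)
                active = np.ones(in_win.size, dtype=bool)
                while True:
                    sub = r2[np.ix_(active, active)]
                    if sub.size == 0 or sub.max() <= r2_threshold:
                        break
                    ai = np.flatnonzero(active)
                    i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
                    gi, gj = ai[i_loc], ai[j_loc]
                    # remove the lower-MAF member; ties broken by position
                    mi, mj = X.maf[in_win[gi]], X.maf[in_win[gj]]
                    if mi < mj:
                        drop = gi
                    elif mj < mi:
                        drop = gj
                    else:
                        drop = gi if X.pos[in_win[gi]] >= X.pos[in_win[gj]] else gj
                    active[drop] = False
                    removed[in_win[drop]] = True
            start += step
    return np.flatnonzero(~removed)


def identify_discoveries(original_results: AssociationResult,
                         corrected_results: AssociationResult,
                         training: TrainingSet, X: GenotypeMatrix,
                         k: float = 1e-2, bh_threshold: float = 0.1) -> pd.DataFrame:
    """SNPs newly significant after phenotype correction, independent of training.

    A discovery is a non-training SNP whose max r^2 with every training SNP is
    below ``k``, with BH-adjusted p < ``bh_threshold`` under the corrected
    phenotype but not under the original phenotype.
    """
    orig, corr = original_results.table, corrected_results.table
    if not np.array_equal(orig["snp_id"].to_numpy(), corr["snp_id"].to_numpy()):
        raise ValueError("original and corrected results cover different SNP universes")
    m = len(orig)
    is_training = np.zeros(m, dtype=bool)
    is_training[training.indices] = True
    max_r2 = _max_r2_with(X, training.indices)
    sig_corr = corr["p_bh"].to_numpy() < bh_threshold
    sig_orig = orig["p_bh"].to_numpy() < bh_threshold
    disc = (~is_training) & (max_r2 < k) & sig_corr & (~sig_orig)
    out = corr.loc[disc, ["snp_id", "chrom", "pos", "beta", "p", "p_bh"]].copy()
    out["max_r2_with_training"] = max_r2[disc]
    return out.reset_index(drop=True)
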