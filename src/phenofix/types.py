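"""Core domain containers shared across the package.

All containers are thin dataclasses over numpy arrays with eager validation:
genotypes are unphased allele counts in {0, 1, 2}, phenotypes are binary
case/control labels, and the kinship matrix is the covariance scale of the
polygenic random effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "KinshipMatrix",
    "PriorSpec",
    "ModelParams",
]


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class GenotypeMatrix:
    """n x m matrix of allele counts with per-SNP metadata.

    Attributes
    ----------
    values : (n, m) array of 0/1/2 allele counts (no missing values).
    snp_ids, chrom, pos : per-SNP identifier, chromosome label, 1-based
        base-pair position.
    maf : per-SNP minor-allele frequency in [0, 0.5], consistent with
        ``values``.
    """

    values: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 samples and m >= 1 SNPs, got {n} x {m}")
        if not np.isin(self.values, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype values must be allele counts in {0, 1, 2}")
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        for name, arr in (
            ("snp_ids", self.snp_ids),
            ("chrom", self.chrom),
            ("pos", self.pos),
            ("maf", self.maf),
        ):
            if arr.shape != (m,):
                raise ValueError(f"{name} must have length m={m}, got {arr.shape}")
        expected = self.computed_maf()
        if np.max(np.abs(expected - self.maf)) > 1e-12:
            raise ValueError("stored maf inconsistent with genotype values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def computed_maf(self) -> np.ndarray:
        """Minor-allele frequency recomputed from the allele counts."""
        freq = self.values.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            maf=self.maf[idx],
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        vals = self.values[idx, :]
        freq = vals.mean(axis=0) / 2.0
        return GenotypeMatrix(
            values=vals,
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            maf=np.minimum(freq, 1.0 - freq),
        )

    @classmethod
    def from_counts(cls, values, snp_ids=None, chrom=None, pos=None) -> "GenotypeMatrix":
        """Build from a raw count matrix, deriving metadata defaults."""
        values = _as_2d_float(values)
        m = values.shape[1]
        if snp_ids is None:
            snp_ids = np.array([f"snp{j}" for j in range(m)])
        if chrom is None:
            chrom = np.array(["1"] * m)
        if pos is None:
            pos = np.arange(1, m + 1, dtype=np.int64)
        freq = values.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        return cls(values=values, snp_ids=snp_ids, chrom=chrom, pos=pos, maf=maf)


@dataclass
class PhenotypeVector:
    """Binary case (1) / control (0) labels with sample identifiers."""

    values: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise ValueError("phenotype must be a 1-D vector")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("phenotype values must be 0 (control) or 1 (case)")
        if self.values.sum() == 0 or self.values.sum() == self.values.size:
            raise ValueError("phenotype needs at least one case and one control")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i}" for i in range(self.values.size)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != self.values.shape:
                raise ValueError("sample_ids length must match phenotype length")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_cases(self) -> int:
        return int(self.values.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n - self.values.sum())


@dataclass
class KinshipMatrix:
    """Genetic relatedness matrix A, jittered to guarantee invertibility.

    The random effects of the probit mixed model follow u ~ MVN(0, sigma_u^2 A);
    a small diagonal augmentation (relative to the mean diagonal) makes the
    empirical GRM safely positive definite before inversion / Cholesky.
    """

    values: np.ndarray
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        n1, n2 = self.values.shape
        if n1 != n2:
            raise ValueError("kinship matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > 1e-8:
            raise ValueError("kinship matrix must be symmetric (within 1e-8)")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("kinship diagonal entries must be positive")
        self.values = 0.5 * (self.values + self.values.T)
        self._jittered = self.values + (
            self.jitter * float(np.mean(np.diag(self.values)))
        ) * np.eye(n1)
        try:
            self._chol = np.linalg.cholesky(self._jittered)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
            raise ValueError("kinship matrix not positive definite after jitter") from exc
        self._inv: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def jittered(self) -> np.ndarray:
        return self._jittered

    @property
    def cholesky(self) -> np.ndarray:
        return self._chol

    @property
    def inverse(self) -> np.ndarray:
        if self._inv is None:
            ident = np.eye(self.n)
            ci = np.linalg.solve(self._chol, ident)
            self._inv = ci.T @ ci
        return self._inv


@dataclass
class PriorSpec:
    """Prior hyperparameters of the misclassification model.

    alpha (true-positive probability) gets an informative Beta(10, 1) prior --
    most true cases are recorded as cases -- which, together with the flat
    Beta(1, 1) on lambda (false-positive probability), enforces the
    identifiability orientation alpha > lambda in the dominant posterior mode.
    SNP effects beta get independent N(0, 1) priors; the random-effect
    variance sigma_u^2 gets a flat prior truncated at ``sigma_u2_max``.
    """

    alpha_prior: tuple[float, float] = (10.0, 1.0)
    lambda_prior: tuple[float, float] = (1.0, 1.0)
    beta_prior: tuple[float, float] = (0.0, 1.0)  # mean, sd
    sigma_u2_max: float = 100.0

    def __post_init__(self) -> None:
        for name in ("alpha_prior", "lambda_prior"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} shapes must be positive")
        if self.beta_prior[1] <= 0:
            raise ValueError("beta prior sd must be positive")
        if self.sigma_u2_max <= 0:
            raise ValueError("sigma_u2_max must be positive")


@dataclass
class ModelParams:
    """One MCMC state of the misclassification model."""

    alpha: float
    lambda_: float
    beta: np.ndarray
    u: np.ndarray
    sigma_u2: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if not (0.0 < self.lambda_ < 1.0):
            raise ValueError("lambda_ must lie strictly in (0, 1)")
        if self.sigma_u2 <= 0:
            raise ValueError("sigma_u2 must be positive")

    def copy(self) -> "ModelParams":
        return ModelParams(
            alpha=self.alpha,
            lambda_=self.lambda_,
            beta=self.beta.copy(),
            u=self.u.copy(),
            sigma_u2=self.sigma_u2,
        )

    @property
    def identifiable(self) -> bool:
        """True when the state sits in the non-switched mode (alpha > lambda)."""
        return self.alpha > self.lambda_
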