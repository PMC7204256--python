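"""Minimal PLINK binary trio (.bed/.bim/.fam) reader and writer.

Supports the SNP-major .bed layout (magic bytes 0x6c 0x1b, mode 0x01) with
the standard 2-bit encoding: 00 = two copies of allele 1, 10 = heterozygote,
11 = zero copies, 01 = missing (rejected here, the pipeline requires complete
genotypes).  Genotype values are counts of allele 1 (the A1/minor allele by
PLINK convention).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PhenotypeVector

__all__ = [
    "read_plink",
    "write_plink",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> allele-1 count (code 1 is missing)
_CODE_TO_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0, 1: 2, 0: 3}


def read_plink(prefix: str | Path):
    """Read a .bed/.bim/.fam trio; returns ``(GenotypeMatrix, fam DataFrame)``."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: bad magic bytes "
                         "(not a SNP-major PLINK .bed file)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ValueError(f"{prefix.with_suffix('.bed')}: size inconsistent "
                         f"with {n} samples x {m} SNPs")
    blocks = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T.astype(float)
    if (counts < 0).any():
        raise ValueError("missing genotypes present; impute or filter first")
    X = GenotypeMatrix.from_counts(
        counts,
        snp_ids=bim["snp_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
    )
    return X, fam


def write_plink(prefix: str | Path, X: GenotypeMatrix,
                sample_ids=None, phenotype=None) -> None:
    """Write a GenotypeMatrix as a .bed/.bim/.fam trio."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = X.n_samples, X.n_snps
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    pheno = (np.asarray(getattr(phenotype, "values", phenotype)) + 1
             if phenotype is not None else np.full(n, -9, dtype=int))

    pd.DataFrame({
        "chrom": X.chrom, "snp_id": X.snp_ids, "cm": 0, "pos": X.pos,
        "a1": "A", "a2": "B",
    }).to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    pd.DataFrame({
        "fid": sample_ids, "iid": sample_ids, "father": 0, "mother": 0,
        "sex": 0, "phenotype": pheno,
    }).to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 3  # pad positions encode "0 copies"
    count_to_code = np.array([_COUNT_TO_CODE[c] for c in (0, 1, 2)], dtype=np.uint8)
    codes[:, :n] = count_to_code[X.values.T.astype(np.int64)]
    blocks = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        blocks |= codes[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        blocks.tofile(fh)


def read_phenotype_tsv(path: str | Path) -> PhenotypeVector:
    """Read a two-column (sample_id, phenotype) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return PhenotypeVector(values=df.iloc[:, 1].to_numpy(),
                           sample_ids=df.iloc[:, 0].to_numpy())


def write_phenotype_tsv(path: str | Path, Y: PhenotypeVector) -> None:
    pd.DataFrame({"sample_id": Y.sample_ids, "phenotype": Y.values}).to_csv(
        path, sep="\t", index=False)
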