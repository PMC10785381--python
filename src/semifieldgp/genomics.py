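"""SNP quality control and the VanRaden (method 1) genomic relationship matrix.

Dosages are coded 0/1/2 copies of the counted allele with NaN for missing.
QC removes SNPs and then lines with more than ``max_missing`` missing data
and SNPs with minor allele frequency below ``min_maf``; residual missingness
is mean-imputed.  The relationship matrix is

    G = M M' / (2 * sum_j p_j (1 - p_j))

with M the dosage matrix centred by twice the per-SNP allele frequency.
The average diagonal d(G) rises towards 2 for fully inbred material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError

__all__ = ["GenotypeMatrix", "Grm", "filter_snps", "impute_missing", "compute_grm", "read_genotypes"]


class GenotypeMatrix:
    """Line x SNP dosage table with QC metadata.

    Wraps a pandas DataFrame (index = line ids, columns = SNP ids, float
    entries in {0, 1, 2} or NaN).
    """

    def __init__(self, dosages: pd.DataFrame):
        values = dosages.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)) | (
            (values >= 0.0) & (values <= 2.0)
        )
        if not ok.all():
            raise ValidationError("dosages must lie in [0, 2] or be missing")
        self.dosages = dosages.astype(float)

    @property
    def line_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def allele_freq(self) -> pd.Series:
        """Counted-allele frequency p_j = mean dosage / 2 (missing ignored)."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    @property
    def maf(self) -> pd.Series:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def snp_missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    @property
    def line_missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)

    def to_csv(self, path, missing_code: str = "NA") -> None:
        self.dosages.to_csv(path, na_rep=missing_code)


def read_genotypes(
    path,
    missing_codes: tuple[str, ...] = ("NA", "-9", ""),
    transposed: bool = False,
    sep: str = ",",
) -> GenotypeMatrix:
    """Read a delimited line x SNP dosage table (first column = line id)."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(missing_codes))
    if transposed:
        df = df.T
    return GenotypeMatrix(df)


def filter_snps(
    geno: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.03,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the QC chain: SNP missingness, line missingness, then MAF.

    SNPs/lines with missing rate strictly above ``max_missing`` are dropped,
    then SNPs with MAF strictly below ``min_maf`` on the retained lines.
    Returns the filtered matrix plus a removal report.
    """
    df = geno.dosages
    snp_keep = df.isna().mean(axis=0) <= max_missing
    df1 = df.loc[:, snp_keep]
    line_keep = df1.isna().mean(axis=1) <= max_missing
    df2 = df1.loc[line_keep]
    p = df2.mean(axis=0, skipna=True) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf_keep = maf >= min_maf
    df3 = df2.loc[:, maf_keep]
    report = {
        "snps_removed_missing": int((~snp_keep).sum()),
        "lines_removed_missing": int((~line_keep).sum()),
        "snps_removed_maf": int((~maf_keep).sum()),
        "snps_retained": df3.shape[1],
        "lines_retained": df3.shape[0],
    }
    if df3.shape[1] == 0:
        raise DegenerateInputError("all SNPs removed by QC filters")
    return GenotypeMatrix(df3), report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean 2*p_j."""
    df = geno.dosages
    means = df.mean(axis=0, skipna=True)
    return GenotypeMatrix(df.fillna(means))


@dataclass
class Grm:
    """Genomic relationship matrix over lines."""

    matrix: pd.DataFrame
    denominator: float

    @property
    def avg_diag(self) -> float:
        """d(G): average of the diagonal elements."""
        return float(np.mean(np.diag(self.matrix.to_numpy())))

    @property
    def line_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def compute_grm(geno: GenotypeMatrix) -> Grm:
    """VanRaden method-1 relationship matrix from a complete dosage matrix."""
    df = geno.dosages
    if df.isna().to_numpy().any():
        raise ValidationError("dosage matrix has missing entries; impute first")
    W = df.to_numpy(dtype=float)
    p = W.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise DegenerateInputError("all SNPs monomorphic: zero VanRaden denominator")
    M = W - 2.0 * p
    G = (M @ M.T) / denom
    G = (G + G.T) / 2.0
    return Grm(pd.DataFrame(G, index=df.index, columns=df.index), denom)
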