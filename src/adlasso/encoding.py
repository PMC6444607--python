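"""Genotype/phenotype I/O, MAF filtering, one-hot encoding and splits.

Genotypes are biallelic SNP counts coded 0/1/2 (individuals x SNPs,
delimited text with a header of SNP ids and a leading individual-id
column).  Each retained SNP is expanded into three indicator columns,
one per genotype class, in the fixed order (0, 1, 2) so that downstream
effect extraction (``a = -theta_gen0 + theta_gen2``, ``d = theta_gen1``)
is unambiguous.  Indicator columns are deliberately left uncentered and
unscaled; phenotype centering absorbs the intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "DesignMatrix",
    "PhenotypeVector",
    "SplitPlan",
    "SnpColumn",
    "CovariateColumn",
    "CovariateTable",
    "read_genotypes",
    "read_phenotypes",
    "read_covariates",
    "maf_filter",
    "one_hot_encode",
    "center_phenotype",
    "make_splits",
]


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class SnpColumn:
    """Provenance of a design column holding one genotype-class indicator."""

    snp_id: str
    genotype_class: int  # 0, 1 or 2


@dataclass(frozen=True)
class CovariateColumn:
    """Provenance of a covariate design column."""

    name: str
    kind: Literal["indicator", "standardized_continuous"]


Column = Union[SnpColumn, CovariateColumn]


@dataclass
class GenotypeMatrix:
    """Raw 0/1/2 genotype counts with row/column identifiers.

    Attributes
    ----------
    values : ndarray of shape (n_individuals, n_snps), integer
        Genotype counts; every entry must be 0, 1 or 2.  Missing values
        are not representable (imputation is out of scope).
    snp_ids : list of str
        Unique column identifiers.
    individual_ids : list of str
        Unique row identifiers.
    """

    values: np.ndarray
    snp_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.snp_ids) != p:
            raise ValidationError(
                f"{len(self.snp_ids)} SNP ids for {p} genotype columns"
            )
        if len(self.individual_ids) != n:
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(set(self.snp_ids)) != p:
            raise ValidationError("duplicate SNP ids")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if not np.issubdtype(self.values.dtype, np.integer):
            flo = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(flo)) or np.any(flo != np.round(flo)):
                bad = _first_bad(~np.isfinite(flo) | (flo != np.round(flo)))
                raise ValidationError(
                    f"non-integer genotype at row {bad[0]}, column {bad[1]}"
                )
            self.values = flo.astype(np.int8)
        bad_mask = (self.values < 0) | (self.values > 2)
        if bad_mask.any():
            r, c = _first_bad(bad_mask)
            raise ValidationError(
                f"genotype {self.values[r, c]} not in {{0,1,2}} at row "
                f"{self.individual_ids[r]!r}, column {self.snp_ids[c]!r}"
            )
        self.values = self.values.astype(np.int8, copy=False)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, sum(g) / (2n)."""
        return self.values.sum(axis=0, dtype=np.float64) / (2.0 * self.n_individuals)

    def minor_allele_frequencies(self) -> np.ndarray:
        p_hat = self.allele_frequencies()
        return np.minimum(p_hat, 1.0 - p_hat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.snp_ids
        )


@dataclass
class CovariateTable:
    """Covariates with a declared kind per column (indicator or continuous)."""

    values: np.ndarray
    names: list[str]
    kinds: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValidationError("covariate shape/name mismatch")
        if len(self.kinds) != len(self.names):
            raise ValidationError("one kind per covariate required")
        for k in self.kinds:
            if k not in ("indicator", "continuous"):
                raise ValidationError(f"unknown covariate kind {k!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite covariate value")


@dataclass
class DesignMatrix:
    """Real-valued model matrix with per-column provenance.

    ``q = 3 * n_snps + n_covariates``; within every SNP's block the three
    indicators sum to exactly 1 in each row.
    """

    values: np.ndarray
    columns: list[Column]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValidationError("design width does not match provenance length")

    @property
    def n_snp_columns(self) -> int:
        return sum(1 for c in self.columns if isinstance(c, SnpColumn))

    @property
    def snp_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.columns:
            if isinstance(c, SnpColumn) and c.genotype_class == 0:
                seen.append(c.snp_id)
        return seen


@dataclass
class PhenotypeVector:
    """Phenotype values plus the training mean retained for prediction."""

    values: np.ndarray
    training_mean: float = 0.0
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite phenotype value")


@dataclass
class SplitPlan:
    """Train/test row partitions; each repeat is disjoint and exhaustive."""

    repeats: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        for tr, te in self.repeats:
            union = np.concatenate([tr, te])
            if len(np.intersect1d(tr, te)) != 0:
                raise ValidationError("train/test overlap in split")
            n = len(union)
            if not np.array_equal(np.sort(union), np.arange(n)):
                raise ValidationError("split does not cover all rows exactly once")


def _first_bad(mask: np.ndarray) -> tuple[int, int]:
    r, c = np.argwhere(mask)[0]
    return int(r), int(c)


def read_genotypes(path, delimiter: str = "\t") -> GenotypeMatrix:
    """Read a delimited genotype table (header = SNP ids, first column = id)."""
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(raw_header)) != len(raw_header):  # pandas would mangle duplicates
        raise ValidationError("duplicate SNP ids in genotype header")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    gm = GenotypeMatrix(
        values=df.to_numpy(),
        snp_ids=[str(c) for c in df.columns],
        individual_ids=[str(i) for i in df.index],
    )
    logger.info("read %d individuals x %d SNPs from %s", gm.n_individuals, gm.n_snps, path)
    return gm


def read_phenotypes(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (individual id, value) phenotype table."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] != 1:
        raise ValidationError("phenotype file must have exactly two columns")
    return df.iloc[:, 0].astype(float)


def read_covariates(path, delimiter: str = "\t") -> CovariateTable:
    """Read covariates; the first body row declares each column's kind."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    kinds = [str(k) for k in df.iloc[0]]
    body = df.iloc[1:].astype(float)
    return CovariateTable(values=body.to_numpy(), names=[str(c) for c in df.columns], kinds=kinds)


def maf_filter(
    G: GenotypeMatrix, threshold: float = 0.01
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop SNPs with minor allele frequency below ``threshold``.

    The rule is inclusive: a SNP is retained when MAF >= threshold, with
    MAF = min(p_hat, 1 - p_hat) and p_hat = sum(g) / (2n).  Monomorphic
    columns (MAF = 0) are always removed.  Returns the filtered matrix
    and the removed SNP ids in original column order.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    maf = G.minor_allele_frequencies()
    keep = (maf >= threshold) & (maf > 0.0)
    removed = [sid for sid, k in zip(G.snp_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("MAF filter removed every SNP (empty design)")
    logger.info("MAF filter at %.4g removed %d of %d SNPs", threshold, len(removed), G.n_snps)
    filtered = GenotypeMatrix(
        values=G.values[:, keep],
        snp_ids=[sid for sid, k in zip(G.snp_ids, keep) if k],
        individual_ids=list(G.individual_ids),
    )
    return filtered, removed


def one_hot_encode(
    G: GenotypeMatrix, covariates: Optional[CovariateTable] = None
) -> DesignMatrix:
    """Expand each SNP into three genotype-class indicator columns.

    Per SNP the block order is fixed at classes (0, 1, 2).  Covariate
    columns are appended after the SNP blocks; continuous covariates are
    standardized to mean 0 and sd 1, indicator covariates pass through.
    """
    n, p = G.values.shape
    X = np.zeros((n, 3 * p), dtype=np.float64)
    for cls in range(3):
        X[:, cls::3] = G.values == cls
    columns: list[Column] = [
        SnpColumn(snp_id=sid, genotype_class=cls)
        for sid in G.snp_ids
        for cls in range(3)
    ]
    if covariates is not None:
        cov = covariates.values.copy()
        for j, kind in enumerate(covariates.kinds):
            if kind == "continuous":
                sd = cov[:, j].std(ddof=0)
                if sd == 0.0:
                    raise ValidationError(
                        f"continuous covariate {covariates.names[j]!r} is constant"
                    )
                cov[:, j] = (cov[:, j] - cov[:, j].mean()) / sd
                columns.append(
                    CovariateColumn(covariates.names[j], "standardized_continuous")
                )
            else:
                columns.append(CovariateColumn(covariates.names[j], "indicator"))
        X = np.hstack([X, cov])
    return DesignMatrix(values=X, columns=columns)


def center_phenotype(y: Union[np.ndarray, Sequence[float], pd.Series]) -> PhenotypeVector:
    """Subtract the mean; the mean is retained for prediction."""
    arr = np.asarray(y, dtype=np.float64).ravel()
    if arr.size < 2:
        raise ValidationError("need at least 2 phenotype values to center")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite phenotype value")
    mean = float(arr.mean())
    return PhenotypeVector(values=arr - mean, training_mean=mean, centered=True)


def make_splits(
    n: int,
    mode: Literal["holdout_tail", "random_repeats"],
    test_fraction: float = 0.3,
    repeats: int = 1,
    seed: int = 0,
) -> SplitPlan:
    """Build train/test partitions of ``range(n)``.

    ``holdout_tail`` puts the last ``ceil(n * test_fraction)`` rows in the
    test set (generation-style split); ``random_repeats`` draws ``repeats``
    independent random partitions from ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    # round() guards ceil against float dust when n * test_fraction is integral
    n_test = math.ceil(round(n * test_fraction, 9))
    if n_test == 0 or n_test == n:
        raise ValidationError("split leaves train or test side empty")
    if mode == "holdout_tail":
        idx = np.arange(n)
        pairs = [(idx[: n - n_test], idx[n - n_test:])]
    elif mode == "random_repeats":
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(repeats):
            perm = rng.permutation(n)
            pairs.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return SplitPlan(repeats=pairs, seed=seed)
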