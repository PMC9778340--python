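"""Readers, writers and the in-memory container for case-control genotype data.

Genotypes are coded additively: 0 = common homozygote, 1 = heterozygote,
2 = rare homozygote.  The phenotype is binary (1 = case, 0 = control).
Internally samples are rows and SNPs are columns; all downstream stages work
with 0-based column indices and only translate back to SNP identifiers at
I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "GenotypeFormatError",
    "GenotypeCodingError",
    "MissingGenotypeError",
    "read_gametes_tsv",
    "write_gametes_tsv",
    "read_plink_raw",
]

#: leading metadata columns of a PLINK .raw file, in required order
_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class GenotypeFormatError(ValueError):
    """The file (or array) does not follow the declared layout."""


class GenotypeCodingError(GenotypeFormatError):
    """A genotype value outside {0, 1, 2} was encountered."""


class MissingGenotypeError(GenotypeFormatError):
    """A missing genotype token was encountered (imputation is out of scope)."""


@dataclass
class GenotypeDataset:
    """A samples x SNPs genotype matrix with a binary phenotype.

    Parameters
    ----------
    genotypes : ndarray of shape (n_samples, n_snps)
        Integer codes in {0, 1, 2}.
    phenotype : ndarray of shape (n_samples,)
        1 for cases, 0 for controls.
    snp_ids : list of str
        Unique identifiers, one per column.
    sample_ids : list of str, optional
        Row identifiers; purely informational.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        y = np.asarray(self.phenotype)
        if g.ndim != 2:
            raise GenotypeFormatError("genotypes must be a 2-D matrix")
        if not np.issubdtype(g.dtype, np.integer):
            if np.issubdtype(g.dtype, np.floating) and np.isnan(g).any():
                raise MissingGenotypeError("genotype matrix contains missing values")
            if not np.all(np.asarray(g, dtype=float) == np.floor(np.asarray(g, dtype=float))):
                raise GenotypeCodingError("genotype values must be integers")
            g = g.astype(np.int64)
        bad = (g < 0) | (g > 2)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            name = self.snp_ids[int(c)] if int(c) < len(self.snp_ids) else "?"
            raise GenotypeCodingError(
                f"genotype value {int(g[r, c])} outside {{0,1,2}} at sample row "
                f"{int(r)}, SNP column {int(c)} ({name!r})"
            )
        self.genotypes = g.astype(np.int8)
        if y.ndim != 1 or y.shape[0] != g.shape[0]:
            raise GenotypeFormatError("phenotype length must equal the number of sample rows")
        if not np.isin(y, (0, 1)).all():
            raise GenotypeFormatError("phenotype values must be binary 0/1")
        self.phenotype = np.asarray(y, dtype=np.int8)
        if len(self.snp_ids) != g.shape[1]:
            raise GenotypeFormatError("snp_ids length must equal the number of SNP columns")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise GenotypeFormatError("snp_ids must be unique")
        if self.sample_ids is not None and len(self.sample_ids) != g.shape[0]:
            raise GenotypeFormatError("sample_ids length must equal the number of samples")
        if self.n_cases == 0 or self.n_controls == 0:
            # A single-class phenotype makes every mutual information zero; the
            # pipeline handles it as a "no interactions selected" outcome.
            warnings.warn(
                "phenotype contains a single class; all interaction scores will be 0",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_snps(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_cases(self) -> int:
        return int(np.count_nonzero(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.count_nonzero(self.phenotype == 0))

    def subset(self, snp_indices) -> "GenotypeDataset":
        """Restrict to the given SNP columns (original identifiers retained)."""
        idx = np.asarray(snp_indices, dtype=np.intp)
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx].copy(),
            phenotype=self.phenotype.copy(),
            snp_ids=[self.snp_ids[int(i)] for i in idx],
            sample_ids=None if self.sample_ids is None else list(self.sample_ids),
        )


def read_gametes_tsv(path) -> GenotypeDataset:
    """Read a GAMETES-style tab-delimited genotype file.

    The header row holds SNP names followed by a final ``Class`` column;
    body rows are integers.  Parsing never drops rows or columns.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[-1] != "Class":
        raise GenotypeFormatError(
            f"{path}: final column must be named 'Class' (got {frame.columns[-1]!r})"
        )
    snp_ids = [str(c) for c in frame.columns[:-1]]
    body = frame.iloc[:, :-1]
    if body.isna().any().any():
        raise MissingGenotypeError(f"{path}: missing genotype value in body")
    try:
        g = body.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise GenotypeCodingError(f"{path}: non-integer genotype value ({exc})") from exc
    cls = frame.iloc[:, -1]
    try:
        y = cls.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise GenotypeFormatError(f"{path}: non-integer Class value ({exc})") from exc
    if not np.isin(y, (0, 1)).all():
        bad = y[~np.isin(y, (0, 1))][0]
        raise GenotypeFormatError(f"{path}: non-binary Class value {int(bad)}")
    bad = (g < 0) | (g > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GenotypeCodingError(
            f"{path}: genotype value {int(g[r, c])} outside {{0,1,2}} at body row "
            f"{int(r) + 1}, column {snp_ids[int(c)]!r}"
        )
    return GenotypeDataset(genotypes=g, phenotype=y, snp_ids=snp_ids)


def write_gametes_tsv(dataset: GenotypeDataset, path) -> None:
    """Write a dataset as GAMETES-style TSV (SNP columns + ``Class``)."""
    frame = pd.DataFrame(dataset.genotypes, columns=dataset.snp_ids)
    frame["Class"] = dataset.phenotype
    frame.to_csv(path, sep="\t", index=False)


def read_plink_raw(path) -> GenotypeDataset:
    """Read a PLINK ``.raw`` additive-coding export.

    PHENOTYPE coded 1/2 is remapped to 0/1; 0/1 coding is taken as-is.
    Missing genotypes (``NA``) are rejected: imputation is out of scope.
    """
    frame = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = list(frame.columns)
    if tuple(cols[: len(_PLINK_META)]) != _PLINK_META:
        raise GenotypeFormatError(
            f"{path}: expected leading columns {_PLINK_META}, got {tuple(cols[:6])}"
        )
    snp_ids = cols[len(_PLINK_META):]
    if not snp_ids:
        raise GenotypeFormatError(f"{path}: no SNP columns present")
    body = frame[snp_ids]
    if body.isna().any().any():
        col = body.columns[body.isna().any()][0]
        row = int(body.index[body[col].isna()][0])
        raise MissingGenotypeError(
            f"{path}: missing genotype (NA) at sample row {row + 1}, SNP {col!r}"
        )
    try:
        g = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise GenotypeCodingError(f"{path}: non-numeric genotype value ({exc})") from exc
    pheno_raw = frame["PHENOTYPE"]
    if pheno_raw.isna().any():
        raise GenotypeFormatError(f"{path}: missing PHENOTYPE value")
    y = pheno_raw.to_numpy(dtype=float)
    if not np.all(y == np.floor(y)):
        raise GenotypeFormatError(f"{path}: PHENOTYPE must be integer coded")
    y = y.astype(np.int64)
    values = set(np.unique(y).tolist())
    if 2 in values and values <= {1, 2}:
        y = y - 1  # PLINK case/control coding: 1=control, 2=case
    elif not values <= {0, 1}:
        raise GenotypeFormatError(
            f"{path}: PHENOTYPE must be coded 1/2 or 0/1 (saw values {sorted(values)})"
        )
    sample_ids = [str(s) for s in frame["IID"]]
    return GenotypeDataset(genotypes=g, phenotype=y, snp_ids=snp_ids, sample_ids=sample_ids)
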