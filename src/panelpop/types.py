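"""Shared domain types for the panel-analysis pipeline.

Coordinates are 1-based with inclusive interval ends everywhere (VCF/GFF
convention); no half-open conversion happens internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid dosage in :class:`GenotypeMatrix`.
MISSING = -1

#: Canonical chromosome names, natural order: A01..A10 then C01..C09.
CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 11)) + tuple(
    f"C{i:02d}" for i in range(1, 10)
)

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing A01..A10 before C01..C09; unknown names last."""
    return (_CHROM_RANK.get(chrom, len(CHROMOSOMES)), chrom)


def subgenome_of(chrom: str) -> str:
    """Subgenome is 'A' iff the chromosome name starts with 'A', else 'C'."""
    return "A" if str(chrom).startswith("A") else "C"


@dataclass
class RawVariantRecord:
    """One VCF site with per-sample GT/AD/DP (and optional mismatch counts).

    Attributes
    ----------
    chrom, pos, ref, alts
        Site description; ``pos`` is 1-based.
    gt
        ``(n_samples, 2)`` int array of allele indices, ``-1`` for missing.
    ad
        ``(n_samples, 1 + len(alts))`` int array of per-allele read depths,
        ``-1`` where absent.
    dp
        ``(n_samples,)`` int array of total depths, ``-1`` where absent.
    mismatches
        Optional ``(n_samples,)`` int array of per-sample alignment mismatch
        counts at this locus (``-1`` = unknown). Carried as an annotation;
        consumed by the mismatch-locus filter.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    gt: np.ndarray
    ad: np.ndarray
    dp: np.ndarray
    mismatches: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.gt = np.asarray(self.gt, dtype=np.int32)
        self.ad = np.asarray(self.ad, dtype=np.int32)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        if self.mismatches is not None:
            self.mismatches = np.asarray(self.mismatches, dtype=np.int32)
        n_alleles = 1 + len(self.alts)
        if self.gt.max(initial=-1) >= n_alleles:
            raise ValueError(
                f"{self.chrom}:{self.pos}: genotype allele index out of range"
            )

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def is_snp(self) -> bool:
        """True for a biallelic single-nucleotide substitution."""
        return len(self.alts) == 1 and len(self.ref) == 1 and len(self.alts[0]) == 1

    def called_mask(self) -> np.ndarray:
        return (self.gt >= 0).all(axis=1)

    def copy(self) -> "RawVariantRecord":
        return RawVariantRecord(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alts=list(self.alts),
            gt=self.gt.copy(),
            ad=self.ad.copy(),
            dp=self.dp.copy(),
            mismatches=None if self.mismatches is None else self.mismatches.copy(),
        )

    def equals(self, other: "RawVariantRecord") -> bool:
        mm_eq = (self.mismatches is None) == (other.mismatches is None)
        if mm_eq and self.mismatches is not None:
            mm_eq = bool(np.array_equal(self.mismatches, other.mismatches))
        return (
            self.chrom == other.chrom
            and self.pos == other.pos
            and self.ref == other.ref
            and self.alts == other.alts
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.ad, other.ad)
            and np.array_equal(self.dp, other.dp)
            and mm_eq
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval; ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    is_focal: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class GenotypeMatrix:
    """Samples x SNPs dosage matrix with metadata.

    Dosages count alternate-allele copies: 0, 1, 2 or :data:`MISSING`.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array.
    samples
        DataFrame indexed by sample id with columns ``growth_habit``,
        ``geography``, ``subpop`` (missing columns are filled with
        ``"unassigned"``).
    snps
        DataFrame indexed by SNP id with columns ``chrom``, ``pos`` and
        optionally ``genic``; ``subgenome`` is derived from ``chrom``.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        samples: pd.DataFrame,
        snps: pd.DataFrame,
        validate: bool = True,
    ):
        self.dosages = np.asarray(dosages, dtype=np.int8)
        self.samples = samples.copy()
        self.snps = snps.copy()
        for col in ("growth_habit", "geography", "subpop"):
            if col not in self.samples.columns:
                self.samples[col] = "unassigned"
        self.snps["subgenome"] = [subgenome_of(c) for c in self.snps["chrom"]]
        if "genic" not in self.snps.columns:
            self.snps["genic"] = False
        if validate:
            self._validate()

    def _validate(self) -> None:
        n, s = self.dosages.shape
        if n != len(self.samples) or s != len(self.snps):
            raise ValueError("dosage shape does not match metadata")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages outside {0,1,2,missing}")
        if s and (self.dosages != MISSING).sum(axis=0).min() < 1:
            raise ValueError("every SNP needs >= 1 non-missing call")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing dosages."""
        return self.dosages != MISSING

    # -- subsetting -------------------------------------------------------
    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx], self.samples.iloc[idx], self.snps, validate=False
        )

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.samples, self.snps.iloc[idx], validate=False
        )

    def subpop_indices(self, subpop: str) -> np.ndarray:
        return np.flatnonzero((self.samples["subpop"] == subpop).to_numpy())

    def subgenome_snp_indices(self, subgenome: str) -> np.ndarray:
        return np.flatnonzero((self.snps["subgenome"] == subgenome).to_numpy())

    # -- allele counting --------------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP ``(alt_copies, called_chromosomes)`` over a sample subset."""
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        chroms = 2 * called.sum(axis=0)
        return np.stack([alt, chroms], axis=1)

    # -- serialization ----------------------------------------------------
    def to_tsv(self, matrix_path, samples_path=None) -> None:
        """Write the dosage matrix (SNP rows) and optional sample metadata."""
        dos = self.dosages.astype(object).T
        dos[dos == MISSING] = "NA"
        df = pd.concat(
            [
                self.snps[["chrom", "pos", "subgenome", "genic"]],
                pd.DataFrame(dos, index=self.snps.index, columns=self.sample_ids),
            ],
            axis=1,
        )
        df.index.name = "snp_id"
        df.to_csv(matrix_path, sep="\t")
        if samples_path is not None:
            out = self.samples.copy()
            out.index.name = "sample_id"
            out.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path=None) -> "GenotypeMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col="snp_id")
        meta_cols = ["chrom", "pos", "subgenome", "genic"]
        sample_cols = [c for c in df.columns if c not in meta_cols]
        dos = df[sample_cols].to_numpy(dtype=float)
        dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8).T
        snps = df[["chrom", "pos", "genic"]].copy()
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
            samples = samples.loc[sample_cols]
        else:
            samples = pd.DataFrame(index=pd.Index(sample_cols, name="sample_id"))
        return cls(dos, samples, snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), self.samples, self.snps, validate=False
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.samples.equals(other.samples)
            and self.snps.equals(other.snps)
        )


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, growth_habit, geography[, subpop])."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return df
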