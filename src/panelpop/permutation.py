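"""Matched-composition permutation test for gene-set statistics.

Each focal gene is represented by exactly ``r`` SNPs (all within-gene SNPs
by position, then nearest flanking SNPs, nearest first with leftward tie
break). The null redraws SNP sets of identical subgenome x genic
composition from the genome and compares the mean per-SNP statistic
(Fst or Pi). The p-value is the plain exceedance count over iterations
(no add-one correction); p = 0 is reported with a "< 1/iterations" note.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fst import per_snp_fst_track
from .sfs import big_pi_per_snp
from .types import GeneAnnotation, GenotypeMatrix, chrom_sort_key


@dataclass
class GeneSnpSet:
    """gene id -> representative SNP indices (each of length r when possible)."""

    r: int
    snps_by_gene: dict[str, np.ndarray]
    incomplete_genes: list[str] = field(default_factory=list)

    @property
    def all_indices(self) -> np.ndarray:
        """Concatenated representative SNPs (duplicates across genes kept)."""
        if not self.snps_by_gene:
            return np.empty(0, dtype=int)
        return np.concatenate(list(self.snps_by_gene.values()))

    def composition_tally(self, matrix: GenotypeMatrix) -> dict[tuple[str, bool], int]:
        """Counts per (subgenome, genic) stratum over the multiset of SNPs."""
        idx = self.all_indices
        sub = matrix.snps["subgenome"].to_numpy()[idx]
        gen = matrix.snps["genic"].to_numpy()[idx].astype(bool)
        tally: dict[tuple[str, bool], int] = {}
        for s, g in zip(sub, gen):
            tally[(s, bool(g))] = tally.get((s, bool(g)), 0) + 1
        return tally


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    iterations: int
    direction: str
    null_values: np.ndarray
    note: str = ""


def representative_snps(
    matrix: GenotypeMatrix, genes: Iterable[GeneAnnotation], r: int = 40
) -> GeneSnpSet:
    """Pick ``r`` representative SNPs per gene.

    All within-gene SNPs come first (by position, truncated at r); the rest
    are the nearest flanking SNPs on the gene's chromosome by distance to
    the gene boundary, nearest first, equidistant ties broken leftward.
    Genes on chromosomes with fewer than r SNPs take what exists and are
    flagged incomplete.
    """
    chroms = matrix.snps["chrom"].to_numpy()
    pos = matrix.snps["pos"].to_numpy()
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        by_chrom[c] = idx[np.argsort(pos[idx], kind="stable")]

    out: dict[str, np.ndarray] = {}
    incomplete: list[str] = []
    for gene in genes:
        chrom_idx = by_chrom.get(gene.chrom, np.empty(0, dtype=int))
        p = pos[chrom_idx]
        inside = chrom_idx[(p >= gene.start) & (p <= gene.end)]
        chosen = list(inside[:r])
        if len(chosen) < r:
            left = chrom_idx[p < gene.start][::-1]  # nearest first
            right = chrom_idx[p > gene.end]
            li = ri = 0
            while len(chosen) < r and (li < left.size or ri < right.size):
                ld = gene.start - pos[left[li]] if li < left.size else np.inf
                rd = pos[right[ri]] - gene.end if ri < right.size else np.inf
                if ld <= rd:  # tie -> leftward
                    chosen.append(left[li])
                    li += 1
                else:
                    chosen.append(right[ri])
                    ri += 1
        if len(chosen) < r:
            incomplete.append(gene.gene_id)
        out[gene.gene_id] = np.array(chosen, dtype=int)
    return GeneSnpSet(r=r, snps_by_gene=out, incomplete_genes=incomplete)


def matched_null_draw(
    matrix: GenotypeMatrix,
    tally: dict[tuple[str, bool], int],
    rng: np.random.Generator,
    pool_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sample SNP indices without replacement, per (subgenome, genic)
    stratum, with counts equal to the tally."""
    sub = matrix.snps["subgenome"].to_numpy()
    gen = matrix.snps["genic"].to_numpy().astype(bool)
    picks = []
    for (s, g), count in tally.items():
        if count == 0:
            continue
        pool = (sub == s) & (gen == g)
        if pool_mask is not None:
            pool &= pool_mask
        pool_idx = np.flatnonzero(pool)
        if pool_idx.size < count:
            raise ValueError(
                f"stratum (subgenome={s}, genic={g}) has {pool_idx.size} SNPs; "
                f"{count} required"
            )
        picks.append(rng.choice(pool_idx, size=count, replace=False))
    if not picks:
        return np.empty(0, dtype=int)
    return np.concatenate(picks)


def fst_statistic(matrix: GenotypeMatrix, pair: tuple[str, str]) -> np.ndarray:
    """Per-SNP Hudson Fst values (NaN where undefined)."""
    return per_snp_fst_track(matrix, pair)["fst"].to_numpy()


def big_pi_statistic(matrix: GenotypeMatrix, subpop: str) -> np.ndarray:
    """Per-SNP average pairwise mismatch within one subpopulation."""
    return big_pi_per_snp(matrix, matrix.subpop_indices(subpop))


def permutation_test(
    matrix: GenotypeMatrix,
    gene_set: GeneSnpSet,
    stat_values: np.ndarray,
    iterations: int,
    seed: int = 0,
    direction: str = "greater",
) -> PermutationResult:
    """Compare the gene-set mean statistic against matched null draws.

    ``stat_values`` is a per-SNP statistic array (NaN = undefined; such
    SNPs are dropped symmetrically from the observed set and the null
    pools). One-sided p per ``direction``.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if iterations < 100:
        warnings.warn(
            f"{iterations} iterations gives p-value resolution of only "
            f"{1.0 / max(iterations, 1):g}",
            stacklevel=2,
        )
    stat_values = np.asarray(stat_values, dtype=float)
    valid = ~np.isnan(stat_values)
    idx = gene_set.all_indices
    idx = idx[valid[idx]]
    if idx.size == 0:
        raise ValueError("no gene-set SNP has a defined statistic")
    observed = float(stat_values[idx].mean())

    filtered = GeneSnpSet(
        r=gene_set.r,
        snps_by_gene={
            g: s[valid[s]] for g, s in gene_set.snps_by_gene.items()
        },
    )
    tally = filtered.composition_tally(matrix)

    rng = np.random.default_rng(seed)
    null = np.empty(iterations)
    for i in range(iterations):
        draw = matched_null_draw(matrix, tally, rng, pool_mask=valid)
        null[i] = stat_values[draw].mean()

    if direction == "greater":
        p = float((null >= observed).sum()) / iterations
    else:
        p = float((null <= observed).sum()) / iterations
    note = f"< {1.0 / iterations:g}" if p == 0.0 else ""
    return PermutationResult(
        observed=observed,
        p_value=p,
        iterations=iterations,
        direction=direction,
        null_values=null,
        note=note,
    )
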