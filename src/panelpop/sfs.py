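"""Folded site-frequency spectra by hypergeometric projection, and the
diversity statistics computed from them (pi, per-SNP Pi, Tajima's D).

Each SNP with at least ``m`` called chromosomes contributes its exact
expected folded minor-allele-count distribution after downsampling without
replacement to ``m`` chromosomes (default 100, i.e. 50 diploids); SNPs with
fewer called chromosomes are excluded and tallied. Fractional expected
masses are used directly (no multinomial resampling).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import MISSING, GenotypeMatrix


@dataclass
class FoldedSFS:
    """Expected folded spectrum projected to ``m`` chromosomes.

    ``mass[k]`` for k = 0..m//2 is the expected SNP count at minor-allele
    count k; k = 0 is the projected-monomorphic mass, excluded from
    segregating-site totals.
    """

    m: int
    mass: np.ndarray  # length m//2 + 1, index = minor allele count
    n_input_snps: int
    n_excluded: int

    @property
    def segregating_mass(self) -> float:
        return float(self.mass[1:].sum())

    @property
    def n_projected(self) -> int:
        return self.n_input_snps - self.n_excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mac": np.arange(len(self.mass)), "mass": self.mass})


@dataclass
class DiversityStats:
    pi: float | None = None
    big_pi_total: float | None = None
    L: float | None = None
    tajimas_d: float | None = None
    S: float | None = None
    n_projected_snps: int | None = None
    snp_density: float | None = None


def project_snp(minor_count: int, called_chromosomes: int, m: int = 100) -> np.ndarray:
    """Folded projection mass vector (length m//2 + 1) for one SNP.

    Entry k is the hypergeometric probability of drawing k copies of the
    allele in ``m`` draws without replacement from ``called_chromosomes``
    chromosomes carrying ``minor_count`` copies, folded by summing k with
    m - k (the fold boundary k = m/2 is counted once). Masses sum to 1.
    """
    j, m_obs = int(minor_count), int(called_chromosomes)
    if m_obs < m:
        raise ValueError(
            f"cannot project {m_obs} called chromosomes up to {m}; exclude this SNP"
        )
    ks = np.arange(m + 1)
    pmf = hypergeom.pmf(ks, m_obs, j, m)
    half = m // 2
    # fold by binning each k at min(k, m-k); the k = m/2 boundary lands once
    folded = np.zeros(half + 1)
    np.add.at(folded, np.minimum(ks, m - ks), pmf)
    return folded


def build_folded_sfs(
    matrix: GenotypeMatrix,
    subpop: str | None = None,
    subgenome: str | None = None,
    m: int = 100,
) -> FoldedSFS:
    """Sum per-SNP projected folded masses over a subpopulation/subgenome.

    Heterozygotes contribute one copy of each allele; missing genotypes are
    excluded from the called-chromosome count. The minor allele is defined
    within the projected subpopulation (the fold makes the choice at a
    50/50 site immaterial).
    """
    sample_idx = (
        matrix.subpop_indices(subpop) if subpop is not None else np.arange(
            matrix.n_samples
        )
    )
    if subpop is not None and sample_idx.size < m // 2:
        raise ValueError(
            f"subpopulation {subpop!r} has {sample_idx.size} samples; "
            f"projection to {m} chromosomes needs >= {m // 2}"
        )
    snp_idx = (
        matrix.subgenome_snp_indices(subgenome)
        if subgenome is not None
        else np.arange(matrix.n_snps)
    )
    counts = matrix.take_snps(snp_idx).allele_counts(sample_idx)
    half = m // 2
    mass = np.zeros(half + 1)
    n_excluded = 0
    cache: dict[tuple[int, int], np.ndarray] = {}
    for alt, chroms in counts:
        if chroms < m:
            n_excluded += 1
            continue
        j = int(min(alt, chroms - alt))
        key = (j, int(chroms))
        if key not in cache:
            cache[key] = project_snp(j, int(chroms), m)
        mass += cache[key]
    if len(counts) and n_excluded == len(counts):
        raise ValueError(
            f"all {len(counts)} SNPs have < {m} called chromosomes; "
            "lower the projection size"
        )
    return FoldedSFS(
        m=m, mass=mass, n_input_snps=len(counts), n_excluded=n_excluded
    )


def _pairwise_site_diversity(m: int) -> np.ndarray:
    """Expected pairwise-difference contribution per MAC k of m chromosomes."""
    ks = np.arange(m // 2 + 1)
    return 2.0 * ks * (m - ks) / (m * (m - 1.0))


def snp_density(
    matrix: GenotypeMatrix, subgenome: str | None = None, genome_bp: float | None = None
) -> float:
    """SNPs per bp, computed on all SNPs before projection/exclusion.

    ``genome_bp`` defaults to the span between the first and last SNP
    position summed over chromosomes (a desk-scale proxy for the covered
    reference length).
    """
    snp_idx = (
        matrix.subgenome_snp_indices(subgenome)
        if subgenome is not None
        else np.arange(matrix.n_snps)
    )
    snps = matrix.snps.iloc[snp_idx]
    if genome_bp is None:
        genome_bp = 0.0
        for _, grp in snps.groupby("chrom", observed=True):
            genome_bp += float(grp["pos"].max() - grp["pos"].min() + 1)
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    return len(snps) / genome_bp


def pi_from_sfs(sfs: FoldedSFS, density: float) -> DiversityStats:
    """Per-bp nucleotide diversity from a projected folded spectrum.

    Total pairwise diversity is sum_k mass(k) * 2k(m-k)/(m(m-1)); the
    effective length is L = n_projected / density (density in SNPs per bp,
    so L is the bp span the projected SNPs represent) and pi = total / L.
    """
    if density <= 0:
        raise ValueError("snp density must be > 0")
    h = _pairwise_site_diversity(sfs.m)
    big_pi_total = float((sfs.mass * h).sum())
    L = sfs.n_projected / density
    if L <= 0:
        raise ValueError("effective sequence length is zero")
    return DiversityStats(
        pi=big_pi_total / L,
        big_pi_total=big_pi_total,
        L=L,
        S=sfs.segregating_mass,
        n_projected_snps=sfs.n_projected,
        snp_density=density,
    )


def tajima_constants(m: int) -> dict[str, float]:
    """Standard Tajima's D normalization constants for m chromosomes."""
    i = np.arange(1, m)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "b1": b1,
        "b2": b2,
        "c1": c1,
        "c2": c2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def tajimas_d(sfs: FoldedSFS) -> float:
    """Tajima's D from the projected folded spectrum.

    Uses fractional masses: S = segregating mass, pi-hat = pairwise-form
    theta estimate (fold-invariant), constants at m chromosomes. Undefined
    (NaN) when S = 0.
    """
    s = sfs.segregating_mass
    if s <= 0:
        return float("nan")
    const = tajima_constants(sfs.m)
    h = _pairwise_site_diversity(sfs.m)
    pi_hat = float((sfs.mass * h).sum())
    var = const["e1"] * s + const["e2"] * s * (s - 1.0)
    return (pi_hat - s / const["a1"]) / np.sqrt(var)


def big_pi_per_snp(
    matrix: GenotypeMatrix, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Average pairwise mismatch fraction per SNP.

    With c0 reference and c1 alternate chromosomes among called genotypes,
    Pi = c0*c1 / C(c0+c1, 2). NaN when fewer than 2 genotypes are called.
    """
    counts = matrix.allele_counts(sample_idx)
    alt = counts[:, 0].astype(float)
    chroms = counts[:, 1].astype(float)
    ref = chroms - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs = chroms * (chroms - 1) / 2.0
        pi = np.where(chroms >= 4, alt * ref / np.where(pairs > 0, pairs, 1.0), np.nan)
    return pi


def heterozygosity_and_callrate_tracks(
    matrix: GenotypeMatrix, subpop: str | None = None
) -> pd.DataFrame:
    """Per-SNP heterozygote proportion (among called) and call rate."""
    idx = (
        matrix.subpop_indices(subpop)
        if subpop is not None
        else np.arange(matrix.n_samples)
    )
    d = matrix.dosages[idx]
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (d == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    call_rate = n_called / idx.size
    return pd.DataFrame(
        {
            "chrom": matrix.snps["chrom"].to_numpy(),
            "pos": matrix.snps["pos"].to_numpy(),
            "heterozygosity": het,
            "call_rate": call_rate,
        },
        index=matrix.snps.index,
    )
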