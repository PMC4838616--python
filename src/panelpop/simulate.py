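"""Synthetic genotype panels with tunable structure.

The generator emulates the statistical features the downstream analysis
assumes: differentiated subpopulations under a Balding-Nichols model with
closed-form expected Fst, selfing-type excess homozygosity, two subgenomes
of unequal SNP density, heavy genotype dropout, and non-recombining
inversion regions segregating at subpopulation-specific frequencies.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, chrom_sort_key, subgenome_of
from .vcfio import write_vcf
from .types import RawVariantRecord

_WINTER = {"WE", "WA", "WAm"}


@dataclass
class InversionSpec:
    """A non-recombining region segregating as two fixed haplotypes.

    ``freq`` maps subpopulation name -> inverted-haplotype frequency.
    ``divergence`` is the per-SNP probability that the two haplotypes carry
    different alleles; ``noise`` is the per-call flip rate.
    """

    chrom: str
    start: int
    end: int
    freq: dict[str, float]
    divergence: float = 0.8
    noise: float = 0.01

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("inversion start > end")
        for v in list(self.freq.values()) + [self.divergence, self.noise]:
            if not 0.0 <= v <= 1.0:
                raise ValueError("inversion frequencies must lie in [0, 1]")


@dataclass
class InjectionConfig:
    """Counts of deliberately broken records for filter-cascade fixtures."""

    n_indels: int = 0
    n_triallelic: int = 0
    n_fixed_alt: int = 0
    n_imbalanced_hets: int = 0
    n_mismatch_entries: int = 0


@dataclass
class SimulationConfig:
    subpop_sizes: dict[str, int] = field(
        default_factory=lambda: {"WE": 120, "WA": 80, "SP": 70}
    )
    n_snps: dict[str, int] = field(default_factory=lambda: {"A": 1200, "C": 1800})
    #: scalar => same drift for every subpopulation (pairwise Fst == value);
    #: dict keyed by frozenset pairs => per-pair targets (matched marginally).
    target_fst: float | dict = 0.2
    f_is: float | dict = 0.8
    call_rate: float = 1.0
    call_rate_dispersion: float = 0.0
    depth_mean: float = 8.0
    depth_dispersion: float = 2.0
    inversions: list[InversionSpec] = field(default_factory=list)
    injections: InjectionConfig = field(default_factory=InjectionConfig)
    #: ancestral allele-frequency spectrum: "uniform" draws U(0.05, 0.95);
    #: "neutral" draws a 1/x-shaped minor-allele spectrum (random fold),
    #: which mimics the rare-variant excess of real panels and keeps
    #: per-SNP statistic tails narrow enough for outlier scans.
    ancestral_spectrum: str = "uniform"
    chrom_length: int = 50_000_000
    seed: int = 0
    #: when True, emitted VCFs have depths/AD that survive the default
    #: filter cascade unchanged (used by bookkeeping fixtures).
    consistent_depths: bool = False

    def __post_init__(self) -> None:
        for g, n in self.n_snps.items():
            if n < 1:
                raise ValueError(f"n_snps[{g}] must be >= 1")
        for v in self._fis_by_subpop().values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("f_is must lie in [0, 1]")
        for v in self._drift_by_subpop().values():
            if not 0.0 <= v < 1.0:
                raise ValueError("target_fst must lie in [0, 1)")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError("call_rate must lie in [0, 1]")
        if self.ancestral_spectrum not in ("uniform", "neutral"):
            raise ValueError("ancestral_spectrum must be 'uniform' or 'neutral'")
        for inv in self.inversions:
            if inv.end > self.chrom_length:
                raise ValueError("inversion interval outside chromosome bounds")

    def _fis_by_subpop(self) -> dict[str, float]:
        if isinstance(self.f_is, dict):
            return {s: self.f_is.get(s, 0.0) for s in self.subpop_sizes}
        return {s: float(self.f_is) for s in self.subpop_sizes}

    def _drift_by_subpop(self) -> dict[str, float]:
        """Per-subpopulation drift F against the shared ancestral pool.

        Two subpopulations with drifts Fx, Fy have expected Hudson Fst
        (Fx + Fy) / 2, so scalar targets map directly and pairwise targets
        are solved as a least-squares linear system.
        """
        subpops = list(self.subpop_sizes)
        if not isinstance(self.target_fst, dict):
            return {s: float(self.target_fst) for s in subpops}
        pairs = [(frozenset(k), v) for k, v in self.target_fst.items()]
        a = np.zeros((len(pairs), len(subpops)))
        b = np.zeros(len(pairs))
        for i, (pair, t) in enumerate(pairs):
            for s in pair:
                a[i, subpops.index(s)] = 1.0
            b[i] = 2.0 * t
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        return {s: float(np.clip(f, 0.0, 0.99)) for s, f in zip(subpops, sol)}


def _chromosomes_for(subgenome: str) -> list[str]:
    if subgenome == "A":
        return [f"A{i:02d}" for i in range(1, 11)]
    return [f"C{i:02d}" for i in range(1, 10)]


def _snp_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for sub in sorted(config.n_snps):
        chroms = _chromosomes_for(sub)
        n = config.n_snps[sub]
        per = [n // len(chroms)] * len(chroms)
        for i in range(n % len(chroms)):
            per[i] += 1
        for chrom, k in zip(chroms, per):
            if k == 0:
                continue
            pos = np.unique(rng.integers(1, config.chrom_length + 1, size=k))
            while pos.size < k:  # redraw collisions (sparse, converges fast)
                extra = rng.integers(1, config.chrom_length + 1, size=k - pos.size)
                pos = np.unique(np.concatenate([pos, extra]))
            pos.sort()
            for p in pos:
                rows.append((f"{chrom}_{p}", chrom, int(p)))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")
    return df


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a genotype panel under the configured structure model.

    Per SNP: ancestral frequency p ~ U(0.05, 0.95); subpopulation frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols; F = 0 keeps p exactly);
    genotypes drawn with P(het) = 2q(1-q)(1-F_is). Inversion regions
    override the site-wise draw; missingness is applied last. Deterministic
    under the config seed.

    The returned matrix carries simulation truth in attributes
    ``true_subpop_freqs`` (subpop -> per-SNP frequency array), ``drift_f``
    and ``inversion_genotypes`` ((chrom, start, end) -> copies of the
    inverted haplotype per sample).
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_layout(config, rng)
    n_snps = len(snps)
    drift = config._drift_by_subpop()
    fis = config._fis_by_subpop()

    if config.ancestral_spectrum == "uniform":
        p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    else:  # 1/x-shaped minor-allele spectrum on [0.02, 0.5], random fold
        x_min = 0.02
        u = rng.random(n_snps)
        maf = x_min * (0.5 / x_min) ** u
        flip = rng.random(n_snps) < 0.5
        p_anc = np.where(flip, 1.0 - maf, maf)
    sample_rows = []
    blocks = []
    freqs: dict[str, np.ndarray] = {}
    for subpop in config.subpop_sizes:
        n = config.subpop_sizes[subpop]
        f = drift[subpop]
        if f == 0.0:
            q = p_anc.copy()
        else:
            c = (1.0 - f) / f
            q = rng.beta(np.maximum(p_anc * c, 1e-9), np.maximum((1 - p_anc) * c, 1e-9))
        freqs[subpop] = q
        fi = fis[subpop]
        p_hom_alt = q * q + fi * q * (1 - q)
        p_het = 2 * q * (1 - q) * (1 - fi)
        u = rng.random((n, n_snps))
        g = np.where(u < p_hom_alt, 2, np.where(u < p_hom_alt + p_het, 1, 0))
        blocks.append(g.astype(np.int8))
        habit = "spring" if subpop.startswith("S") else "winter"
        geo = {"WE": "Europe", "WA": "Asia", "WAm": "America", "SP": "Europe"}.get(
            subpop, "Europe"
        )
        for i in range(n):
            sample_rows.append((f"{subpop}_{i:04d}", habit, geo, subpop))

    dosages = np.vstack(blocks)
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "growth_habit", "geography", "subpop"]
    ).set_index("sample_id")
    matrix = GenotypeMatrix(dosages, samples, snps, validate=False)
    matrix.true_subpop_freqs = freqs
    matrix.drift_f = drift
    matrix.inversion_genotypes = {}

    for spec in config.inversions:
        matrix = simulate_inversion(matrix, spec, rng)

    _apply_missingness(matrix, config, rng)
    return matrix


def simulate_inversion(
    matrix: GenotypeMatrix, spec: InversionSpec, rng: np.random.Generator
) -> GenotypeMatrix:
    """Overwrite a region's genotypes with a two-haplotype inversion pattern.

    Every sample receives 0/1/2 copies of the inverted haplotype per its
    subpopulation's frequency; the two fixed haplotype allele vectors differ
    per SNP with probability ``spec.divergence``; heterozygous carriers are
    heterozygous at differing sites. A small per-call noise rate flips
    dosages. Missing entries stay missing.
    """
    chroms = matrix.snps["chrom"].to_numpy()
    pos = matrix.snps["pos"].to_numpy()
    region = np.flatnonzero(
        (chroms == spec.chrom) & (pos >= spec.start) & (pos <= spec.end)
    )
    if region.size < 20:
        raise ValueError(
            f"inversion region {spec.chrom}:{spec.start}-{spec.end} has "
            f"{region.size} SNPs (< 20); pattern would be undetectable"
        )
    out = matrix.copy()
    h0 = rng.integers(0, 2, size=region.size)
    differs = rng.random(region.size) < spec.divergence
    h1 = np.where(differs, 1 - h0, h0)

    subpops = out.samples["subpop"].to_numpy()
    inv_copies = np.empty(out.n_samples, dtype=np.int8)
    for subpop in np.unique(subpops):
        sel = subpops == subpop
        f = spec.freq.get(subpop, 0.0)
        inv_copies[sel] = rng.binomial(2, f, size=sel.sum())

    new = (
        np.outer(2 - inv_copies, h0) + np.outer(inv_copies, h1)
    ).astype(np.int8)
    flip = rng.random(new.shape) < spec.noise
    noise_vals = rng.integers(0, 3, size=new.shape).astype(np.int8)
    new = np.where(flip, noise_vals, new)

    missing = out.dosages[:, region] == MISSING
    block = np.where(missing, MISSING, new).astype(np.int8)
    out.dosages[:, region] = block

    truths = dict(getattr(matrix, "inversion_genotypes", {}))
    truths[(spec.chrom, spec.start, spec.end)] = inv_copies
    out.inversion_genotypes = truths
    out.true_subpop_freqs = getattr(matrix, "true_subpop_freqs", {})
    out.drift_f = getattr(matrix, "drift_f", {})
    return out


def _apply_missingness(
    matrix: GenotypeMatrix, config: SimulationConfig, rng: np.random.Generator
) -> None:
    if config.call_rate >= 1.0:
        return
    n, s = matrix.dosages.shape
    if config.call_rate_dispersion > 0:
        shape = 1.0 / config.call_rate_dispersion
        snp_factor = rng.gamma(shape, 1.0 / shape, size=s)
    else:
        snp_factor = np.ones(s)
    p_call = np.clip(config.call_rate * snp_factor, 0.0, 1.0)
    called = rng.random((n, s)) < p_call
    # every SNP keeps at least one call (matrix invariant)
    empty = np.flatnonzero(~called.any(axis=0))
    if empty.size:
        keep = rng.integers(0, n, size=empty.size)
        called[keep, empty] = True
    matrix.dosages[~called] = MISSING


@dataclass
class VcfTruth:
    """Bookkeeping of what :func:`emit_raw_vcf` wrote (for test assertions)."""

    n_base: int
    n_indels: int
    n_triallelic: int
    n_fixed_alt: int
    imbalanced_hets: list[tuple[str, int, int]]
    mismatch_entries: list[tuple[str, int, int]]
    n_low_depth_calls: int


def emit_raw_vcf(
    matrix: GenotypeMatrix, config: SimulationConfig, path
) -> VcfTruth:
    """Write a raw VCF for the matrix, with per-genotype DP/AD and planted
    filter violations per ``config.injections``.

    DP ~ negative binomial (``depth_mean``, ``depth_dispersion``); AD splits
    DP consistently with the genotype plus error reads. With
    ``config.consistent_depths`` every called genotype gets DP >= 4 and
    balanced het AD so that only the planted violations are filterable.
    """
    rng = np.random.default_rng(config.seed + 987654321)
    inj = config.injections
    n = matrix.n_samples
    k = config.depth_dispersion
    p_nb = k / (k + config.depth_mean)

    def draw_dp(size):
        return rng.negative_binomial(k, p_nb, size=size)

    records: list[RawVariantRecord] = []
    chroms = matrix.snps["chrom"].to_numpy()
    positions = matrix.snps["pos"].to_numpy()
    n_low_depth = 0

    # choose planted het-imbalance / mismatch entries among called genotypes,
    # skipping SNPs the non-biallelic/fixed-alt stage would drop anyway
    called = matrix.called()
    fixed_alt_site = (np.where(called, matrix.dosages, 2) == 2).all(axis=0)
    plantable = called & ~fixed_alt_site[None, :]
    het = (matrix.dosages == 1) & plantable
    het_entries = np.argwhere(het)
    call_entries = np.argwhere(plantable & ~het)
    if inj.n_imbalanced_hets > len(het_entries):
        raise ValueError("not enough het calls to plant imbalanced hets")
    if inj.n_mismatch_entries > len(call_entries):
        raise ValueError("not enough non-het calls to plant mismatch entries")
    imb_pick = het_entries[
        rng.choice(len(het_entries), size=inj.n_imbalanced_hets, replace=False)
    ] if inj.n_imbalanced_hets else np.empty((0, 2), dtype=int)
    mm_pick = call_entries[
        rng.choice(len(call_entries), size=inj.n_mismatch_entries, replace=False)
    ] if inj.n_mismatch_entries else np.empty((0, 2), dtype=int)
    imb_by_snp: dict[int, list[int]] = {}
    for i, j in imb_pick:
        imb_by_snp.setdefault(j, []).append(i)
    mm_by_snp: dict[int, list[int]] = {}
    for i, j in mm_pick:
        mm_by_snp.setdefault(j, []).append(i)

    imbalanced_truth: list[tuple[str, int, int]] = []
    mismatch_truth: list[tuple[str, int, int]] = []

    for j in range(matrix.n_snps):
        dos = matrix.dosages[:, j]
        gt = np.full((n, 2), -1, dtype=np.int32)
        gt[dos == 0] = (0, 0)
        gt[dos == 1] = (0, 1)
        gt[dos == 2] = (1, 1)
        dp = draw_dp(n).astype(np.int64)
        is_called = dos != MISSING
        if config.consistent_depths:
            dp[is_called] = np.maximum(dp[is_called], 4)
        dp[~is_called] = np.minimum(dp[~is_called], 3)
        n_low_depth += int((dp[is_called] < 4).sum())

        alt_reads = np.zeros(n, dtype=np.int64)
        err = rng.binomial(np.maximum(dp, 0), 0.01)
        hom_ref = dos == 0
        hom_alt = dos == 2
        is_het = dos == 1
        alt_reads[hom_ref] = err[hom_ref]
        alt_reads[hom_alt] = dp[hom_alt] - err[hom_alt]
        alt_reads[is_het] = rng.binomial(dp[is_het], 0.5)
        if config.consistent_depths and is_het.any():
            # keep het minor-read fraction comfortably above the 0.2 recode rule
            lo = np.ceil(0.25 * dp[is_het]).astype(np.int64)
            hi = dp[is_het] - lo
            alt_reads[is_het] = np.clip(alt_reads[is_het], lo, np.maximum(hi, lo))
        chrom, pos = chroms[j], int(positions[j])
        for i in imb_by_snp.get(j, ()):
            d = max(int(dp[i]), 5)
            dp[i] = d
            alt_reads[i] = int(0.1 * d)  # minor fraction <= 0.1 < 0.2
            imbalanced_truth.append((chrom, pos, i))
        mm = rng.integers(0, 3, size=n).astype(np.int32)
        for i in mm_by_snp.get(j, ()):
            mm[i] = 4 + int(rng.integers(0, 3))
            mismatch_truth.append((chrom, pos, i))

        ad = np.stack([dp - alt_reads, alt_reads], axis=1).astype(np.int32)
        records.append(
            RawVariantRecord(
                chrom=chrom,
                pos=pos,
                ref="A",
                alts=["G"],
                gt=gt,
                ad=ad,
                dp=dp.astype(np.int32),
                mismatches=mm,
            )
        )

    taken = {(r.chrom, r.pos) for r in records}

    def free_site():
        while True:
            chrom = str(rng.choice(chroms))
            pos = int(rng.integers(1, config.chrom_length + 1))
            if (chrom, pos) not in taken:
                taken.add((chrom, pos))
                return chrom, pos

    def junk_genotypes(n_alleles: int):
        gt = np.full((n, 2), -1, dtype=np.int32)
        which = rng.random(n) < 0.5
        alleles = rng.integers(0, n_alleles, size=(n, 2)).astype(np.int32)
        gt[which] = alleles[which]
        dp = draw_dp(n).astype(np.int32)
        ad = np.zeros((n, n_alleles), dtype=np.int32)
        for i in range(n):
            if which[i]:
                ad[i, gt[i, 0]] += dp[i] // 2
                ad[i, gt[i, 1]] += dp[i] - dp[i] // 2
        mm = rng.integers(0, 3, size=n).astype(np.int32)
        return gt, ad, dp, mm

    for _ in range(inj.n_indels):
        chrom, pos = free_site()
        gt, ad, dp, mm = junk_genotypes(2)
        records.append(
            RawVariantRecord(chrom, pos, "A", ["AT"], gt, ad, dp, mismatches=mm)
        )
    for _ in range(inj.n_triallelic):
        chrom, pos = free_site()
        gt, ad, dp, mm = junk_genotypes(3)
        records.append(
            RawVariantRecord(chrom, pos, "A", ["C", "G"], gt, ad, dp, mismatches=mm)
        )
    for _ in range(inj.n_fixed_alt):
        chrom, pos = free_site()
        gt = np.full((n, 2), -1, dtype=np.int32)
        which = rng.random(n) < 0.8
        gt[which] = (1, 1)
        dp = draw_dp(n).astype(np.int64)
        if config.consistent_depths:
            dp[which] = np.maximum(dp[which], 4)
        err = rng.binomial(np.maximum(dp, 0), 0.01)
        alt_reads = np.where(which, dp - err, 0)
        ad = np.stack([dp - alt_reads, alt_reads], axis=1).astype(np.int32)
        mm = rng.integers(0, 3, size=n).astype(np.int32)
        records.append(
            RawVariantRecord(
                chrom, pos, "A", ["G"], gt, ad, dp.astype(np.int32), mismatches=mm
            )
        )

    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos))
    write_vcf(
        records,
        matrix.sample_ids,
        path,
        contig_lengths={c: config.chrom_length for c in np.unique(chroms)},
    )
    return VcfTruth(
        n_base=matrix.n_snps,
        n_indels=inj.n_indels,
        n_triallelic=inj.n_triallelic,
        n_fixed_alt=inj.n_fixed_alt,
        imbalanced_hets=imbalanced_truth,
        mismatch_entries=mismatch_truth,
        n_low_depth_calls=n_low_depth,
    )
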