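"""Region-of-interest scanning and inversion-signature diagnosis.

SNPs whose per-SNP statistic exceeds the genome-wide mean + k SD are
merged into candidate regions; each region's PC1 score distribution is
clustered to detect the discrete band pattern produced by a segregating
non-recombining haplotype pair (two homozygote bands plus a heterozygote
middle band).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ppca import ppca_fit
from .types import MISSING, GenotypeMatrix, chrom_sort_key


@dataclass
class RegionOfInterest:
    chrom: str
    start: int
    end: int
    n_outlier_snps: int
    trigger: str = ""
    diagnosis: str = "none"  # none | two-band | three-band
    band_occupancy: pd.DataFrame | None = None
    pc1_scores: np.ndarray | None = None
    band_assignment: np.ndarray | None = None
    reason: str = ""


def outlier_snps(values: np.ndarray, k_sd: float = 3.0) -> np.ndarray:
    """Indices of SNPs with value > mean + k_sd * SD (NaN ignored).

    The mean/SD are genome-wide over defined values; an all-identical track
    flags nothing.
    """
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    if defined.sum() < 2:
        return np.empty(0, dtype=int)
    mu = values[defined].mean()
    sd = values[defined].std(ddof=0)
    if sd == 0:
        return np.empty(0, dtype=int)
    return np.flatnonzero(defined & (values > mu + k_sd * sd))


def merge_regions(
    chroms: np.ndarray,
    positions: np.ndarray,
    flagged: np.ndarray,
    max_gap_bp: int = 1_000_000,
    min_snps: int = 10,
) -> list[RegionOfInterest]:
    """Merge flagged SNPs within ``max_gap_bp`` on one chromosome into
    regions; drop regions with < ``min_snps`` members. Boundaries are the
    first/last member positions (1-based inclusive)."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    flagged = np.asarray(flagged, dtype=int)
    if flagged.size == 0:
        return []
    order = sorted(
        flagged, key=lambda i: (chrom_sort_key(str(chroms[i])), positions[i])
    )
    regions: list[RegionOfInterest] = []
    cur_chrom, cur_start, cur_end, cur_n = None, 0, 0, 0
    for i in order:
        c, p = str(chroms[i]), int(positions[i])
        if c == cur_chrom and p - cur_end <= max_gap_bp:
            cur_end, cur_n = p, cur_n + 1
        else:
            if cur_chrom is not None and cur_n >= min_snps:
                regions.append(
                    RegionOfInterest(cur_chrom, cur_start, cur_end, cur_n)
                )
            cur_chrom, cur_start, cur_end, cur_n = c, p, p, 1
    if cur_chrom is not None and cur_n >= min_snps:
        regions.append(RegionOfInterest(cur_chrom, cur_start, cur_end, cur_n))
    return regions


def _kmeans_1d(x: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Exact (globally optimal) 1-D k-means by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the problem
    reduces to a k-segmentation minimizing within-segment SSE.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i: int, j: int) -> float:  # segment xs[i:j]
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        return s2 - s * s / (j - i)

    inf = np.inf
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, arg = inf, kk - 1
            for i in range(kk - 1, j):
                c = cost[kk - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[kk, j] = best
            split[kk, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for kk in range(k, 0, -1):
        i = split[kk, j]
        labels_sorted[i:j] = kk - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def _silhouette_1d(x: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    if len(np.unique(labels)) < 2:
        return -1.0
    return float(silhouette_score(x.reshape(-1, 1), labels))


def _bands_valid(
    x: np.ndarray, labels: np.ndarray, separation_ratio: float
) -> bool:
    """Adjacent clusters must be separated by a gap larger than
    ``separation_ratio`` x the larger of the two within-cluster spreads."""
    ks = np.unique(labels)
    for a, b in zip(ks[:-1], ks[1:]):
        xa, xb = x[labels == a], x[labels == b]
        gap = xb.min() - xa.max()
        spread = max(xa.std(ddof=0), xb.std(ddof=0), 1e-12)
        if gap <= separation_ratio * spread:
            return False
    return True


def region_pca_banding(
    matrix: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    min_snps: int = 20,
    separation_ratio: float = 0.5,
    seed: int = 0,
) -> RegionOfInterest:
    """Diagnose the band structure of PC1 within one region.

    PPCA restricted to the region's SNPs; PC1 scores are clustered with
    1-D k-means at k = 1, 2, 3; a k > 1 solution is accepted only when
    every adjacent band pair is separated by a clear gap (see
    ``separation_ratio``); among accepted solutions the best silhouette
    wins. ``three-band`` requires k = 3. Per-subpopulation occupancy of
    each band is reported. Runs on all samples jointly.
    """
    snp_chroms = matrix.snps["chrom"].to_numpy()
    snp_pos = matrix.snps["pos"].to_numpy()
    region_snps = np.flatnonzero(
        (snp_chroms == chrom) & (snp_pos >= start) & (snp_pos <= end)
    )
    roi = RegionOfInterest(chrom, start, end, n_outlier_snps=region_snps.size)
    if region_snps.size < min_snps:
        roi.reason = f"only {region_snps.size} SNPs in region (< {min_snps})"
        return roi
    sub = matrix.take_snps(region_snps)
    has_call = sub.called().any(axis=1)
    sample_sel = np.flatnonzero(has_call)
    sub = sub.take_samples(sample_sel)
    q = min(2, min(sub.n_samples, sub.n_snps) - 1)
    result = ppca_fit(sub, q=q, seed=seed, max_iter=100)
    pc1 = result.scores[:, 0]
    roi.pc1_scores = pc1

    best_k, best_labels, best_sil = 1, np.zeros(pc1.size, dtype=int), -np.inf
    for k in (2, 3):
        if pc1.size <= k:
            continue
        labels = _kmeans_1d(pc1, k, seed=seed)
        if len(np.unique(labels)) < k:
            continue
        if not _bands_valid(pc1, labels, separation_ratio):
            continue
        sil = _silhouette_1d(pc1, labels)
        if sil > best_sil:
            best_k, best_labels, best_sil = k, labels, sil

    roi.band_assignment = best_labels
    if best_k == 3:
        roi.diagnosis = "three-band"
    elif best_k == 2:
        roi.diagnosis = "two-band"
    else:
        roi.diagnosis = "none"
        roi.reason = roi.reason or "no separated band structure on PC1"

    subpops = sub.samples["subpop"].to_numpy()
    occ = pd.crosstab(
        pd.Series(subpops, name="subpop"),
        pd.Series(best_labels, name="band"),
    )
    roi.band_occupancy = occ
    return roi


def scan_genome(
    matrix: GenotypeMatrix,
    tracks: dict[str, np.ndarray],
    k_sd: float = 3.0,
    max_gap_bp: int = 1_000_000,
    min_snps: int = 10,
    min_region_snps: int = 20,
    separation_ratio: float = 0.5,
    seed: int = 0,
) -> list[RegionOfInterest]:
    """Full scan: outlier SNPs per track -> merged regions -> banding.

    ``tracks`` maps a trigger name (e.g. "fst:WE-SP" or "pi:WA") to a
    per-SNP statistic array aligned with ``matrix.snps``. Overlapping
    regions from different tracks are reported separately with their
    trigger names.
    """
    chroms = matrix.snps["chrom"].to_numpy()
    positions = matrix.snps["pos"].to_numpy()
    out: list[RegionOfInterest] = []
    for trigger, values in tracks.items():
        flagged = outlier_snps(values, k_sd=k_sd)
        for region in merge_regions(
            chroms, positions, flagged, max_gap_bp=max_gap_bp, min_snps=min_snps
        ):
            diag = region_pca_banding(
                matrix,
                region.chrom,
                region.start,
                region.end,
                min_snps=min_region_snps,
                separation_ratio=separation_ratio,
                seed=seed,
            )
            diag.trigger = trigger
            diag.n_outlier_snps = region.n_outlier_snps
            out.append(diag)
    return out


def roi_table(regions: list[RegionOfInterest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_outlier_snps": r.n_outlier_snps,
                "trigger": r.trigger,
                "diagnosis": r.diagnosis,
                "reason": r.reason,
            }
            for r in regions
        ]
    )
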