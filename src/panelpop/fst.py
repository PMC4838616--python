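"""Hudson-estimator Fst: genome-wide ratio of averages and per-SNP track.

The genome-wide estimate is sum(numerators)/sum(denominators) over
qualifying SNPs (ratio of averages); per-SNP values are kept, may be
negative, and recombine exactly to the genome-wide value. An optional
inbreeding adjustment deflates each subpopulation's chromosome count to
n/(1 + F) with F estimated from that subpopulation's heterozygote deficit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix


@dataclass
class FstResult:
    pair: tuple[str, str]
    ascertainment: str
    subgenome: str | None
    fst: float
    n_snps: int
    numerators: np.ndarray
    denominators: np.ndarray
    snp_indices: np.ndarray
    inbreeding_adjust: bool
    f_hat: dict[str, float]

    @property
    def fst_clipped(self) -> float:
        """Reporting convenience; the raw ratio is in ``fst``."""
        return float(np.clip(self.fst, 0.0, 1.0))


def hudson_components(p1, n1, p2, n2):
    """Per-SNP Hudson numerator/denominator from sample frequencies.

    ``n1``/``n2`` are chromosome counts (may be non-integer after the
    inbreeding deflation); both must exceed 1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("need > 1 chromosome in each subpopulation")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def estimate_f_is(matrix: GenotypeMatrix, subpop: str) -> float:
    """Inbreeding coefficient from the heterozygote deficit.

    F = 1 - mean(H_obs)/mean(H_exp) over SNPs polymorphic in the
    subpopulation, clipped to [0, 1].
    """
    idx = matrix.subpop_indices(subpop)
    d = matrix.dosages[idx]
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, d, 0).sum(axis=0) / np.maximum(2 * n_called, 1)
        h_obs = (d == 1).sum(axis=0) / np.maximum(n_called, 1)
    h_exp = 2 * p * (1 - p)
    poly = (n_called > 0) & (p > 0) & (p < 1)
    if not poly.any():
        return 0.0
    f = 1.0 - h_obs[poly].mean() / h_exp[poly].mean()
    return float(np.clip(f, 0.0, 1.0))


def _freqs_and_counts(matrix: GenotypeMatrix, subpop: str):
    idx = matrix.subpop_indices(subpop)
    if idx.size == 0:
        raise ValueError(f"subpopulation {subpop!r} has no samples")
    counts = matrix.allele_counts(idx)
    alt, chroms = counts[:, 0].astype(float), counts[:, 1].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(chroms > 0, alt / np.maximum(chroms, 1), np.nan)
    return p, chroms


def _ascertained(p: np.ndarray, chroms: np.ndarray) -> np.ndarray:
    """Polymorphic in the ascertainment subpopulation: minor count >= 1."""
    return (chroms > 0) & (p > 0) & (p < 1)


def genomewide_fst(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    subgenome: str | None = None,
    ascertainment: str | None = None,
    inbreeding_adjust: bool = True,
) -> FstResult:
    """Ratio-of-averages Hudson Fst over ascertained SNPs of one subgenome.

    SNPs qualify when both subpopulations have >= 2 called chromosomes and
    the site is polymorphic (minor allele present) in the ascertainment
    subpopulation (default: the first of ``pair``).
    """
    s1, s2 = pair
    ascertainment = ascertainment or s1
    if ascertainment not in pair:
        raise ValueError("ascertainment subpopulation must be one of the pair")
    p1, c1 = _freqs_and_counts(matrix, s1)
    p2, c2 = _freqs_and_counts(matrix, s2)
    pa = p1 if ascertainment == s1 else p2
    ca = c1 if ascertainment == s1 else c2

    keep = _ascertained(pa, ca) & (c1 >= 2) & (c2 >= 2)
    if subgenome is not None:
        keep &= (matrix.snps["subgenome"] == subgenome).to_numpy()
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(
            f"no qualifying SNPs for pair {pair} ascertained in {ascertainment}"
            f" (subgenome {subgenome})"
        )

    f_hat = {s1: 0.0, s2: 0.0}
    n1 = c1[idx]
    n2 = c2[idx]
    if inbreeding_adjust:
        f_hat = {s: estimate_f_is(matrix, s) for s in pair}
        n1 = n1 / (1.0 + f_hat[s1])
        n2 = n2 / (1.0 + f_hat[s2])

    num, den = hudson_components(p1[idx], n1, p2[idx], n2)
    return FstResult(
        pair=(s1, s2),
        ascertainment=ascertainment,
        subgenome=subgenome,
        fst=float(num.sum() / den.sum()),
        n_snps=idx.size,
        numerators=num,
        denominators=den,
        snp_indices=idx,
        inbreeding_adjust=inbreeding_adjust,
        f_hat=f_hat,
    )


def per_snp_fst_track(
    matrix: GenotypeMatrix,
    pair: tuple[str, str],
    inbreeding_adjust: bool = False,
) -> pd.DataFrame:
    """Per-SNP Hudson Fst (numerator/denominator) in genome order.

    Sites where the denominator is 0 (monomorphic in both subpopulations)
    or where either subpopulation has < 2 called chromosomes get NaN.
    Columns: chrom, pos, fst, numerator, denominator.
    """
    s1, s2 = pair
    p1, c1 = _freqs_and_counts(matrix, s1)
    p2, c2 = _freqs_and_counts(matrix, s2)
    ok = (c1 >= 2) & (c2 >= 2)
    n1 = np.maximum(c1, 2.0)
    n2 = np.maximum(c2, 2.0)
    if inbreeding_adjust:
        n1 = n1 / (1.0 + estimate_f_is(matrix, s1))
        n2 = n2 / (1.0 + estimate_f_is(matrix, s2))
    p1s = np.where(ok, p1, 0.5)
    p2s = np.where(ok, p2, 0.5)
    num, den = hudson_components(p1s, n1, p2s, n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ok & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return pd.DataFrame(
        {
            "chrom": matrix.snps["chrom"].to_numpy(),
            "pos": matrix.snps["pos"].to_numpy(),
            "fst": fst,
            "numerator": num,
            "denominator": den,
        },
        index=matrix.snps.index,
    )


def fst_table(
    matrix: GenotypeMatrix,
    pairs: list[tuple[str, str]],
    subgenomes: tuple[str, ...] = ("A", "C"),
    inbreeding_adjust: bool = True,
) -> pd.DataFrame:
    """Dual-ascertainment Fst per pair and subgenome (long table)."""
    rows = []
    for pair in pairs:
        for asc in pair:
            for sub in subgenomes:
                r = genomewide_fst(
                    matrix,
                    pair,
                    subgenome=sub,
                    ascertainment=asc,
                    inbreeding_adjust=inbreeding_adjust,
                )
                rows.append(
                    {
                        "pop1": pair[0],
                        "pop2": pair[1],
                        "ascertainment": asc,
                        "subgenome": sub,
                        "fst": r.fst,
                        "n_snps": r.n_snps,
                    }
                )
    return pd.DataFrame(rows)
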