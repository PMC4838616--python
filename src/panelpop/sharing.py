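"""Venn partition of minor-allele presence across subpopulations.

The minor allele is defined once, from the pooled frequency over the three
major subpopulations (ties at 0.5 break toward the alternate allele);
presence in a subpopulation means >= 1 copy of that allele among its called
genotypes. Counts are reported per subgenome, optionally averaged over
random downsamplings that equalize subpopulation sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

DEFAULT_SUBPOPS = ("WE", "WA", "SP")


@dataclass
class SharingPartition:
    subpops: tuple[str, ...]
    subgenome: str | None
    #: Venn cell -> SNP count; keys are frozensets of subpop names.
    cells: dict[frozenset, float]
    totals: dict[str, float]
    n_snps_with_minor: float
    replicate_sd: dict[frozenset, float] | None = None
    n_replicates: int = 0

    def cell(self, *subpops: str) -> float:
        return self.cells[frozenset(subpops)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell": "+".join(sorted(k)),
                "n_subpops": len(k),
                "count": v,
                "sd": (self.replicate_sd or {}).get(k, 0.0),
            }
            for k, v in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def define_minor_allele(
    matrix: GenotypeMatrix, subpops: tuple[str, ...] = DEFAULT_SUBPOPS
) -> np.ndarray:
    """Per-SNP minor allele (0 = reference, 1 = alternate) from the pooled
    frequency over the given subpopulations; ties break toward alternate.
    SNPs uncalled in all subpopulations get -1 (excluded downstream).
    """
    idx = np.concatenate([matrix.subpop_indices(s) for s in subpops])
    counts = matrix.allele_counts(idx)
    alt, chroms = counts[:, 0], counts[:, 1]
    minor = np.full(matrix.n_snps, -1, dtype=np.int8)
    called = chroms > 0
    ref = chroms - alt
    # alt is minor when alt count <= ref count (tie -> alternate)
    minor[called] = np.where(alt[called] <= ref[called], 1, 0)
    return minor


def _presence(
    matrix: GenotypeMatrix, minor: np.ndarray, sample_idx: np.ndarray
) -> np.ndarray:
    """Per-SNP bool: >= 1 copy of the minor allele among called genotypes."""
    d = matrix.dosages[sample_idx]
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=0)
    chroms = 2 * called.sum(axis=0)
    minor_copies = np.where(minor == 1, alt, chroms - alt)
    return (minor >= 0) & (minor_copies >= 1)


def venn_partition(
    matrix: GenotypeMatrix,
    subpops: tuple[str, ...] = DEFAULT_SUBPOPS,
    subgenome: str | None = None,
    minor: np.ndarray | None = None,
    sample_indices: dict[str, np.ndarray] | None = None,
) -> SharingPartition:
    """7-cell presence partition for one subgenome.

    ``sample_indices`` overrides the per-subpopulation sample sets (used by
    downsampling); the minor-allele definition stays fixed unless supplied.
    """
    if minor is None:
        minor = define_minor_allele(matrix, subpops)
    snp_mask = np.ones(matrix.n_snps, dtype=bool)
    if subgenome is not None:
        snp_mask = (matrix.snps["subgenome"] == subgenome).to_numpy()

    pres = {}
    for s in subpops:
        idx = (
            sample_indices[s] if sample_indices is not None else matrix.subpop_indices(s)
        )
        pres[s] = _presence(matrix, minor, idx) & snp_mask

    any_present = np.zeros(matrix.n_snps, dtype=bool)
    for s in subpops:
        any_present |= pres[s]

    cells: dict[frozenset, float] = {}
    for r in range(1, len(subpops) + 1):
        for combo in combinations(subpops, r):
            mask = any_present.copy()
            for s in subpops:
                mask &= pres[s] if s in combo else ~pres[s]
            cells[frozenset(combo)] = float(mask.sum())
    totals = {s: float(pres[s].sum()) for s in subpops}
    return SharingPartition(
        subpops=tuple(subpops),
        subgenome=subgenome,
        cells=cells,
        totals=totals,
        n_snps_with_minor=float(any_present.sum()),
    )


def downsampled_partition(
    matrix: GenotypeMatrix,
    target_n: int,
    n_replicates: int = 100,
    seed: int = 0,
    subpops: tuple[str, ...] = DEFAULT_SUBPOPS,
    subgenome: str | None = None,
) -> SharingPartition:
    """Partition averaged over random downsamplings to ``target_n`` samples.

    Subpopulations larger than ``target_n`` are sampled without replacement
    each replicate; smaller-or-equal ones are used as-is (exactly equal is
    the identity). The minor-allele definition is fixed from the full
    matrix so cells stay comparable across replicates.
    """
    rng = np.random.default_rng(seed)
    minor = define_minor_allele(matrix, subpops)
    full_idx = {s: matrix.subpop_indices(s) for s in subpops}
    for s, idx in full_idx.items():
        if target_n > idx.size:
            raise ValueError(
                f"target_n={target_n} exceeds size of subpopulation {s} ({idx.size})"
            )
    acc: dict[frozenset, list[float]] = {}
    totals_acc: dict[str, list[float]] = {s: [] for s in subpops}
    n_with_minor: list[float] = []
    for _ in range(n_replicates):
        indices = {
            s: (
                rng.choice(idx, size=target_n, replace=False)
                if idx.size > target_n
                else idx
            )
            for s, idx in full_idx.items()
        }
        part = venn_partition(
            matrix, subpops, subgenome, minor=minor, sample_indices=indices
        )
        for k, v in part.cells.items():
            acc.setdefault(k, []).append(v)
        for s in subpops:
            totals_acc[s].append(part.totals[s])
        n_with_minor.append(part.n_snps_with_minor)
    cells = {k: float(np.mean(v)) for k, v in acc.items()}
    sds = {k: float(np.std(v, ddof=0)) for k, v in acc.items()}
    return SharingPartition(
        subpops=tuple(subpops),
        subgenome=subgenome,
        cells=cells,
        totals={s: float(np.mean(v)) for s, v in totals_acc.items()},
        n_snps_with_minor=float(np.mean(n_with_minor)),
        replicate_sd=sds,
        n_replicates=n_replicates,
    )
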