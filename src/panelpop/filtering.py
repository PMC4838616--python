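"""Raw-variant -> analysis-set filter cascade.

Stage order is pinned: non-biallelic/fixed-alt removal -> low-depth
genotype masking -> imbalanced-het recoding -> mismatch-locus masking ->
site call-rate -> sample call-rate. Boundary semantics follow the source
thresholds strictly: DP < 4 masks (DP = 4 kept), > 3 mismatches masks
(3 kept), sites called in < 30 samples drop (30 kept), samples with
missingness > 0.80 drop.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, RawVariantRecord
from .vcfio import records_to_matrix

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_genotype_depth: int = 4
    het_imbalance_threshold: float = 0.2
    max_locus_mismatches: int = 3
    min_samples_called: int = 30
    max_sample_missingness: float = 0.80

    def __post_init__(self) -> None:
        if self.min_genotype_depth < 0 or self.max_locus_mismatches < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.het_imbalance_threshold <= 1.0:
            raise ValueError("het_imbalance_threshold must lie in [0, 1]")
        if not 0.0 <= self.max_sample_missingness <= 1.0:
            raise ValueError("max_sample_missingness must lie in [0, 1]")


@dataclass
class FilterStage:
    stage: str
    unit: str  # 'records' | 'genotypes' | 'samples'
    n_input: int
    n_removed: int
    detail: dict = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if stage.n_removed < 0 or stage.n_removed > stage.n_input:
            raise ValueError(f"inconsistent counts in stage {stage.stage}")
        self.stages.append(stage)

    def __getitem__(self, name: str) -> FilterStage:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "unit": s.unit,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "n_output": s.n_output,
                    **{f"detail_{k}": v for k, v in s.detail.items()},
                }
                for s in self.stages
            ]
        )


def remove_nonbiallelic(
    records: list[RawVariantRecord],
) -> tuple[list[RawVariantRecord], FilterStage]:
    """Keep 1-bp biallelic substitutions that are not fixed-alternate.

    Fixed-alternate = every called genotype is homozygous for the alternate
    allele (sites differing from the reference but invariant in the panel).
    """
    kept: list[RawVariantRecord] = []
    n_indel = n_multi = n_fixed = 0
    for r in records:
        if len(r.alts) != 1:
            n_multi += 1
            continue
        if len(r.ref) != 1 or len(r.alts[0]) != 1:
            n_indel += 1
            continue
        called = r.called_mask()
        if called.any() and (r.gt[called] == 1).all():
            n_fixed += 1
            continue
        kept.append(r)
    stage = FilterStage(
        stage="nonbiallelic_fixed_alt",
        unit="records",
        n_input=len(records),
        n_removed=n_indel + n_multi + n_fixed,
        detail={"indels": n_indel, "multiallelic": n_multi, "fixed_alt": n_fixed},
    )
    return kept, stage


def mask_low_depth(
    records: list[RawVariantRecord], config: FilterConfig
) -> tuple[list[RawVariantRecord], FilterStage]:
    """Set genotypes with DP < min_genotype_depth missing (absent DP => 0)."""
    out = []
    n_geno = n_masked = 0
    for r in records:
        r = r.copy()
        called = r.called_mask()
        n_geno += int(called.sum())
        dp = np.where(r.dp < 0, 0, r.dp)
        low = called & (dp < config.min_genotype_depth)
        r.gt[low] = -1
        n_masked += int(low.sum())
        out.append(r)
    stage = FilterStage(
        stage="low_depth_mask", unit="genotypes", n_input=n_geno, n_removed=n_masked
    )
    return out, stage


def recode_imbalanced_hets(
    records: list[RawVariantRecord], config: FilterConfig
) -> tuple[list[RawVariantRecord], FilterStage]:
    """Recode strongly imbalanced hets to the majority-read homozygote.

    A het whose minor-allele read fraction is < threshold becomes
    homozygous for the allele with more reads; hets without usable AD are
    set missing (imbalance cannot be assessed).
    """
    out = []
    n_het = n_recoded = n_dropped = 0
    for r in records:
        r = r.copy()
        het = r.called_mask() & (r.gt[:, 0] != r.gt[:, 1])
        n_het += int(het.sum())
        for i in np.flatnonzero(het):
            a, b = int(r.gt[i, 0]), int(r.gt[i, 1])
            ra, rb = int(r.ad[i, a]), int(r.ad[i, b])
            if ra < 0 or rb < 0 or ra + rb == 0:
                r.gt[i] = (-1, -1)
                n_dropped += 1
                continue
            frac = min(ra, rb) / (ra + rb)
            if frac < config.het_imbalance_threshold:
                major = a if ra >= rb else b
                r.gt[i] = (major, major)
                n_recoded += 1
        out.append(r)
    stage = FilterStage(
        stage="het_imbalance_recode",
        unit="genotypes",
        n_input=n_het,
        n_removed=n_recoded + n_dropped,
        detail={"recoded": n_recoded, "set_missing": n_dropped},
    )
    return out, stage


def drop_mismatch_loci(
    records: list[RawVariantRecord], config: FilterConfig
) -> tuple[list[RawVariantRecord], FilterStage]:
    """Mask (sample, locus) genotypes with > max_locus_mismatches mismatches.

    Requires the per-sample mismatch-count annotation (VCF MM field or a
    sidecar attached to the records); if absent everywhere, the stage is
    skipped with a logged warning.
    """
    if all(r.mismatches is None for r in records):
        warnings.warn(
            "per-locus mismatch counts absent; mismatch-locus stage skipped",
            stacklevel=2,
        )
        logger.warning("mismatch-locus stage skipped: no mismatch annotation")
        stage = FilterStage(
            stage="mismatch_locus_mask",
            unit="genotypes",
            n_input=0,
            n_removed=0,
            detail={"skipped": 1},
        )
        return list(records), stage
    out = []
    n_geno = n_masked = 0
    for r in records:
        r = r.copy()
        called = r.called_mask()
        n_geno += int(called.sum())
        if r.mismatches is not None:
            bad = called & (r.mismatches > config.max_locus_mismatches)
            r.gt[bad] = -1
            n_masked += int(bad.sum())
        out.append(r)
    stage = FilterStage(
        stage="mismatch_locus_mask",
        unit="genotypes",
        n_input=n_geno,
        n_removed=n_masked,
    )
    return out, stage


def apply_site_and_sample_callrate(
    records: list[RawVariantRecord],
    sample_ids: list[str],
    config: FilterConfig,
    sample_metadata: pd.DataFrame | None = None,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Site call-rate filter, then sample missingness filter; emit matrix.

    Sites called in < min_samples_called samples drop first; then samples
    with missingness > max_sample_missingness (computed over the surviving
    sites) drop. Raises if nothing survives.
    """
    report = report or FilterReport()
    matrix = records_to_matrix(records, sample_ids, sample_metadata)

    # genotype-level masking/recoding may have left sites fixed for the
    # alternate allele; sweep them here so the cascade is idempotent
    called = matrix.called()
    fixed_alt = np.array(
        [
            called[:, j].any() and (matrix.dosages[called[:, j], j] == 2).all()
            for j in range(matrix.n_snps)
        ],
        dtype=bool,
    )
    report.add(
        FilterStage(
            stage="post_stage_fixed_alt",
            unit="records",
            n_input=matrix.n_snps,
            n_removed=int(fixed_alt.sum()),
        )
    )
    if fixed_alt.any():
        matrix = matrix.take_snps(np.flatnonzero(~fixed_alt))

    called = matrix.called()
    keep_snps = called.sum(axis=0) >= config.min_samples_called
    report.add(
        FilterStage(
            stage="site_call_rate",
            unit="records",
            n_input=matrix.n_snps,
            n_removed=int((~keep_snps).sum()),
        )
    )
    matrix = matrix.take_snps(np.flatnonzero(keep_snps))
    if matrix.n_snps == 0:
        raise ValueError("no SNPs survive the site call-rate filter")

    missingness = 1.0 - matrix.called().sum(axis=1) / matrix.n_snps
    keep_samples = missingness <= config.max_sample_missingness
    report.add(
        FilterStage(
            stage="sample_missingness",
            unit="samples",
            n_input=matrix.n_samples,
            n_removed=int((~keep_samples).sum()),
        )
    )
    matrix = matrix.take_samples(np.flatnonzero(keep_samples))
    if matrix.n_samples == 0:
        raise ValueError("no samples survive the missingness filter")

    # a SNP may have lost its last call when samples dropped
    lost = matrix.called().sum(axis=0) == 0
    if lost.any():
        matrix = matrix.take_snps(np.flatnonzero(~lost))
    return matrix, report


def run_filter_cascade(
    records: list[RawVariantRecord],
    sample_ids: list[str],
    config: FilterConfig | None = None,
    sample_metadata: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run all stages in the pinned order and return matrix + full report."""
    config = config or FilterConfig()
    report = FilterReport()
    records, stage = remove_nonbiallelic(records)
    report.add(stage)
    records, stage = mask_low_depth(records, config)
    report.add(stage)
    records, stage = recode_imbalanced_hets(records, config)
    report.add(stage)
    records, stage = drop_mismatch_loci(records, config)
    report.add(stage)
    return apply_site_and_sample_callrate(
        records, sample_ids, config, sample_metadata, report
    )


def refilter_matrix(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> GenotypeMatrix:
    """Re-apply the matrix-level stages (fixed-alt sweep, site/sample
    call rate) to an already-filtered matrix; used for idempotence checks.
    """
    config = config or FilterConfig()
    called = matrix.called()
    fixed_alt = np.array(
        [
            called[:, j].any() and (matrix.dosages[called[:, j], j] == 2).all()
            for j in range(matrix.n_snps)
        ],
        dtype=bool,
    )
    out = matrix.take_snps(np.flatnonzero(~fixed_alt)) if fixed_alt.any() else matrix
    keep_snps = out.called().sum(axis=0) >= config.min_samples_called
    out = out.take_snps(np.flatnonzero(keep_snps))
    missingness = 1.0 - out.called().sum(axis=1) / max(out.n_snps, 1)
    keep_samples = missingness <= config.max_sample_missingness
    return out.take_samples(np.flatnonzero(keep_samples))


def record_level_stages(
    records: list[RawVariantRecord], config: FilterConfig | None = None
) -> list[RawVariantRecord]:
    """The four record/genotype-level stages only (used for idempotence checks)."""
    config = config or FilterConfig()
    records, _ = remove_nonbiallelic(records)
    records, _ = mask_low_depth(records, config)
    records, _ = recode_imbalanced_hets(records, config)
    records, _ = drop_mismatch_loci(records, config)
    return records
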