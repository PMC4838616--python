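"""VCF reading/writing for biallelic-and-simple-multiallelic SNP panels.

Reading is backed by cyvcf2; writing emits a minimal VCF v4.2 with
GT:AD:DP (and an optional per-sample MM mismatch-count field used by the
mismatch-locus filter). Multi-allelic records are retained at parse time;
the filter cascade rejects them later.
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np

from .types import MISSING, GenotypeMatrix, RawVariantRecord, chrom_sort_key

logger = logging.getLogger(__name__)


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed at all (malformed header etc.)."""


def read_vcf(path) -> list[RawVariantRecord]:
    """Parse a VCF v4.x with GT (and ideally AD/DP) FORMAT fields.

    Returns one :class:`RawVariantRecord` per data line, in file order.
    Missing genotypes ("./.") map to allele index -1; absent AD/DP fields
    produce a per-record warning and are stored as -1.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc

    records: list[RawVariantRecord] = []
    n_samples = len(vcf.samples)
    warned: set[str] = set()
    for v in vcf:
        gt = np.array([g[:2] for g in v.genotypes], dtype=np.int32)
        n_alleles = 1 + len(v.ALT)

        ad = _format_field(v, "AD", (n_samples, n_alleles), warned, v.CHROM, v.POS)
        dp = _format_field(v, "DP", (n_samples,), warned, v.CHROM, v.POS)
        mm = None
        try:
            raw = v.format("MM")
        except KeyError:
            raw = None
        if raw is not None:
            mm = _sanitize(raw, (n_samples,))

        records.append(
            RawVariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=list(v.ALT),
                gt=gt,
                ad=ad,
                dp=dp,
                mismatches=mm,
            )
        )
    vcf.close()
    return records


def _format_field(v, key, shape, warned, chrom, pos) -> np.ndarray:
    try:
        raw = v.format(key)
    except KeyError:
        raw = None
    if raw is None:
        tag = f"{key}@{chrom}"
        if tag not in warned:
            warned.add(tag)
            warnings.warn(
                f"FORMAT field {key} absent at {chrom}:{pos}; values set missing",
                stacklevel=3,
            )
        return np.full(shape, -1, dtype=np.int32)
    return _sanitize(raw, shape)


def _sanitize(raw: np.ndarray, shape) -> np.ndarray:
    arr = np.asarray(raw)
    if arr.dtype.kind == "f":
        arr = np.where(np.isnan(arr), -1, arr)
    arr = arr.astype(np.int64)
    # cyvcf2 encodes missing ints as large negatives
    arr = np.where(arr < 0, -1, arr)
    if len(shape) == 1:
        arr = arr.reshape(-1)[: shape[0]]
    else:
        arr = arr.reshape(shape[0], -1)
        if arr.shape[1] < shape[1]:
            pad = np.full((shape[0], shape[1] - arr.shape[1]), -1, dtype=np.int64)
            arr = np.hstack([arr, pad])
        arr = arr[:, : shape[1]]
    return arr.astype(np.int32)


def write_vcf(
    records: Iterable[RawVariantRecord],
    sample_ids: list[str],
    path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as VCF v4.2 with GT:AD:DP(:MM) per sample."""
    records = list(records)
    chroms: dict[str, int] = dict(contig_lengths or {})
    for r in records:
        chroms.setdefault(r.chrom, 0)
        chroms[r.chrom] = max(chroms[r.chrom], r.pos)
    has_mm = any(r.mismatches is not None for r in records)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelpop\n")
        for chrom in sorted(chroms, key=chrom_sort_key):
            fh.write(f"##contig=<ID={chrom},length={max(chroms[chrom], 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref, alt...)">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_mm:
            fh.write(
                '##FORMAT=<ID=MM,Number=1,Type=Integer,'
                'Description="Sample-specific mismatches vs reference at locus">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        fmt = "GT:AD:DP" + (":MM" if has_mm else "")
        for r in records:
            alt = ",".join(r.alts) if r.alts else "."
            cols = [r.chrom, str(r.pos), ".", r.ref, alt, ".", "PASS", ".", fmt]
            mm = r.mismatches
            for i in range(r.n_samples):
                a, b = r.gt[i]
                gts = "./." if a < 0 or b < 0 else f"{a}/{b}"
                ad = ",".join("." if x < 0 else str(x) for x in r.ad[i])
                dp = "." if r.dp[i] < 0 else str(r.dp[i])
                cell = f"{gts}:{ad}:{dp}"
                if has_mm:
                    cell += ":" + ("." if mm is None or mm[i] < 0 else str(mm[i]))
                cols.append(cell)
            fh.write("\t".join(cols) + "\n")


def records_to_matrix(
    records: Iterable[RawVariantRecord],
    sample_ids: list[str],
    sample_metadata=None,
) -> GenotypeMatrix:
    """Convert biallelic records to a dosage matrix (alt-allele copies)."""
    import pandas as pd

    records = [r for r in records if r.is_snp]
    n = len(sample_ids)
    dos = np.full((n, len(records)), MISSING, dtype=np.int8)
    rows = []
    for j, r in enumerate(records):
        called = r.called_mask()
        dos[called, j] = r.gt[called].sum(axis=1)
        rows.append((f"{r.chrom}_{r.pos}", r.chrom, r.pos))
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")
    if sample_metadata is not None:
        samples = sample_metadata.loc[sample_ids]
    else:
        samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return GenotypeMatrix(dos, samples, snps, validate=False)
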