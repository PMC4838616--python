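"""Gene annotation: GFF3 parsing and genic/intergenic SNP classification."""
from __future__ import annotations

import re
from typing import Iterable

import numpy as np
import pandas as pd

from .types import GeneAnnotation, GenotypeMatrix

_ID_RE = re.compile(r"ID=([^;]+)")


def read_gff3_genes(path, focal_ids: set[str] | None = None) -> list[GeneAnnotation]:
    """Read ``type == "gene"`` rows from a GFF3 file.

    Gene ids come from the ``ID=`` attribute (falling back to a positional
    id). ``focal_ids`` marks members of the focal gene set.
    """
    focal_ids = focal_ids or set()
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, attrs = parts[0], int(parts[3]), int(parts[4]), parts[8]
            m = _ID_RE.search(attrs)
            gid = m.group(1) if m else f"{chrom}:{start}-{end}"
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    is_focal=gid in focal_ids,
                )
            )
    return genes


def write_gff3_genes(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpanelpop\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )


def read_focal_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def genic_mask(
    chroms: np.ndarray, positions: np.ndarray, genes: Iterable[GeneAnnotation]
) -> np.ndarray:
    """True where (chrom, pos) lies within [start, end] of >= 1 gene."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    mask = np.zeros(len(positions), dtype=bool)
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        pos = positions[sel]
        starts = np.array([g.start for g in chrom_genes])
        ends = np.array([g.end for g in chrom_genes])
        # chunked containment test: genes-per-chromosome stays small
        hit = np.zeros(pos.size, dtype=bool)
        step = 4096
        for lo in range(0, pos.size, step):
            p = pos[lo : lo + step, None]
            hit[lo : lo + step] = ((p >= starts) & (p <= ends)).any(axis=1)
        mask[sel] = hit
    return mask


def annotate_snps(
    matrix: GenotypeMatrix, genes: Iterable[GeneAnnotation]
) -> GenotypeMatrix:
    """Set the per-SNP genic flag (interval containment, inclusive ends).

    SNPs on chromosomes absent from the annotation are intergenic. The
    subgenome column is (re)derived from the chromosome prefix.
    """
    out = matrix.copy()
    out.snps["genic"] = genic_mask(
        out.snps["chrom"].to_numpy(), out.snps["pos"].to_numpy(), genes
    )
    return out
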