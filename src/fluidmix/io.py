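"""File-format adapters: VCF 4.2 variant input and BED gene intervals."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import VariantRecord

log = logging.getLogger(__name__)

_GT_TYPES = {0: "hom_ref", 1: "het", 3: "hom_alt", 2: "no_call"}


def read_vcf(path: str | Path, gene_bed: str | Path | None = None) -> list[VariantRecord]:
    """Read a single-sample VCF 4.2 with GT:DP:GQ:AD fields.

    The source gene comes from INFO/GENE when present, otherwise from the
    ``gene_bed`` interval annotation (0-based half-open BED with a name
    column).  Multi-allelic or malformed rows are skipped with a logged
    count.
    """
    from cyvcf2 import VCF

    intervals = read_gene_bed(gene_bed) if gene_bed is not None else None
    records: list[VariantRecord] = []
    skipped = 0
    for v in VCF(str(path)):
        try:
            if len(v.ALT) != 1:
                skipped += 1
                continue
            dp = int(v.format("DP")[0][0]) if v.format("DP") is not None else 0
            gq = int(v.format("GQ")[0][0]) if v.format("GQ") is not None else 0
            ad = v.format("AD")
            if ad is not None:
                ref_d, alt_d = int(ad[0][0]), int(ad[0][1])
            else:
                ref_d, alt_d = dp, 0
            gene = v.INFO.get("GENE")
            if gene is None and intervals is not None:
                gene = assign_gene(intervals, str(v.CHROM), int(v.POS))
            records.append(
                VariantRecord(
                    chrom=str(v.CHROM),
                    pos=int(v.POS),
                    ref=str(v.REF),
                    alt=str(v.ALT[0]),
                    genotype=_GT_TYPES.get(int(v.gt_types[0]), "no_call"),
                    dp=ref_d + alt_d if ad is not None else dp,
                    gq=gq,
                    ad=(ref_d, alt_d),
                    gene_id=gene,
                )
            )
        except Exception:
            skipped += 1
    if skipped:
        log.warning("skipped %d malformed/multiallelic VCF rows", skipped)
    return records


def read_gene_bed(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Parse a BED file (chrom, start, end, gene_id) into per-chromosome
    interval arrays for position lookup."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"], comment="#",
    )
    out = {}
    for chrom, sub in bed.groupby("chrom", sort=False):
        out[str(chrom)] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["gene_id"].astype(str).tolist(),
        )
    return out


def assign_gene(intervals, chrom: str, pos: int) -> str | None:
    """Gene containing the 1-based position, or None (first match wins)."""
    entry = intervals.get(str(chrom))
    if entry is None:
        return None
    starts, ends, genes = entry
    hits = np.nonzero((starts <= pos - 1) & (pos - 1 < ends))[0]
    return genes[hits[0]] if hits.size else None


def write_gene_bed(gene_spans: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals (columns chrom, start, end; index gene_id) as BED."""
    bed = gene_spans[["chrom", "start", "end"]].copy()
    bed["gene_id"] = gene_spans.index
    bed.to_csv(path, sep="\t", header=False, index=False)
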