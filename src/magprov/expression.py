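"""Metatranscriptome summaries: MAPQ filtering, FPKM, bin-level fractions.

Mapped fragments are kept only when their mapping quality is strictly
greater than 2, removing ambiguously placed reads. FPKM is
``count / (length_kb) / (total_mapped_millions)`` with the denominator
taken over all genes in the table. Multi-mapping survivors contribute
once, through their primary alignment; no expectation-maximization
reassignment of multireads is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pysam

DEFAULT_MIN_MAPQ_EXCLUSIVE = 2


@dataclass
class SamRecord:
    """The slice of a SAM line this module needs."""

    qname: str
    rname: str
    mapq: int
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False


@dataclass
class ExpressionRecord:
    gene_id: str
    length: int
    count: int
    fpkm: float


@dataclass
class FilterStats:
    kept: int
    dropped_unmapped: int
    dropped_low_mapq: int


def read_sam(path: str | Path) -> list[SamRecord]:
    """Read a (headered) SAM file; only QNAME/FLAG/RNAME/MAPQ are used."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            records.append(
                SamRecord(
                    qname=seg.query_name,
                    rname=seg.reference_name or "*",
                    mapq=seg.mapping_quality,
                    is_unmapped=seg.is_unmapped,
                    is_secondary=seg.is_secondary,
                    is_supplementary=seg.is_supplementary,
                )
            )
    return records


def filter_mapq(
    alignments: Iterable[SamRecord],
    min_mapq_exclusive: int = DEFAULT_MIN_MAPQ_EXCLUSIVE,
) -> tuple[list[SamRecord], FilterStats]:
    """Keep records with MAPQ strictly greater than the threshold.

    MAPQ 3 survives the default, MAPQ 2 does not; unmapped records are
    always dropped. Counts of dropped records are reported.
    """
    kept: list[SamRecord] = []
    dropped_unmapped = dropped_low = 0
    for rec in alignments:
        if rec.is_unmapped:
            dropped_unmapped += 1
        elif rec.mapq > min_mapq_exclusive:
            kept.append(rec)
        else:
            dropped_low += 1
    return kept, FilterStats(len(kept), dropped_unmapped, dropped_low)


def fpkm_table(
    counts: Mapping[str, int], lengths: Mapping[str, int]
) -> list[ExpressionRecord]:
    """Fragments per kilobase per million mapped fragments, per gene.

    ``total_mapped`` is the sum of counts over every gene in the table,
    so rescaling all counts by a constant leaves FPKM unchanged.
    """
    missing = [g for g in counts if g not in lengths]
    if missing:
        raise ValueError(f"no length for gene(s): {sorted(missing)}")
    bad = [g for g in counts if lengths[g] <= 0]
    if bad:
        raise ValueError(f"non-positive length for gene(s): {sorted(bad)}")
    total = sum(counts.values())
    records = []
    for gene in counts:
        c, ln = counts[gene], lengths[gene]
        fpkm = c / (ln / 1000.0) / (total / 1e6) if total > 0 else math.nan
        records.append(ExpressionRecord(gene, ln, c, fpkm))
    return records


def count_by_reference(alignments: Iterable[SamRecord]) -> dict[str, int]:
    """Primary-alignment fragment counts per reference sequence."""
    counts: dict[str, int] = {}
    for rec in alignments:
        if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
            continue
        counts[rec.rname] = counts.get(rec.rname, 0) + 1
    return counts


def bin_fraction(
    alignments: Iterable[SamRecord],
    bin_gene_sets: Mapping[str, set[str]],
) -> dict[str, Optional[float]]:
    """Fraction of filtered fragments assigned to each bin.

    ``bin_gene_sets`` maps bin id -> set of reference names (genes or
    contigs) belonging to that bin; membership must not overlap.
    Fragments mapping outside every bin fall under ``"unbinned"``, so the
    fractions over bins + unbinned always sum to 1. With zero filtered
    fragments every fraction is ``None`` (undefined), never 0.
    """
    owner: dict[str, str] = {}
    for bin_id, genes in bin_gene_sets.items():
        for g in genes:
            if g in owner:
                raise ValueError(
                    f"reference {g!r} assigned to both {owner[g]!r} and {bin_id!r}"
                )
            owner[g] = bin_id
    counts = count_by_reference(alignments)
    total = sum(counts.values())
    if total == 0:
        return {b: None for b in list(bin_gene_sets) + ["unbinned"]}
    per_bin = {b: 0 for b in bin_gene_sets}
    unbinned = 0
    for rname, c in counts.items():
        b = owner.get(rname)
        if b is None:
            unbinned += c
        else:
            per_bin[b] += c
    out: dict[str, Optional[float]] = {b: c / total for b, c in per_bin.items()}
    out["unbinned"] = unbinned / total
    return out


def complex_fpkm(
    records: Iterable[ExpressionRecord], member_genes: Iterable[str]
) -> Optional[float]:
    """Average FPKM over a complex's transcribed member genes (the value
    reported for multi-subunit enzymes)."""
    members = set(member_genes)
    values = [r.fpkm for r in records if r.gene_id in members]
    if not values:
        return None
    return sum(values) / len(values)
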