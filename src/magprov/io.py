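"""Readers and writers for the plain-text formats the pipeline consumes.

Sequences travel as FASTA, gene annotations as a TSV feature table
(1-based inclusive coordinates on disk, 0-based half-open in memory),
similarity-search results as a tabular hit file, and trees as Newick.
No science happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTN")
# ambiguity codes other than N collapse to N so composition math stays defined
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")

FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "repeat_region", "other"}

HIT_TABLE_COLUMNS = [
    "query", "subject", "pident", "length", "qcov", "evalue", "bitscore", "taxon",
]

FEATURE_TABLE_COLUMNS = [
    "contig_id", "start", "end", "strand", "feature_type", "gene_label",
    "ko_id", "best_hit_taxon", "best_hit_identity", "feature_id",
]


@dataclass
class SequenceRecord:
    """A named sequence, either nucleotide (A/C/G/T/N) or protein."""

    id: str
    residues: str
    kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeBin:
    """A genome bin (MAG): a named set of contigs with optional mean depths."""

    bin_id: str
    contigs: list[SequenceRecord]
    coverage: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids in bin {self.bin_id!r}: {dupes}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, contig_id: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"no contig {contig_id!r} in bin {self.bin_id!r}")


@dataclass
class Feature:
    """An annotated interval on a contig, 0-based half-open in memory."""

    contig_id: str
    start: int
    end: int
    strand: Optional[str] = None
    feature_type: str = "CDS"
    gene_label: Optional[str] = None
    ko_id: Optional[str] = None
    best_hit_taxon: Optional[str] = None
    best_hit_identity: Optional[float] = None
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.feature_type in ("CDS", "tRNA", "rRNA") and self.strand not in ("+", "-"):
            raise ValueError(
                f"strand required for {self.feature_type} feature on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class HitRecord:
    """One row of a tabular similarity search (blastn/blastp style)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_coverage: float
    evalue: float
    bitscore: float
    subject_taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError(f"query_coverage out of range: {self.query_coverage}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _clean_nucleotide(raw: str, seq_id: str) -> str:
    seq = raw.upper()
    bad = [b for b in set(seq) if b not in NUCLEOTIDE_ALPHABET]
    if bad:
        unknown = [b for b in bad if b not in _IUPAC_AMBIGUOUS and b != "U"]
        if unknown:
            raise ValueError(f"invalid residues {sorted(unknown)} in {seq_id!r}")
        n_mapped = sum(seq.count(b) for b in bad)
        logger.info("mapped %d ambiguous bases to N in %s", n_mapped, seq_id)
        table = str.maketrans({b: "N" for b in bad})
        seq = seq.translate(table)
    return seq


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; for nucleotide input, IUPAC ambiguity codes
    other than N are mapped to N (count logged). Duplicate ids and empty
    files are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if kind == "nucleotide":
            residues = _clean_nucleotide(residues, rec.id)
        else:
            residues = residues.upper()
        records.append(SequenceRecord(rec.id, residues, kind))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_genome_bin(
    path: str | Path,
    bin_id: Optional[str] = None,
    coverage: Optional[dict[str, float]] = None,
) -> GenomeBin:
    """Load a contig FASTA as a :class:`GenomeBin` (bin_id defaults to the stem)."""
    path = Path(path)
    return GenomeBin(bin_id or path.stem, read_fasta(path, "nucleotide"), coverage)


def _parse_optional(value: str) -> Optional[str]:
    return None if value in ("", ".", "NA") else value


def read_feature_table(path: str | Path) -> list[Feature]:
    """Read the TSV feature table (1-based inclusive coords on disk).

    Columns: contig_id, start, end, strand, feature_type, gene_label, ko_id,
    best_hit_taxon, best_hit_identity, feature_id; the first five are
    required, the rest may be '.' or empty. Rows whose disk end <= start
    are rejected with their row number.
    """
    features: list[Feature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(FEATURE_TABLE_COLUMNS)] != FEATURE_TABLE_COLUMNS[: len(header)]:
            raise ValueError(f"unexpected feature-table header in {path}: {header}")
        for row_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            cols += [""] * (len(FEATURE_TABLE_COLUMNS) - len(cols))
            contig, start_s, end_s, strand, ftype = cols[:5]
            start1, end1 = int(start_s), int(end_s)
            if end1 <= start1:
                raise ValueError(
                    f"{path} row {row_no}: end ({end1}) <= start ({start1})"
                )
            strand_val = _parse_optional(strand)
            if strand_val not in (None, "+", "-"):
                raise ValueError(f"{path} row {row_no}: unknown strand {strand!r}")
            ident = _parse_optional(cols[8])
            features.append(
                Feature(
                    contig_id=contig,
                    start=start1 - 1,  # to 0-based half-open
                    end=end1,
                    strand=strand_val,
                    feature_type=ftype,
                    gene_label=_parse_optional(cols[5]),
                    ko_id=_parse_optional(cols[6]),
                    best_hit_taxon=_parse_optional(cols[7]),
                    best_hit_identity=float(ident) if ident is not None else None,
                    feature_id=_parse_optional(cols[9]),
                )
            )
    return features


def write_feature_table(features: Iterable[Feature], path: str | Path) -> None:
    """Write features back to the 1-based inclusive disk dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
        for f in features:
            ident = "" if f.best_hit_identity is None else f"{f.best_hit_identity:g}"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        str(f.start + 1),
                        str(f.end),
                        f.strand or ".",
                        f.feature_type,
                        f.gene_label or ".",
                        f.ko_id or ".",
                        f.best_hit_taxon or ".",
                        ident or ".",
                        f.feature_id or ".",
                    ]
                )
                + "\n"
            )


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a similarity hit TSV with header
    ``query subject pident length qcov evalue bitscore taxon``."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        header = fh.readline().split()
        if header != HIT_TABLE_COLUMNS:
            raise ValueError(f"unexpected hit-table header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            q, s, pid, ln, qc, ev, bs, *rest = line.split("\t")
            taxon = rest[0].strip() if rest else ""
            hits.append(
                HitRecord(
                    query_id=q,
                    subject_id=s,
                    pct_identity=float(pid),
                    aln_length=int(ln),
                    query_coverage=float(qc),
                    evalue=float(ev),
                    bitscore=float(bs),
                    subject_taxon=taxon or None,
                )
            )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:g}",
                        str(h.aln_length),
                        f"{h.query_coverage:g}",
                        f"{h.evalue:g}",
                        f"{h.bitscore:g}",
                        h.subject_taxon or "",
                    ]
                )
                + "\n"
            )


def read_newick(path: str | Path):
    """Read a single Newick tree (delegates to :mod:`magprov.phylo`)."""
    from .phylo import Tree

    return Tree.from_file(path)
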