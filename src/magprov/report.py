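"""Study-style report bundle: bin summary rows, presence matrix, per-operon
HGT verdicts, tree-congruence calls, and an AAI matrix.

The bundle is a deterministic function of the inputs and configuration;
the configuration is serialized verbatim into the report for
reproducibility, and every threshold applied is logged. Completeness and
redundancy are accepted as external annotations only — they are never
computed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import complexes as _complexes
from . import delineation as _delineation
from . import phylo as _phylo
from . import provenance as _provenance
from .composition import gc_content
from .io import (
    Feature,
    GenomeBin,
    read_fasta,
    read_feature_table,
    read_genome_bin,
    read_hit_table,
)

logger = logging.getLogger(__name__)


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class BinSummary:
    """One summary row for a genome bin (the recomputable columns)."""

    bin_id: str
    n_contigs: int
    total_length: int
    gc_percent: Optional[float]  # 1 decimal, round half up
    n_cds: Optional[int] = None
    n_rna: Optional[int] = None
    mean_coverage: Optional[float] = None
    completeness: Optional[float] = None  # passthrough only
    redundancy: Optional[float] = None  # passthrough only


def summarize_bin(
    genome: GenomeBin,
    features: Optional[list[Feature]] = None,
    extras: Optional[dict] = None,
) -> BinSummary:
    """Recompute the bin summary columns from sequence (and annotations).

    GC is the fraction of unambiguous bases that are G or C over all
    contigs, printed at one decimal with round-half-up. CDS and RNA counts
    come from the feature table when supplied; completeness/redundancy are
    emitted only if provided externally.
    """
    if not genome.contigs:
        raise ValueError(f"bin {genome.bin_id!r} has no contigs")
    gc_num = gc_den = 0
    for c in genome.contigs:
        s = c.residues
        gc = s.count("G") + s.count("C")
        gc_num += gc
        gc_den += gc + s.count("A") + s.count("T")
    gc_percent = round_half_up(100.0 * gc_num / gc_den) if gc_den else None
    n_cds = n_rna = None
    if features is not None:
        n_cds = sum(1 for f in features if f.feature_type == "CDS")
        n_rna = sum(1 for f in features if f.feature_type in ("tRNA", "rRNA"))
    mean_cov = None
    if genome.coverage:
        total = sum(len(c) for c in genome.contigs if c.id in genome.coverage)
        if total:
            mean_cov = (
                sum(
                    genome.coverage[c.id] * len(c)
                    for c in genome.contigs
                    if c.id in genome.coverage
                )
                / total
            )
    extras = extras or {}
    return BinSummary(
        bin_id=genome.bin_id,
        n_contigs=len(genome.contigs),
        total_length=genome.total_length,
        gc_percent=gc_percent,
        n_cds=n_cds,
        n_rna=n_rna,
        mean_coverage=mean_cov,
        completeness=extras.get("completeness"),
        redundancy=extras.get("redundancy"),
    )


# ---------------------------------------------------------------------------
# pipeline configuration and report schema

class BinInput(BaseModel):
    bin_id: str
    fasta: str
    features: Optional[str] = None
    extras: dict = Field(default_factory=dict)


class OperonInput(BaseModel):
    bin_id: str
    contig_id: str
    start: int
    end: int
    name: str = "operon"


class TreeInput(BaseModel):
    gene_tree: str
    genome_tree: str
    focal_clade: list[str]
    name: str = "gene_tree"


class ProteomeInput(BaseModel):
    bin_id: str
    fasta: str


class Thresholds(BaseModel):
    flag_quantile: float = 0.95
    gc_flag: float = 0.05
    discordance_flag: float = 0.5
    flank_bp: int = 10_000
    complex_threshold: float = 0.75
    rbh_min_identity: float = 30.0
    rbh_min_coverage: float = 0.7
    congruence_k: int = 2


class RunConfig(BaseModel):
    bins: list[BinInput]
    operons: list[OperonInput] = Field(default_factory=list)
    trees: list[TreeInput] = Field(default_factory=list)
    proteomes: list[ProteomeInput] = Field(default_factory=list)
    integron_hits: Optional[str] = None
    transposon_hits: Optional[str] = None
    catalog: Optional[str] = None
    thresholds: Thresholds = Field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "magprov_out"


class ReportBundle(BaseModel):
    """Schema of report.json (shipped alongside as report.schema.json)."""

    config: dict
    bins: list[dict]
    presence_matrix: Optional[dict] = None
    hgt_reports: list[dict] = Field(default_factory=list)
    congruence: list[dict] = Field(default_factory=list)
    aai: list[dict] = Field(default_factory=list)
    notices: list[str] = Field(default_factory=list)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage the configuration enables and write the bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []

    genomes: dict[str, GenomeBin] = {}
    features: dict[str, list[Feature]] = {}
    bins_rows = []
    for entry in config.bins:
        g = read_genome_bin(entry.fasta, entry.bin_id)
        genomes[entry.bin_id] = g
        feats = read_feature_table(entry.features) if entry.features else None
        if feats is not None:
            features[entry.bin_id] = feats
        bins_rows.append(asdict(summarize_bin(g, feats, entry.extras)))

    presence = None
    if features:
        defs, synonyms = _complexes.load_catalog(config.catalog)
        matrix = _complexes.presence_matrix(features, defs, synonyms)
        matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        presence = {
            "complexes": list(matrix.columns),
            "bins": {b: [bool(v) for v in row] for b, row in matrix.iterrows()},
        }
    else:
        notices.append("no feature tables supplied; presence matrix skipped")

    integron_hits = read_hit_table(config.integron_hits) if config.integron_hits else None
    transposon_hits = (
        read_hit_table(config.transposon_hits) if config.transposon_hits else None
    )
    th = config.thresholds
    hgt_reports = []
    for op in config.operons:
        genome = genomes[op.bin_id]
        feats = features.get(op.bin_id, [])
        members = [
            f
            for f in feats
            if f.contig_id == op.contig_id
            and f.feature_type == "CDS"
            and op.start <= f.start
            and f.end <= op.end
        ]
        region = _provenance.OperonRegion(
            bin_id=op.bin_id,
            contig_id=op.contig_id,
            start=op.start,
            end=op.end,
            member_genes=members,
            flank_bp=th.flank_bp,
            name=op.name,
        )
        report = _provenance.build_report(
            region,
            genome,
            feats,
            integron_hits,
            transposon_hits,
            flag_quantile=th.flag_quantile,
            gc_flag=th.gc_flag,
            discordance_flag=th.discordance_flag,
        )
        logger.info("operon %s verdict: %s", op.name, report.verdict)
        hgt_reports.append(report.to_dict())
    if hgt_reports:
        (outdir / "hgt_reports.json").write_text(
            json.dumps(hgt_reports, indent=2, sort_keys=True)
        )

    congruence_rows = []
    if config.trees:
        for t in config.trees:
            gene = _phylo.Tree.from_file(t.gene_tree)
            genome_tree = _phylo.Tree.from_file(t.genome_tree)
            call = _phylo.placement_congruence(
                gene, genome_tree, t.focal_clade, k=th.congruence_k
            )
            row = {"name": t.name, "call": call}
            if gene.leaves == genome_tree.leaves:
                row["rf"] = _phylo.rf_distance(gene, genome_tree)
            congruence_rows.append(row)
    else:
        notices.append("no trees supplied; congruence section skipped")

    aai_rows = []
    if len(config.proteomes) >= 2:
        loaded = [
            (p.bin_id, read_fasta(p.fasta, "protein")) for p in config.proteomes
        ]
        for i in range(len(loaded)):
            for j in range(i + 1, len(loaded)):
                (ida, pa), (idb, pb) = loaded[i], loaded[j]
                result = _delineation.aai_between(
                    pa, pb, ida, idb, th.rbh_min_identity, th.rbh_min_coverage
                )
                aai_rows.append(asdict(result))

    bundle = ReportBundle(
        config=config.model_dump(),
        bins=bins_rows,
        presence_matrix=presence,
        hgt_reports=hgt_reports,
        congruence=congruence_rows,
        aai=aai_rows,
        notices=notices,
    )
    (outdir / "report.json").write_text(
        json.dumps(bundle.model_dump(), indent=2, sort_keys=True)
    )
    with open(outdir / "bins.tsv", "w") as fh:
        cols = [
            "bin_id", "n_contigs", "total_length", "gc_percent",
            "n_cds", "n_rna", "mean_coverage", "completeness", "redundancy",
        ]
        fh.write("\t".join(cols) + "\n")
        for row in bins_rows:
            fh.write(
                "\t".join("" if row[c] is None else str(row[c]) for c in cols) + "\n"
            )
    return bundle


def write_schema(path: str | Path) -> None:
    """Write the JSON schema that report.json validates against."""
    Path(path).write_text(json.dumps(ReportBundle.model_json_schema(), indent=2))
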