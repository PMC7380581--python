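"""Per-operon horizontal-transfer evidence: composition, mobile-element
hallmarks in the flanks, and taxonomic discordance of the neighborhood.

Three independent lines of evidence distinguish a vertically inherited
operon from a recent acquisition:

1. compositional deviation of the operon from its host genome
   (:mod:`magprov.composition`);
2. mobile-element hallmarks — integrons, transposons, repeat regions,
   tRNAs — in a window on either side of the operon;
3. discordance between the best-hit taxonomy of the operon's genes and
   that of the flanking genes.

Any positive line yields ``hgt_suspected``. All three negative (and
computable) yields ``vertical_consistent``; otherwise the verdict is
``indeterminate``. Note that a clean screen cannot exclude ancient
transfer — composition ameliorates toward the host over time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .composition import DeviationScore, score_region
from .io import Feature, GenomeBin, HitRecord

HALLMARK_KINDS = {"integron", "transposon", "repeat", "tRNA"}

DEFAULT_FLANK_BP = 10_000
DEFAULT_DISCORDANCE_FLAG = 0.5

# Published screen thresholds. The integron screen keeps hits with at least
# 30% identity over 75% of the gene length (inclusive, no e-value cap); the
# transposon screen requires strictly more than 30% identity and 75%
# coverage at e-value strictly below 1e-5.
INTEGRON_SCREEN = dict(min_identity=30.0, min_coverage=0.75, max_evalue=None, inclusive=True)
TRANSPOSON_SCREEN = dict(min_identity=30.0, min_coverage=0.75, max_evalue=1e-5, inclusive=False)


@dataclass
class OperonRegion:
    """A candidate operon: an interval plus its member genes and flank width."""

    bin_id: str
    contig_id: str
    start: int
    end: int
    member_genes: list[Feature] = field(default_factory=list)
    flank_bp: int = DEFAULT_FLANK_BP
    name: str = "operon"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad operon interval [{self.start}, {self.end})")
        for g in self.member_genes:
            if g.start < self.start or g.end > self.end:
                raise ValueError(
                    f"member gene [{g.start}, {g.end}) outside operon "
                    f"[{self.start}, {self.end})"
                )

    def flank_windows(self, contig_length: int) -> list[tuple[int, int]]:
        """Upstream and downstream windows, truncated at contig edges."""
        if self.end > contig_length:
            raise ValueError(
                f"operon end {self.end} beyond contig length {contig_length}"
            )
        windows = []
        up = (max(0, self.start - self.flank_bp), self.start)
        down = (self.end, min(contig_length, self.end + self.flank_bp))
        for lo, hi in (up, down):
            if hi > lo:
                windows.append((lo, hi))
        return windows


@dataclass
class MobileHallmark:
    """One mobile-element signature found near an operon."""

    kind: str
    contig_id: str
    start: int
    end: int
    evidence: str

    def __post_init__(self) -> None:
        if self.kind not in HALLMARK_KINDS:
            raise ValueError(f"unknown hallmark kind {self.kind!r}")


@dataclass
class HgtReport:
    """Evidence bundle and verdict for one operon."""

    region: OperonRegion
    composition: DeviationScore
    hallmarks: list[MobileHallmark]
    neighborhood_discordance: Optional[float]
    verdict: str
    evidence: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "operon": self.region.name,
            "bin_id": self.region.bin_id,
            "contig_id": self.region.contig_id,
            "start": self.region.start,
            "end": self.region.end,
            "verdict": self.verdict,
            "composition": {
                "gc": self.composition.gc,
                "gc_delta": self.composition.gc_delta,
                "kmer_distance": self.composition.kmer_distance,
                "percentile": self.composition.percentile,
                "flagged": self.composition.flagged,
            },
            "hallmarks": [
                {"kind": h.kind, "start": h.start, "end": h.end, "evidence": h.evidence}
                for h in self.hallmarks
            ],
            "neighborhood_discordance": self.neighborhood_discordance,
            "evidence": self.evidence,
        }


def filter_hits(
    hits: Iterable[HitRecord],
    min_identity: float,
    min_coverage: float,
    max_evalue: Optional[float] = None,
    inclusive: bool = True,
) -> list[HitRecord]:
    """Apply identity/coverage/e-value thresholds, preserving input order.

    ``inclusive`` switches identity and coverage between >= (integron
    screen) and strict > (transposon screen); the e-value cut is always
    strict <.
    """
    if min_identity < 0 or min_coverage < 0 or (max_evalue is not None and max_evalue < 0):
        raise ValueError("thresholds must be non-negative")
    kept = []
    for h in hits:
        if inclusive:
            ok = h.pct_identity >= min_identity and h.query_coverage >= min_coverage
        else:
            ok = h.pct_identity > min_identity and h.query_coverage > min_coverage
        if ok and max_evalue is not None:
            ok = h.evalue < max_evalue
        if ok:
            kept.append(h)
    return kept


def _features_in_windows(
    features: Iterable[Feature], contig_id: str, windows: list[tuple[int, int]]
) -> list[Feature]:
    out = []
    for f in features:
        if f.contig_id != contig_id:
            continue
        if any(f.overlaps(lo, hi) for lo, hi in windows):
            out.append(f)
    return out


def scan_flanks(
    region: OperonRegion,
    features: Iterable[Feature],
    integron_hits: Optional[Iterable[HitRecord]] = None,
    transposon_hits: Optional[Iterable[HitRecord]] = None,
    contig_length: Optional[int] = None,
) -> list[MobileHallmark]:
    """Mobile-element hallmarks intersecting either flank window.

    tRNA and repeat hallmarks come from the feature table directly;
    integron/transposon hallmarks come from similarity hits (queried by
    ``feature_id``) after applying the respective published screens.
    Anything inside the operon itself is excluded: only the flanks count.
    """
    features = list(features)
    if contig_length is None:
        contig_length = max(
            [region.end] + [f.end for f in features if f.contig_id == region.contig_id]
        )
    windows = region.flank_windows(contig_length)
    hallmarks: list[MobileHallmark] = []
    for f in _features_in_windows(features, region.contig_id, windows):
        if f.feature_type == "tRNA":
            hallmarks.append(
                MobileHallmark("tRNA", f.contig_id, f.start, f.end,
                               f"tRNA feature {f.feature_id or f.gene_label or ''}".strip())
            )
        elif f.feature_type == "repeat_region":
            hallmarks.append(
                MobileHallmark("repeat", f.contig_id, f.start, f.end,
                               f"repeat feature {f.feature_id or ''}".strip())
            )
    by_id = {f.feature_id: f for f in features if f.feature_id}
    for kind, raw_hits, screen in (
        ("integron", integron_hits, INTEGRON_SCREEN),
        ("transposon", transposon_hits, TRANSPOSON_SCREEN),
    ):
        if raw_hits is None:
            continue
        for h in filter_hits(raw_hits, **screen):
            f = by_id.get(h.query_id)
            if f is None or f.contig_id != region.contig_id:
                continue
            if any(f.overlaps(lo, hi) for lo, hi in windows):
                hallmarks.append(
                    MobileHallmark(
                        kind, f.contig_id, f.start, f.end,
                        f"{h.query_id} vs {h.subject_id} "
                        f"({h.pct_identity:.0f}% id, cov {h.query_coverage:.2f}, "
                        f"E={h.evalue:g})",
                    )
                )
    return hallmarks


def neighborhood_discordance(
    region: OperonRegion,
    features: Iterable[Feature],
    contig_length: Optional[int] = None,
    min_labelled: int = 3,
) -> Optional[float]:
    """Fraction of labelled flank genes whose best-hit taxon differs from
    the modal taxon of the operon's member genes.

    Returns ``None`` (undefined) when fewer than ``min_labelled`` flank
    genes carry taxon labels, or when no member gene does. Modal ties are
    broken toward the higher discordance (conservative).
    """
    features = list(features)
    member_taxa = [g.best_hit_taxon for g in region.member_genes if g.best_hit_taxon]
    if not member_taxa:
        return None
    counts = Counter(member_taxa)
    top = max(counts.values())
    modal_candidates = [t for t, c in counts.items() if c == top]
    if contig_length is None:
        contig_length = max(
            [region.end] + [f.end for f in features if f.contig_id == region.contig_id]
        )
    windows = region.flank_windows(contig_length)
    member_ids = {id(g) for g in region.member_genes}
    flank_taxa = [
        f.best_hit_taxon
        for f in _features_in_windows(features, region.contig_id, windows)
        if f.feature_type == "CDS" and f.best_hit_taxon and id(f) not in member_ids
    ]
    if len(flank_taxa) < min_labelled:
        return None
    return max(
        sum(1 for t in flank_taxa if t != modal) / len(flank_taxa)
        for modal in modal_candidates
    )


def build_report(
    region: OperonRegion,
    genome: GenomeBin,
    features: Iterable[Feature],
    integron_hits: Optional[Iterable[HitRecord]] = None,
    transposon_hits: Optional[Iterable[HitRecord]] = None,
    flag_quantile: float = 0.95,
    gc_flag: float = 0.05,
    discordance_flag: float = DEFAULT_DISCORDANCE_FLAG,
    win_len: Optional[int] = None,
) -> HgtReport:
    """Assemble composition, hallmark, and discordance evidence into a verdict."""
    features = list(features)
    contig = genome.contig(region.contig_id)
    region_seq = contig.residues[region.start : region.end]
    comp = score_region(
        region_seq,
        genome,
        win_len=win_len,
        flag_quantile=flag_quantile,
        gc_flag=gc_flag,
        region_id=region.name,
    )
    hallmarks = scan_flanks(
        region, features, integron_hits, transposon_hits, contig_length=len(contig)
    )
    disc = neighborhood_discordance(region, features, contig_length=len(contig))

    evidence = [
        {
            "criterion": "composition_deviation",
            "value": {"percentile": comp.percentile, "gc_delta": comp.gc_delta},
            "threshold": {"flag_quantile": flag_quantile, "gc_flag": gc_flag},
            "triggered": comp.flagged,
        },
        {
            "criterion": "mobile_hallmarks_in_flanks",
            "value": len(hallmarks),
            "threshold": {
                "integron_screen": INTEGRON_SCREEN,
                "transposon_screen": TRANSPOSON_SCREEN,
                "flank_bp": region.flank_bp,
            },
            "triggered": bool(hallmarks),
        },
        {
            "criterion": "neighborhood_discordance",
            "value": disc,
            "threshold": {"discordance_flag": discordance_flag},
            "triggered": disc is not None and disc >= discordance_flag,
        },
    ]
    triggered = [e["triggered"] for e in evidence]
    computable = [True, True, disc is not None]
    if any(triggered):
        verdict = "hgt_suspected"
    elif all(computable):
        verdict = "vertical_consistent"
    else:
        verdict = "indeterminate"
    return HgtReport(
        region=region,
        composition=comp,
        hallmarks=hallmarks,
        neighborhood_discordance=disc,
        verdict=verdict,
        evidence=evidence,
    )
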