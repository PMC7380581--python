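"""Taxonomic novelty metrics between genomes.

Orthologs are operationalized as reciprocal best hits (RBH) between two
proteomes; the average amino acid identity (AAI) over those pairs, the
fraction of each proteome in an ortholog pair, and the 16S rRNA percent
identity are the inputs to a rank suggestion against the conventional
thresholds: AAI below ~65% against every member of the same family marks
a candidate new genus, roughly 65-95% a congeneric, and >= ~95% the same
species.

For test-scale proteomes the similarity provider is an internal affine-gap
Smith-Waterman with BLOSUM62 scoring (a fast edit-distance prefilter skips
clearly unrelated pairs); at scale, external tabular hits can be supplied
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

# global edit-distance ratio above which a protein pair cannot plausibly
# pass the 30%-identity filter; skips the expensive DP for unrelated pairs
_PREFILTER_MAX_DISTANCE_RATIO = 0.65


@dataclass
class OrthologPair:
    query_id: str
    subject_id: str
    identity: float  # percent over aligned columns
    coverage_a: float
    coverage_b: float
    score: float


@dataclass
class AaiResult:
    """AAI and ortholog sharing between one pair of proteomes."""

    bin_a: str
    bin_b: str
    n_orthologs: int
    mean_identity: Optional[float]
    shared_fraction_a: float
    shared_fraction_b: float

    @property
    def defined(self) -> bool:
        return self.mean_identity is not None


@dataclass
class Identity16sResult:
    percent: float
    columns: int
    warning: Optional[str] = None


@dataclass
class RankSuggestion:
    rank: str
    aai: float
    identity_16s: Optional[float] = None
    notes: list[str] = field(default_factory=list)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(alignment, len_a: int, len_b: int) -> tuple[float, float, float]:
    """(percent identity over aligned columns, coverage on a, coverage on b)."""
    s1, s2 = str(alignment[0]), str(alignment[1])
    columns = len(s1)
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    identity = 100.0 * matches / columns if columns else 0.0
    cov_a = sum(1 for x in s1 if x != "-") / len_a
    cov_b = sum(1 for x in s2 if x != "-") / len_b
    return identity, cov_a, cov_b


def score_proteome_pair(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
) -> dict[tuple[str, str], OrthologPair]:
    """All-vs-all local alignment stats for plausibly homologous pairs."""
    aligner = _protein_aligner()
    out: dict[tuple[str, str], OrthologPair] = {}
    for a in proteome_a:
        for b in proteome_b:
            ratio = edlib.align(a.residues, b.residues, mode="NW", task="distance")[
                "editDistance"
            ] / max(len(a), len(b))
            if ratio > _PREFILTER_MAX_DISTANCE_RATIO:
                continue
            alignment = aligner.align(a.residues, b.residues)[0]
            identity, cov_a, cov_b = _alignment_stats(alignment, len(a), len(b))
            out[(a.id, b.id)] = OrthologPair(
                a.id, b.id, identity, cov_a, cov_b, float(alignment.score)
            )
    return out


def rbh_orthologs(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    min_identity: float = 30.0,
    min_coverage: float = 0.7,
    pair_scores: Optional[dict[tuple[str, str], OrthologPair]] = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs passing identity/coverage filters.

    Best hits are taken by alignment score (ties broken on the partner id
    for determinism); each protein appears in at most one pair.
    ``pair_scores`` may carry externally computed stats keyed by
    (id_a, id_b); otherwise the internal aligner is used.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    if pair_scores is None:
        pair_scores = score_proteome_pair(proteome_a, proteome_b)
    best_ab: dict[str, OrthologPair] = {}
    best_ba: dict[str, OrthologPair] = {}
    for pair in pair_scores.values():
        cur = best_ab.get(pair.query_id)
        if cur is None or (pair.score, cur.subject_id) > (cur.score, pair.subject_id):
            best_ab[pair.query_id] = pair
        cur = best_ba.get(pair.subject_id)
        if cur is None or (pair.score, cur.query_id) > (cur.score, pair.query_id):
            best_ba[pair.subject_id] = pair
    pairs = []
    for a_id in sorted(best_ab):
        p = best_ab[a_id]
        back = best_ba.get(p.subject_id)
        if back is None or back.query_id != a_id:
            continue
        if p.identity < min_identity:
            continue
        if min(p.coverage_a, p.coverage_b) < min_coverage:
            continue
        pairs.append(p)
    return pairs


def aai(pairs: Sequence[OrthologPair], size_a: int, size_b: int,
        bin_a: str = "A", bin_b: str = "B") -> AaiResult:
    """Unweighted mean identity over RBH pairs plus shared fractions.

    Zero pairs yields an undefined (None) mean, never 0.
    """
    if size_a <= 0 or size_b <= 0:
        raise ValueError("proteome sizes must be positive")
    n = len(pairs)
    mean = sum(p.identity for p in pairs) / n if n else None
    return AaiResult(
        bin_a=bin_a,
        bin_b=bin_b,
        n_orthologs=n,
        mean_identity=mean,
        shared_fraction_a=n / size_a,
        shared_fraction_b=n / size_b,
    )


def aai_between(
    proteome_a: Sequence[SequenceRecord],
    proteome_b: Sequence[SequenceRecord],
    bin_a: str = "A",
    bin_b: str = "B",
    min_identity: float = 30.0,
    min_coverage: float = 0.7,
) -> AaiResult:
    """Convenience wrapper: RBH then AAI for two proteomes."""
    pairs = rbh_orthologs(proteome_a, proteome_b, min_identity, min_coverage)
    return aai(pairs, len(proteome_a), len(proteome_b), bin_a, bin_b)


def identity_16s(seq_a: SequenceRecord, seq_b: SequenceRecord) -> Identity16sResult:
    """Global-alignment percent identity between two 16S (fragment) genes.

    Terminal gap overhangs are excluded from the columns — fragments are
    routinely compared against full-length genes — while internal gaps
    count as non-matching columns. Inputs shorter than 200 bp yield a
    warning-tagged (unreliable) result.
    """
    for s in (seq_a, seq_b):
        if s.kind != "nucleotide":
            raise ValueError("identity_16s expects nucleotide records")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aligner.end_gap_score = 0  # overhangs are free; trimmed from columns below
    alignment = aligner.align(seq_a.residues, seq_b.residues)[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    start = 0
    while start < len(s1) and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    end = len(s1)
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    columns = end - start
    matches = sum(
        1 for i in range(start, end) if s1[i] == s2[i] and s1[i] != "-"
    )
    percent = 100.0 * matches / columns if columns else 0.0
    warning = None
    if min(len(seq_a), len(seq_b)) < 200:
        warning = "sequence shorter than 200 bp; identity estimate unreliable"
    return Identity16sResult(percent=percent, columns=columns, warning=warning)


# conventional AAI rank boundaries (percent identity)
AAI_SPECIES = 95.0
AAI_GENUS = 65.0
AAI_FAMILY = 45.0
# 16S similarity above which two genomes are conventionally congeneric
S16_GENUS = 94.5


def assign_rank(
    aai_results: AaiResult | Iterable[AaiResult],
    identity_16s_pct: Optional[float] = None,
) -> RankSuggestion:
    """Suggest a taxonomic rank relationship from AAI (and optionally 16S).

    ``aai_results`` may hold comparisons against several same-family
    reference genomes; the operative value is the maximum AAI (the closest
    reference). A candidate new genus requires AAI < 65% against all of
    them. A supplied 16S identity is annotated as a supporting or
    conflicting line of evidence, never overriding the AAI call.
    """
    if isinstance(aai_results, AaiResult):
        aai_results = [aai_results]
    results = [r for r in aai_results]
    if not results or any(not r.defined for r in results):
        raise ValueError("AAI undefined (no ortholog pairs)")
    operative = max(r.mean_identity for r in results)
    if operative >= AAI_SPECIES:
        rank = "same_species"
    elif operative >= AAI_GENUS:
        rank = "same_genus"
    elif operative >= AAI_FAMILY:
        rank = "new_genus_candidate"
    else:
        rank = "higher_rank"
    notes = []
    if identity_16s_pct is not None:
        if rank == "new_genus_candidate" and identity_16s_pct >= S16_GENUS:
            notes.append(
                f"conflict: 16S identity {identity_16s_pct:.1f}% is above the "
                f"{S16_GENUS}% congeneric threshold while AAI suggests a new genus"
            )
        elif rank == "new_genus_candidate":
            notes.append(
                f"16S identity {identity_16s_pct:.1f}% (< {S16_GENUS}%) supports "
                "genus-level novelty"
            )
    return RankSuggestion(
        rank=rank, aai=operative, identity_16s=identity_16s_pct, notes=notes
    )
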