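"""Compositional signatures: GC content, tetranucleotide spectra, and a
nonparametric screen for regions that deviate from their host genome.

Genomic islands acquired by horizontal transfer tend to retain the donor's
base composition for some evolutionary time. The screen here compares a
candidate region's canonical (strand-collapsed) 4-mer spectrum against the
spectrum of the whole genome, and ranks its Manhattan distance among the
distances of equal-length background windows tiled over the genome. A
region is flagged when it is more deviant than a quantile of the genome's
own windows, or when its GC content departs from the genome mean by more
than a fixed offset. Windows containing N are skipped, never imputed: draft
MAGs contain assembly gaps and imputation would bias the spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import GenomeBin, SequenceRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _canonical_kmers(k: int) -> tuple[str, ...]:
    """All canonical k-mers: lexicographic min of each k-mer / revcomp pair."""
    from itertools import product

    keys = set()
    for tup in product("ACGT", repeat=k):
        kmer = "".join(tup)
        keys.add(min(kmer, revcomp(kmer)))
    return tuple(sorted(keys))


CANONICAL_4MERS: tuple[str, ...] = _canonical_kmers(4)  # 136 keys
_INDEX_4 = {kmer: i for i, kmer in enumerate(CANONICAL_4MERS)}
_CANON_CACHE: dict[int, tuple[tuple[str, ...], dict[str, int]]] = {
    4: (CANONICAL_4MERS, _INDEX_4)
}


def _canon_index(k: int) -> tuple[tuple[str, ...], dict[str, int]]:
    if k not in _CANON_CACHE:
        keys = _canonical_kmers(k)
        _CANON_CACHE[k] = (keys, {kmer: i for i, kmer in enumerate(keys)})
    return _CANON_CACHE[k]


@dataclass
class CompositionProfile:
    """GC fraction plus a normalized canonical k-mer frequency vector."""

    gc: Optional[float]
    kmer_freqs: np.ndarray
    n_informative: int
    length: int
    k: int = 4

    def __post_init__(self) -> None:
        if self.n_informative > 0:
            total = float(self.kmer_freqs.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"kmer_freqs sum {total}, expected 1")
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"gc out of range: {self.gc}")


@dataclass
class DeviationScore:
    """Compositional deviation of a region relative to its host genome."""

    region_id: str
    length: int
    gc: Optional[float]
    gc_delta: float
    kmer_distance: float
    percentile: float
    flagged: bool
    n_background: int = 0
    flag_quantile: float = 0.95
    gc_flag: float = 0.05


def gc_content(seq: SequenceRecord | str) -> Optional[float]:
    """Fraction of unambiguous bases that are G or C.

    N is excluded from both numerator and denominator; an all-N sequence
    yields ``None`` (undefined), never 0.
    """
    if isinstance(seq, SequenceRecord):
        if seq.kind != "nucleotide":
            raise ValueError(f"gc_content needs a nucleotide record, got {seq.kind}")
        s = seq.residues
    else:
        s = seq.upper()
    gc = s.count("G") + s.count("C")
    informative = gc + s.count("A") + s.count("T")
    if informative == 0:
        return None
    return gc / informative


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _canon_code_table(k: int) -> np.ndarray:
    """Map each of the 4**k dense k-mer codes to its canonical-key index."""
    keys, index = _canon_index(k)
    table = np.empty(4 ** k, dtype=np.int64)
    bases = "ACGT"
    for code in range(4 ** k):
        c, kmer = code, []
        for _ in range(k):
            kmer.append(bases[c % 4])
            c //= 4
        mer = "".join(reversed(kmer))
        table[code] = index[min(mer, revcomp(mer))]
    return table


_CODE_TABLE_CACHE: dict[int, np.ndarray] = {}


def _kmer_counts(seq: str, k: int) -> tuple[np.ndarray, int]:
    """Canonical k-mer counts over sliding windows (step 1); windows with N skipped."""
    keys, _ = _canon_index(k)
    if k not in _CODE_TABLE_CACHE:
        _CODE_TABLE_CACHE[k] = _canon_code_table(k)
    table = _CODE_TABLE_CACHE[k]
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(len(keys), dtype=np.int64), 0
    kcodes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for offset in range(k):
        window = codes[offset : offset + n]
        valid &= window >= 0
        kcodes = kcodes * 4 + np.where(window >= 0, window, 0)
    informative = kcodes[valid]
    counts = np.bincount(table[informative], minlength=len(keys))
    return counts.astype(np.int64), int(valid.sum())


def kmer_profile(seq: SequenceRecord | str, k: int = 4) -> CompositionProfile:
    """Canonical k-mer spectrum of one sequence (strand-collapsed, step-1 windows)."""
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    if len(s) < k:
        raise ValueError(f"sequence length {len(s)} < k={k}")
    counts, n_inf = _kmer_counts(s, k)
    freqs = counts / n_inf if n_inf > 0 else counts.astype(float)
    return CompositionProfile(gc_content(s), freqs, n_inf, len(s), k)


def genome_profile(genome: GenomeBin, k: int = 4) -> CompositionProfile:
    """Pooled spectrum of all contigs (counts summed before normalizing,
    so junction windows between contigs never exist)."""
    _, index = _canon_index(k)
    counts = np.zeros(len(index), dtype=np.int64)
    n_inf = 0
    gc_num = 0
    gc_den = 0
    total_len = 0
    for contig in genome.contigs:
        s = contig.residues
        c, n = _kmer_counts(s, k)
        counts += c
        n_inf += n
        gc = s.count("G") + s.count("C")
        gc_num += gc
        gc_den += gc + s.count("A") + s.count("T")
        total_len += len(s)
    if n_inf == 0:
        raise ValueError(f"no informative {k}-mer windows in bin {genome.bin_id!r}")
    return CompositionProfile(
        gc_num / gc_den if gc_den else None, counts / n_inf, n_inf, total_len, k
    )


def kmer_distance(a: CompositionProfile, b: CompositionProfile) -> float:
    """Manhattan distance between two frequency vectors; lies in [0, 2]."""
    if a.k != b.k:
        raise ValueError("profiles computed with different k")
    return float(np.abs(a.kmer_freqs - b.kmer_freqs).sum())


def background_windows(
    genome: GenomeBin, win_len: int, k: int = 4
) -> list[CompositionProfile]:
    """Profiles of non-overlapping windows tiled across all contigs.

    A terminal fragment shorter than ``win_len/2`` is dropped; a longer one
    is kept as a short window.
    """
    if win_len < 1000:
        raise ValueError("win_len must be >= 1000 bp")
    if genome.total_length < win_len:
        raise ValueError(
            f"bin {genome.bin_id!r} ({genome.total_length} bp) shorter than "
            f"window length {win_len}"
        )
    profiles: list[CompositionProfile] = []
    for contig in genome.contigs:
        s = contig.residues
        n_full = len(s) // win_len
        for i in range(n_full):
            profiles.append(kmer_profile(s[i * win_len : (i + 1) * win_len], k))
        tail = len(s) - n_full * win_len
        if tail >= win_len / 2 and tail >= k:
            profiles.append(kmer_profile(s[n_full * win_len :], k))
    return profiles


def score_region(
    region_seq: SequenceRecord | str,
    genome: GenomeBin,
    win_len: Optional[int] = None,
    flag_quantile: float = 0.95,
    gc_flag: float = 0.05,
    k: int = 4,
    region_id: Optional[str] = None,
    background: Optional[Sequence[CompositionProfile]] = None,
) -> DeviationScore:
    """Score a region's compositional deviation from its host genome.

    ``percentile`` is the fraction of equal-length background windows whose
    Manhattan distance to the genome spectrum is <= the region's distance;
    the region is flagged when percentile > ``flag_quantile`` or
    ``|gc_delta|`` > ``gc_flag``. ``win_len`` defaults to the region length
    rounded to the nearest kb (minimum 1 kb).
    """
    s = region_seq.residues if isinstance(region_seq, SequenceRecord) else region_seq
    rid = region_id or (region_seq.id if isinstance(region_seq, SequenceRecord) else "region")
    if len(s) < 1000:
        raise ValueError(
            f"region {rid!r} is {len(s)} bp; the screen requires >= 1000 bp"
        )
    if win_len is None:
        win_len = max(1000, int(round(len(s) / 1000.0)) * 1000)
    gprof = genome_profile(genome, k)
    rprof = kmer_profile(s, k)
    dist = kmer_distance(rprof, gprof)
    if background is None:
        background = background_windows(genome, win_len, k)
    bg_dists = np.array([kmer_distance(w, gprof) for w in background])
    percentile = float((bg_dists <= dist).mean()) if len(bg_dists) else 1.0
    gc_delta = (rprof.gc or 0.0) - (gprof.gc or 0.0)
    flagged = percentile > flag_quantile or abs(gc_delta) > gc_flag
    return DeviationScore(
        region_id=rid,
        length=len(s),
        gc=rprof.gc,
        gc_delta=gc_delta,
        kmer_distance=dist,
        percentile=percentile,
        flagged=flagged,
        n_background=len(bg_dists),
        flag_quantile=flag_quantile,
        gc_flag=gc_flag,
    )
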