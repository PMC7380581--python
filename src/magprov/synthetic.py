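"""Seed-deterministic synthetic data with known ground truth.

Every stage of the pipeline gets a generator that emulates the
statistical structure it assumes:

* genomes drawn from an order-3 Markov chain whose per-step G+C
  probability is exactly the target, so a native operon generated from
  the same chain is genuinely indistinguishable by the tetranucleotide
  screen while the genome still carries a strong 4-mer signature;
* operons planted into a genome with native or alien (donor) composition,
  optionally with mobile-element hallmarks (transposase + tRNA) in the
  flanks;
* species/gene tree sets where one gene tree equals the species tree and
  the other has a focal clade moved by a subtree-prune-and-regraft to a
  topologically distant branch;
* proteome pairs with a controlled fraction of shared genes mutated to a
  target mean identity (uniform substitutions to a different residue, no
  indels in shared cores, so the identity target is analytic).

All generators are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import Feature, GenomeBin, HitRecord, SequenceRecord
from .phylo import Tree
from .provenance import OperonRegion

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MarkovModel:
    """Order-3 nucleotide chain; P(G or C | context) equals ``gc`` for every
    context, so the stationary GC content is exactly the target."""

    gc: float
    cum: np.ndarray  # (64, 4) cumulative probabilities over ACGT
    marginal_cum: np.ndarray  # (4,) for the first `order` bases
    order: int = 3


@dataclass
class SyntheticTruth:
    """Ground-truth record for generated fixtures."""

    seed: int
    genome: Optional[GenomeBin] = None
    planted_regions: list[tuple] = field(default_factory=list)  # (region, provenance, donor_gc)
    hallmark_positions: list[tuple[str, int, int]] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    transposon_hits: list[HitRecord] = field(default_factory=list)
    tree_truth: Optional[tuple] = None  # (species, vertical, hgt, focal leaves)
    proteome_truth: Optional[tuple] = None  # (n_genes, n_shared, target_identity)


def build_markov_model(gc: float, rng: np.random.Generator, order: int = 3) -> MarkovModel:
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    n_ctx = 4 ** order
    # per-context split of the fixed GC (and AT) mass between G/C (A/T)
    s = rng.uniform(0.2, 0.8, size=n_ctx)
    t = rng.uniform(0.2, 0.8, size=n_ctx)
    probs = np.empty((n_ctx, 4))
    probs[:, 0] = (1 - gc) * t        # A
    probs[:, 1] = gc * s              # C
    probs[:, 2] = gc * (1 - s)        # G
    probs[:, 3] = (1 - gc) * (1 - t)  # T
    marginal = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return MarkovModel(gc, probs.cumsum(axis=1), marginal.cumsum(), order)


def generate_sequence(model: MarkovModel, length: int, rng: np.random.Generator) -> str:
    """Draw one sequence from the chain."""
    if length < model.order + 1:
        raise ValueError(f"length must exceed the chain order ({model.order})")
    draws = rng.random(length)
    mcum = model.marginal_cum
    cum = model.cum
    out = np.empty(length, dtype=np.int64)
    ctx = 0
    for i in range(model.order):
        b = int(np.searchsorted(mcum, draws[i], side="right"))
        b = min(b, 3)
        out[i] = b
        ctx = (ctx * 4 + b) % 64
    cum_list = cum  # local alias; row-wise scalar comparisons below
    for i in range(model.order, length):
        r = draws[i]
        row = cum_list[ctx]
        if r < row[0]:
            b = 0
        elif r < row[1]:
            b = 1
        elif r < row[2]:
            b = 2
        else:
            b = 3
        out[i] = b
        ctx = ((ctx * 4) + b) % 64
    lookup = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lookup[out].tobytes().decode("ascii")


def _contig_lengths(total: int, n_contigs: int, rng: np.random.Generator) -> list[int]:
    weights = rng.uniform(0.5, 1.5, size=n_contigs)
    lens = np.floor(weights / weights.sum() * total).astype(int)
    lens[lens < 10] = 10
    diff = total - int(lens.sum())
    lens[0] += diff
    if lens[0] < 10:
        raise ValueError("infeasible contig length split")
    return [int(x) for x in lens]


def make_genome(
    gc: float,
    length: int,
    n_contigs: int = 1,
    seed: int = 0,
    bin_id: str = "synthetic_bin",
) -> GenomeBin:
    """Synthetic genome bin from an order-3 Markov chain.

    The measured GC converges to the target within about +-0.01 from
    ~100 kb upward. The generating model is attached as ``.markov_model``
    so native operons can later be drawn from the identical chain.
    """
    if n_contigs < 1 or length < n_contigs * 10:
        raise ValueError("infeasible genome parameters")
    rng = np.random.default_rng(seed)
    model = build_markov_model(gc, rng)
    contigs = [
        SequenceRecord(f"{bin_id}_c{i + 1}", generate_sequence(model, ln, rng))
        for i, ln in enumerate(_contig_lengths(length, n_contigs, rng))
    ]
    bin_ = GenomeBin(bin_id, contigs)
    bin_.markov_model = model
    return bin_


def plant_operon(
    genome: GenomeBin,
    donor_gc: float,
    length: int = 6000,
    provenance: str = "native",
    with_flank_hallmarks: bool = False,
    seed: int = 0,
    n_genes: int = 8,
    flank_bp: int = 10_000,
) -> tuple[GenomeBin, SyntheticTruth]:
    """Insert an operon of native or alien composition at a recorded locus.

    Native operons are drawn from the host genome's own Markov chain
    (``donor_gc`` must equal the genome's target GC); alien operons come
    from a fresh chain at ``donor_gc``. Member genes are tiled across the
    operon and labelled mtrA..; flanking context genes carry the host
    lineage as best-hit taxon, member genes the donor lineage when alien.
    ``with_flank_hallmarks`` adds a tRNA feature and a transposase gene
    (with a screen-passing similarity hit) within 5 kb of the operon.
    """
    if provenance not in ("native", "alien"):
        raise ValueError(f"provenance must be native or alien, got {provenance!r}")
    model: MarkovModel = getattr(genome, "markov_model", None)
    if model is None:
        raise ValueError("genome lacks a generating model; use make_genome()")
    if provenance == "native" and abs(donor_gc - model.gc) > 1e-12:
        raise ValueError("native operons require donor_gc == genome gc")
    rng = np.random.default_rng(seed)
    target = max(genome.contigs, key=lambda c: len(c))
    if length >= len(target):
        raise ValueError("operon longer than the longest contig")
    donor_model = model if provenance == "native" else build_markov_model(donor_gc, rng)
    operon_seq = generate_sequence(donor_model, length, rng)
    margin = min(flank_bp + 2000, (len(target) - length) // 3)
    pos = int(rng.integers(margin, len(target) - margin))
    new_seq = target.residues[:pos] + operon_seq + target.residues[pos:]
    contigs = [
        SequenceRecord(c.id, new_seq) if c.id == target.id else c
        for c in genome.contigs
    ]
    new_bin = GenomeBin(genome.bin_id, contigs, genome.coverage)
    new_bin.markov_model = model

    member_taxon = "DonorLineage" if provenance == "alien" else "HostLineage"
    gene_len = length // n_genes
    members = []
    for i in range(n_genes):
        g_start = pos + i * gene_len
        g_end = pos + (i + 1) * gene_len if i < n_genes - 1 else pos + length
        members.append(
            Feature(
                contig_id=target.id,
                start=g_start,
                end=g_end,
                strand="+",
                feature_type="CDS",
                gene_label=f"mtr{chr(ord('A') + i)}",
                best_hit_taxon=member_taxon,
                best_hit_identity=float(rng.uniform(40, 70)),
                feature_id=f"operon_g{i + 1}",
            )
        )
    region = OperonRegion(
        bin_id=genome.bin_id,
        contig_id=target.id,
        start=pos,
        end=pos + length,
        member_genes=members,
        flank_bp=flank_bp,
        name=f"planted_{provenance}_operon",
    )

    features = list(members)
    # flanking context genes with host taxonomy, both sides
    for side, base in (("up", pos - 9000), ("down", pos + length + 500)):
        for j in range(5):
            f_start = base + j * 1600
            f_end = f_start + 1200
            if f_start < 0 or f_end > len(new_seq):
                continue
            features.append(
                Feature(
                    contig_id=target.id,
                    start=f_start,
                    end=f_end,
                    strand="+",
                    feature_type="CDS",
                    gene_label=f"ctx_{side}{j + 1}",
                    best_hit_taxon="HostLineage",
                    best_hit_identity=float(rng.uniform(55, 75)),
                    feature_id=f"ctx_{side}{j + 1}",
                )
            )

    hallmark_positions: list[tuple[str, int, int]] = []
    transposon_hits: list[HitRecord] = []
    if with_flank_hallmarks:
        trna = Feature(
            contig_id=target.id,
            start=max(0, pos - 3000),
            end=max(75, pos - 3000 + 75),
            strand="+",
            feature_type="tRNA",
            gene_label="tRNA-Gly",
            feature_id="planted_trna",
        )
        tnp = Feature(
            contig_id=target.id,
            start=pos + length + 2000,
            end=pos + length + 3000,
            strand="-",
            feature_type="CDS",
            gene_label="transposase",
            feature_id="planted_tnp",
        )
        features += [trna, tnp]
        hallmark_positions += [
            ("tRNA", trna.start, trna.end),
            ("transposon", tnp.start, tnp.end),
        ]
        transposon_hits.append(
            HitRecord(
                query_id="planted_tnp",
                subject_id="IS_element_synthetic",
                pct_identity=55.0,
                aln_length=320,
                query_coverage=0.92,
                evalue=1e-30,
                bitscore=250.0,
            )
        )

    truth = SyntheticTruth(
        seed=seed,
        genome=new_bin,
        planted_regions=[(region, provenance, donor_gc)],
        hallmark_positions=hallmark_positions,
        features=features,
        transposon_hits=transposon_hits,
    )
    return new_bin, truth


# ---------------------------------------------------------------------------
# trees

def _random_join(items: list, rng: np.random.Generator):
    items = list(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = (items[i], items[j])
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return items[0]


def _nested_to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_nested_to_newick(c) for c in node) + ")"


def _substitute(node, placeholder: str, subtree):
    if isinstance(node, str):
        return subtree if node == placeholder else node
    return tuple(_substitute(c, placeholder, subtree) for c in node)


def _prune(node, placeholder: str):
    if isinstance(node, str):
        return None if node == placeholder else node
    kept = [p for p in (_prune(c, placeholder) for c in node) if p is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def _leaves_of(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    out = []
    for c in node:
        out.extend(_leaves_of(c))
    return out


def _sibling_leaves(node, placeholder: str) -> Optional[list[str]]:
    """Leaves of the sister subtree of the placeholder leaf."""
    if isinstance(node, str):
        return None
    kids = list(node)
    for i, c in enumerate(kids):
        if isinstance(c, str) and c == placeholder:
            sibs = []
            for j, other in enumerate(kids):
                if j != i:
                    sibs.extend(_leaves_of(other))
            return sibs
    for c in kids:
        found = _sibling_leaves(c, placeholder)
        if found is not None:
            return found
    return None


def _replace_leaf(node, leaf: str, subtree):
    if isinstance(node, str):
        return (leaf, subtree) if node == leaf else node
    return tuple(_replace_leaf(c, leaf, subtree) for c in node)


def _leaf_depths_from(tree: Tree, start_leaf: str) -> dict[str, int]:
    from .phylo import _orient_from_outgroup

    parent, leafsets, order = _orient_from_outgroup(tree, start_leaf)
    depths = {}
    for n in order:
        if n.is_leaf:
            d, p = 0, n
            while parent[id(p)] is not None:
                p = parent[id(p)]
                d += 1
            depths[n.name] = d
    return depths


def make_tree_set(
    n_leaves: int,
    transferred_clade_size: int,
    seed: int = 0,
) -> tuple[Tree, Tree, Tree, frozenset[str]]:
    """(species tree, vertical gene tree, HGT gene tree, focal clade leaves).

    The vertical gene tree is topology-identical to the species tree; the
    HGT tree has the focal clade pruned and regrafted onto the leaf branch
    most distant (nodally) from its original sister group.
    """
    if n_leaves < 6:
        raise ValueError("need at least 6 leaves")
    if transferred_clade_size < 2 or transferred_clade_size >= n_leaves - 2:
        raise ValueError("clade size must be in [2, n_leaves - 3]")
    rng = np.random.default_rng(seed)
    focal = [f"F{i + 1}" for i in range(transferred_clade_size)]
    others = [f"T{i + 1}" for i in range(n_leaves - transferred_clade_size)]
    placeholder = "__FOCAL__"
    backbone = _random_join(others + [placeholder], rng)
    focal_sub = _random_join(focal, rng) if len(focal) > 1 else focal[0]
    species_nested = _substitute(backbone, placeholder, focal_sub)
    species = Tree.from_newick(_nested_to_newick(species_nested) + ";")
    vertical = Tree.from_newick(_nested_to_newick(species_nested) + ";")

    pruned = _prune(backbone, placeholder)
    sib = _sibling_leaves(backbone, placeholder) or others[:1]
    pruned_tree = Tree.from_newick(_nested_to_newick(pruned) + ";")
    depths = _leaf_depths_from(pruned_tree, sib[0])
    candidates = [l for l in others if l not in sib]
    target_leaf = max(candidates, key=lambda l: (depths.get(l, 0), l))
    hgt_nested = _replace_leaf(pruned, target_leaf, focal_sub)
    hgt = Tree.from_newick(_nested_to_newick(hgt_nested) + ";")
    return species, vertical, hgt, frozenset(focal)


# ---------------------------------------------------------------------------
# proteomes

def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(_AA), size=length)
    return "".join(_AA[i] for i in idx)


def _mutate_protein(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``p`` to a different one,
    so the expected identity is exactly 1 - p."""
    mask = rng.random(len(seq)) < p
    shifts = rng.integers(1, len(_AA), size=len(seq))
    out = []
    for i, ch in enumerate(seq):
        if mask[i]:
            out.append(_AA[(_AA.index(ch) + int(shifts[i])) % len(_AA)])
        else:
            out.append(ch)
    return "".join(out)


def make_proteome_pair(
    n_genes: int,
    shared_fraction: float,
    mean_identity: float,
    seed: int = 0,
    min_len: int = 150,
    max_len: int = 300,
) -> tuple[list[SequenceRecord], list[SequenceRecord], SyntheticTruth]:
    """Two proteomes of ``n_genes`` each, sharing a controlled ortholog core.

    The shared genes in B are mutated copies of the corresponding genes in
    A with expected identity ``mean_identity`` percent; the remaining
    genes on each side are independent random proteins.
    """
    if not (0.0 < shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in (0, 1]")
    if not (20.0 <= mean_identity <= 100.0):
        raise ValueError("mean_identity must be in [20, 100]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * n_genes))
    p = 1.0 - mean_identity / 100.0
    proteome_a, proteome_b = [], []
    for i in range(n_genes):
        length = int(rng.integers(min_len, max_len + 1))
        seq_a = _random_protein(rng, length)
        proteome_a.append(SequenceRecord(f"A_{i + 1:03d}", seq_a, "protein"))
        if i < n_shared:
            proteome_b.append(
                SequenceRecord(f"B_{i + 1:03d}", _mutate_protein(seq_a, p, rng), "protein")
            )
    for i in range(n_shared, n_genes):
        length = int(rng.integers(min_len, max_len + 1))
        proteome_b.append(
            SequenceRecord(f"B_{i + 1:03d}", _random_protein(rng, length), "protein")
        )
    truth = SyntheticTruth(
        seed=seed, proteome_truth=(n_genes, n_shared, mean_identity)
    )
    return proteome_a, proteome_b, truth


def mutate_nucleotide(seq: str, rate: float, seed: int = 0) -> str:
    """Point-mutate a nucleotide sequence (always to a different base)."""
    rng = np.random.default_rng(seed)
    mask = rng.random(len(seq)) < rate
    shifts = rng.integers(1, 4, size=len(seq))
    out = []
    for i, ch in enumerate(seq):
        if mask[i] and ch in _BASES:
            out.append(_BASES[(_BASES.index(ch) + int(shifts[i])) % 4])
        else:
            out.append(ch)
    return "".join(out)
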