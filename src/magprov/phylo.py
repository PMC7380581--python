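"""Tree and alignment machinery: column trimming, subunit concatenation,
bipartition algebra, Robinson-Foulds distance, extended-majority-rule
consensus, and gene-tree vs. genome-tree placement congruence.

Split semantics are unrooted throughout (the PHYLIP convention): a
bipartition is the unordered pair of leaf sets induced by an internal
edge, represented canonically as the block NOT containing the
lexicographically smallest leaf. Consensus follows the extended majority
rule: every split occurring in more than half the input trees is kept,
then the remaining observed splits are added greedily in decreasing
frequency (ties broken on the lexicographic encoding of the split) while
they remain compatible with the accepted set. Input trees are weighted
equally. Consensus edges carry frequencies, never branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "Alignment", "TrimResult", "ConcatResult", "Tree",
    "read_alignment_fasta", "trim_columns", "concatenate",
    "bipartitions", "split_frequencies", "rf_distance",
    "rf_distance_normalized", "consensus", "placement_congruence",
]


# ---------------------------------------------------------------------------
# alignments

@dataclass
class Alignment:
    """A multiple alignment: taxon -> aligned residue string, gap '-'."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.rows)

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.rows.values())


@dataclass
class TrimResult:
    alignment: Alignment
    removed_columns: list[int]


@dataclass
class ConcatResult:
    alignment: Alignment
    offsets: list[int]  # starting column of each input block
    padded_taxa: list[str] = field(default_factory=list)


def read_alignment_fasta(path: str | Path) -> Alignment:
    from .io import read_fasta

    records = read_fasta(path, kind="protein")
    return Alignment({r.id: r.residues for r in records})


def trim_columns(aln: Alignment, max_gap_frac: float = 0.10) -> TrimResult:
    """Keep exactly the columns whose gap fraction is < ``max_gap_frac``.

    The cut is strict: a 10-taxon column with one gap (exactly 10%) is
    removed at the default. Row order is preserved; removed column indices
    are reported.
    """
    n_taxa = len(aln.rows)
    keep, removed = [], []
    for j in range(aln.n_cols):
        gaps = sum(1 for s in aln.rows.values() if s[j] == "-")
        (keep if gaps / n_taxa < max_gap_frac else removed).append(j)
    if not keep:
        raise ValueError(
            f"all {aln.n_cols} columns have >= {max_gap_frac:.0%} gaps; "
            "raise max_gap_frac"
        )
    rows = {t: "".join(s[j] for j in keep) for t, s in aln.rows.items()}
    return TrimResult(Alignment(rows), removed)


def concatenate(alns: Sequence[Alignment], pad_missing: bool = False) -> ConcatResult:
    """Concatenate subunit alignments into one supermatrix.

    Taxon sets must agree unless ``pad_missing`` is set, in which case a
    taxon absent from a block gets an all-gap row there (reported).
    """
    if not alns:
        raise ValueError("nothing to concatenate")
    all_taxa = sorted(set().union(*(a.taxa for a in alns)))
    padded: set[str] = set()
    for a in alns:
        missing = set(all_taxa) - a.taxa
        if missing and not pad_missing:
            raise ValueError(
                f"taxa {sorted(missing)} missing from a block; "
                "set pad_missing=True to fill with gaps"
            )
        padded |= missing
    # preserve row order of the first block, then any extras alphabetically
    order = list(alns[0].rows)
    order += [t for t in all_taxa if t not in alns[0].rows]
    offsets, pos = [], 0
    for a in alns:
        offsets.append(pos)
        pos += a.n_cols
    rows = {
        t: "".join(a.rows.get(t, "-" * a.n_cols) for a in alns) for t in order
    }
    return ConcatResult(Alignment(rows), offsets, sorted(padded))


# ---------------------------------------------------------------------------
# trees

class _Node:
    __slots__ = ("children", "name", "support", "length")

    def __init__(self, name=None, children=None, support=None, length=None):
        self.name = name
        self.children: list[_Node] = children or []
        self.support = support
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A leaf-labelled topology (rooted nesting retained, unrooted semantics
    for split work); polytomies allowed, branch lengths/support optional."""

    def __init__(self, root: _Node):
        self.root = root
        labels = [n.name for n in self._iter_leaves()]
        if any(l is None or l == "" for l in labels):
            raise ValueError("unlabelled leaf in tree")
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self.leaves: frozenset[str] = frozenset(labels)

    # -- construction

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # malformed newick, duplicate taxa, ...
            if "duplicate" in str(exc).lower() or "occurrences" in str(exc).lower():
                raise ValueError(f"duplicate leaf labels in newick: {exc}") from exc
            raise ValueError(f"cannot parse newick: {exc}") from exc
        return cls(cls._convert(dt.seed_node))

    @classmethod
    def from_file(cls, path: str | Path) -> "Tree":
        return cls.from_newick(Path(path).read_text())

    @staticmethod
    def _convert(dnode) -> _Node:
        if dnode.is_leaf():
            return _Node(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                pass
        return _Node(
            children=[Tree._convert(c) for c in dnode.child_nodes()],
            support=support,
            length=dnode.edge.length,
        )

    # -- traversal

    def _iter_leaves(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                yield n
            else:
                stack.extend(n.children)

    def _postorder(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    # -- output

    def to_newick(self) -> str:
        def fmt(n: _Node) -> str:
            if n.is_leaf:
                body = n.name
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.support is not None:
                    body += f"{n.support:g}"
            if n.length is not None:
                body += f":{n.length:g}"
            return body

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"Tree({self.to_newick()})"


def _leafsets(tree: Tree) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for n in tree._postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset([n.name])
        else:
            sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
    return sets


def _canonical(block: frozenset[str], leaves: frozenset[str], ref: str) -> frozenset[str]:
    return leaves - block if ref in block else block


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial splits of the tree under unrooted interpretation.

    Each split is the block not containing the lexicographically smallest
    leaf. Trees with fewer than 4 leaves have no nontrivial splits.
    """
    leaves = tree.leaves
    if len(leaves) < 4:
        return set()
    ref = min(leaves)
    sets = _leafsets(tree)
    splits: set[frozenset[str]] = set()
    for n in tree._postorder():
        if n is tree.root or n.is_leaf:
            continue
        block = _canonical(sets[id(n)], leaves, ref)
        if 2 <= len(block) <= len(leaves) - 2:
            splits.add(block)
    return splits


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two split sets. Requires identical leaf sets."""
    if t1.leaves != t2.leaves:
        only1 = sorted(t1.leaves - t2.leaves)
        only2 = sorted(t2.leaves - t1.leaves)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def rf_distance_normalized(t1: Tree, t2: Tree) -> float:
    """RF divided by its maximum over fully resolved trees, 2*(n-3)."""
    n = len(t1.leaves)
    denom = 2 * (n - 3)
    if denom <= 0:
        return 0.0
    return rf_distance(t1, t2) / denom


def split_frequencies(trees: Sequence[Tree]) -> dict[frozenset[str], float]:
    """Fraction of input trees containing each observed split."""
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    leaves = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != leaves:
            raise ValueError("trees have different leaf sets")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in bipartitions(t):
            counts[s] = counts.get(s, 0) + 1
    return {s: c / len(trees) for s, c in counts.items()}


def splits_compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    """Compatibility of two canonical splits (both exclude the reference
    leaf): they coexist in one tree iff nested or disjoint."""
    return a <= b or b <= a or not (a & b)


def _split_sort_key(block: frozenset[str], leaves: frozenset[str]) -> tuple:
    # lexicographic encoding: the side containing the smallest leaf
    return tuple(sorted(leaves - block))


def select_consensus_splits(
    freqs: Mapping[frozenset[str], float],
    leaves: frozenset[str],
    rule: str = "extended_majority",
) -> dict[frozenset[str], float]:
    """Apply the (extended) majority rule to a split frequency table."""
    if rule not in ("majority", "extended_majority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    accepted = {s: f for s, f in freqs.items() if f > 0.5}
    if rule == "extended_majority":
        remaining = sorted(
            (s for s, f in freqs.items() if f <= 0.5),
            key=lambda s: (-freqs[s], _split_sort_key(s, leaves)),
        )
        for s in remaining:
            if all(splits_compatible(s, a) for a in accepted):
                accepted[s] = freqs[s]
    return accepted


def tree_from_splits(
    splits: Mapping[frozenset[str], float], leaves: frozenset[str]
) -> Tree:
    """Build the (unique) tree whose nontrivial splits are the given
    compatible set; edges carry the supplied frequencies as support."""
    blocks = sorted(splits, key=lambda b: (-len(b), _split_sort_key(b, leaves)))
    root = _Node()
    nodes: list[tuple[frozenset[str], _Node]] = []
    for b in blocks:
        node = _Node(support=splits[b])
        # parent = smallest strict superset already placed, else the root
        best = None
        for pb, pn in nodes:
            if b < pb and (best is None or len(pb) < len(best[0])):
                best = (pb, pn)
        (best[1] if best else root).children.append(node)
        nodes.append((b, node))
    for leaf in sorted(leaves):
        best = None
        for pb, pn in nodes:
            if leaf in pb and (best is None or len(pb) < len(best[0])):
                best = (pb, pn)
        (best[1] if best else root).children.append(_Node(name=leaf))
    return Tree(root)


def consensus(trees: Sequence[Tree], rule: str = "extended_majority") -> Tree:
    """Consensus of equally weighted input trees (>= 2, same leaf set).

    ``extended_majority`` reproduces the PHYLIP CONSENSE behaviour with a
    deterministic tie-break; ``majority`` keeps strictly >50% splits only.
    Consensus edges carry split frequencies as support values.
    """
    freqs = split_frequencies(trees)
    leaves = trees[0].leaves
    accepted = select_consensus_splits(freqs, leaves, rule)
    return tree_from_splits(accepted, leaves)


# ---------------------------------------------------------------------------
# placement congruence

def _orient_from_outgroup(tree: Tree, outgroup: str):
    """Parent map and descendant leaf sets with the tree re-rooted at the
    given outgroup leaf (adjacency walk; original nesting irrelevant)."""
    adj: dict[int, list[_Node]] = {}
    parent0: dict[int, Optional[_Node]] = {id(tree.root): None}
    stack = [tree.root]
    nodes = []
    while stack:
        n = stack.pop()
        nodes.append(n)
        for c in n.children:
            parent0[id(c)] = n
            stack.append(c)
    for n in nodes:
        neigh = list(n.children)
        p = parent0[id(n)]
        if p is not None:
            neigh.append(p)
        adj[id(n)] = neigh
    start = next(n for n in nodes if n.is_leaf and n.name == outgroup)
    parent: dict[int, Optional[_Node]] = {id(start): None}
    order = [start]
    stack = [start]
    visited = {id(start)}
    while stack:
        n = stack.pop()
        for m in adj[id(n)]:
            if id(m) in visited:
                continue
            visited.add(id(m))
            parent[id(m)] = n
            order.append(m)
            stack.append(m)
    leafsets: dict[int, set[str]] = {id(n): set() for n in order}
    for n in reversed(order):
        if n.is_leaf:
            leafsets[id(n)].add(n.name)
        p = parent[id(n)]
        if p is not None:
            leafsets[id(p)] |= leafsets[id(n)]
    return parent, leafsets, order


def _sister_sequence(
    tree: Tree,
    focal: frozenset[str],
    outgroup: str,
    lineage_map: Mapping[str, str],
    k: int,
) -> Optional[list[frozenset[str]]]:
    parent, leafsets, order = _orient_from_outgroup(tree, outgroup)
    focal_node = None
    for n in order:
        if leafsets[id(n)] == set(focal):
            focal_node = n
            break
    if focal_node is None:
        return None  # not monophyletic in this orientation => not a clade
    seq: list[frozenset[str]] = []
    node = focal_node
    while len(seq) < k:
        p = parent[id(node)]
        if p is None:
            break
        sisters = leafsets[id(p)] - leafsets[id(node)]
        seq.append(frozenset(lineage_map.get(l, l) for l in sisters))
        node = p
    return seq


def placement_congruence(
    gene_tree: Tree,
    genome_tree: Tree,
    focal_clade: Iterable[str],
    lineage_map: Optional[Mapping[str, str]] = None,
    k: int = 2,
) -> str:
    """Compare where a focal clade sits in a gene tree vs. the genome tree.

    Walking rootward from the focal clade, the sets of sister lineages
    encountered (after mapping leaves through ``lineage_map``) must match
    between the trees for the first ``k`` steps to call ``congruent``. A
    focal clade that is not monophyletic in either tree is
    ``unresolvable``. Both trees are oriented at the same deterministic
    outgroup (the smallest non-focal leaf shared by both).
    """
    focal = frozenset(focal_clade)
    if not focal:
        raise ValueError("empty focal clade")
    for name, t in (("gene", gene_tree), ("genome", genome_tree)):
        missing = focal - t.leaves
        if missing:
            raise ValueError(f"focal leaves absent from {name} tree: {sorted(missing)}")
    lineage_map = dict(lineage_map or {})
    shared_outgroups = (gene_tree.leaves & genome_tree.leaves) - focal
    if not shared_outgroups:
        raise ValueError("no shared non-focal leaf to orient the trees")
    outgroup = min(shared_outgroups)
    seq_gene = _sister_sequence(gene_tree, focal, outgroup, lineage_map, k)
    seq_genome = _sister_sequence(genome_tree, focal, outgroup, lineage_map, k)
    if seq_gene is None or seq_genome is None:
        return "unresolvable"
    return "congruent" if seq_gene[:k] == seq_genome[:k] else "incongruent"
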