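from itertools import combinations

import dendropy
import pytest

from magprov.phylo import Tree


def dendropy_splits(newick: str) -> set[frozenset[str]]:
    """Independent split extraction: dendropy bipartition encoding, converted
    to the canonical block-not-containing-the-smallest-leaf form."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    tns = tree.taxon_namespace
    leaves = frozenset(t.label for t in tns)
    ref = min(leaves)
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        mask = edge.bipartition.leafset_bitmask
        block = frozenset(
            t.label for i, t in enumerate(tns) if mask & (1 << i)
        )
        if ref in block:
            block = leaves - block
        if 2 <= len(block) <= len(leaves) - 2:
            splits.add(block)
    return splits


def oracle_consensus_splits(
    split_sets: list[set[frozenset[str]]], leaves: frozenset[str]
) -> dict[frozenset[str], float]:
    """Brute-force extended-majority consensus: enumerate every possible
    nontrivial split of the leaf set, count its occurrences, apply the rule."""
    ref = min(leaves)
    others = sorted(leaves - {ref})
    freqs = {}
    for r in range(2, len(leaves) - 1):
        for comb in combinations(others, r):
            s = frozenset(comb)
            c = sum(s in ss for ss in split_sets)
            if c:
                freqs[s] = c / len(split_sets)
    accepted = {s: f for s, f in freqs.items() if f > 0.5}

    def compatible(a, b):
        return a <= b or b <= a or not (a & b)

    rest = sorted(
        (s for s, f in freqs.items() if f <= 0.5),
        key=lambda s: (-freqs[s], tuple(sorted(leaves - s))),
    )
    for s in rest:
        if all(compatible(s, a) for a in accepted):
            accepted[s] = freqs[s]
    return accepted


def _all_resolved_trees(leaves: list[str]) -> list:
    """All unrooted fully resolved topologies on the given leaves, as nested
    tuples, built by inserting each leaf into every edge (stepwise addition)."""
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    # unrooted base: star of the first three leaves
    trees = [(leaves[0], leaves[1], leaves[2])]
    for leaf in leaves[3:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_on_every_edge(t, leaf))
        trees = nxt
    return trees


def _insert_on_every_edge(tree, leaf):
    out = []

    def rec(node, rebuild):
        # attach on the edge above each child of this (internal) node
        for i, child in enumerate(node):
            joined = tuple(
                (leaf, child) if j == i else c for j, c in enumerate(node)
            )
            out.append(rebuild(joined))
            if not isinstance(child, str):
                rec(child, lambda sub, i=i, node=node, rebuild=rebuild: rebuild(
                    tuple(sub if j == i else c for j, c in enumerate(node))
                ))

    rec(tree, lambda x: x)
    return out


def nested_to_tree(nested) -> Tree:
    def to_newick(n):
        if isinstance(n, str):
            return n
        return "(" + ",".join(to_newick(c) for c in n) + ")"

    return Tree.from_newick(to_newick(nested) + ";")


@pytest.fixture(scope="session")
def resolved_trees_5():
    return [nested_to_tree(t) for t in _all_resolved_trees(list("ABCDE"))]


@pytest.fixture(scope="session")
def resolved_trees_6():
    return [nested_to_tree(t) for t in _all_resolved_trees(list("ABCDEF"))]
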