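"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from domrep.genome_orf import reverse_complement
from domrep.phylo_parsimony import Phylogeny, PhyloNode, parse_newick

STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str, min_aa: int, mode: str) -> set[tuple[str, int, int, int]]:
    """Exhaustive per-position ORF scan, independent of the implementation.

    Tests every position of both strands for an ATG, walks codon by codon to
    the first in-frame stop, and reports (strand, frame, start, end) in
    forward-strand 0-based half-open coordinates including the stop codon.
    """
    n = len(seq)
    found: set[tuple[str, int, int, int]] = set()
    for strand, working in (("+", seq.upper()), ("-", reverse_complement(seq))):
        for i in range(n - 2):
            if working[i : i + 3] != "ATG":
                continue
            if mode == "maximal":
                # not maximal if an in-frame ATG precedes i with no stop between
                j, shadowed = i - 3, False
                while j >= 0:
                    codon = working[j : j + 3]
                    if codon in STOPS:
                        break
                    if codon == "ATG":
                        shadowed = True
                        break
                    j -= 3
                if shadowed:
                    continue
            j = i + 3
            while j + 3 <= n and working[j : j + 3] not in STOPS:
                j += 3
            if j + 3 > n:
                continue  # ran off the end without a stop
            if (j - i) // 3 < min_aa:
                continue
            if strand == "+":
                found.add(("+", i % 3, i, j + 3))
            else:
                found.add(("-", i % 3, n - (j + 3), n - i))
    return found


def tree_shapes(n: int) -> list:
    """All rooted binary tree shapes with n leaves, as nested tuples."""
    if n == 1:
        return [None]
    shapes = []
    for i in range(1, n // 2 + 1):
        left_shapes = tree_shapes(i)
        right_shapes = tree_shapes(n - i)
        for li, left in enumerate(left_shapes):
            for ri, right in enumerate(right_shapes):
                if i == n - i and ri < li:
                    continue  # unordered pair
                shapes.append((left, right))
    return shapes


def shape_to_tree(shape) -> Phylogeny:
    """Materialize a shape as a Phylogeny with leaves L1..Ln (left to right)."""
    counter = [0]

    def build(s) -> PhyloNode:
        if s is None:
            counter[0] += 1
            return PhyloNode(label=f"L{counter[0]}")
        node = PhyloNode(label="")
        node.add_child(build(s[0]))
        node.add_child(build(s[1]))
        return node

    root = build(shape)
    k = [2]

    def name(node: PhyloNode) -> None:
        if not node.is_leaf:
            node.label = f"n{k[0]}"
            k[0] += 1
            for c in node.children:
                name(c)

    name(root)
    return Phylogeny(root)


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> Phylogeny:
    """Random rooted binary topology by sequential leaf attachment."""
    leaves = [PhyloNode(label=f"L{i + 1}") for i in range(n_leaves)]
    root = PhyloNode(label="")
    root.add_child(leaves[0])
    root.add_child(leaves[1])
    edges = [leaves[0], leaves[1]]
    for leaf in leaves[2:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        inner = PhyloNode(label="")
        parent.children[parent.children.index(target)] = inner
        inner.parent = parent
        inner.add_child(target)
        inner.add_child(leaf)
        edges.extend([inner, leaf])
    k = [2]

    def name(node: PhyloNode) -> None:
        if not node.is_leaf:
            node.label = f"n{k[0]}"
            k[0] += 1
            for c in node.children:
                name(c)

    name(root)
    return Phylogeny(root)


@pytest.fixture
def balanced4() -> Phylogeny:
    return parse_newick("((A,B),(C,D));")
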