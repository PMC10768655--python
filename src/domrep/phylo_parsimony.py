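"""Rooted trees and linear (Wagner) parsimony for integer domain counts.

Domain copy counts are meristic, additive characters: changing a count from
i to j along a branch costs |i - j| unit events. For each domain column the
minimum total cost over all ancestral assignments is found either by the
Farris interval down-pass (binary trees) or by a Sankoff-style dynamic
programme with the linear cost matrix (any multifurcating tree); a single
canonical most-parsimonious assignment is then extracted with an explicit,
configurable tie-break policy. Branch lengths are carried for plotting and
simulation but never influence parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, TextIO

import dendropy
import numpy as np

__all__ = [
    "PhyloNode",
    "Phylogeny",
    "StateInterval",
    "AncestralAssignment",
    "parse_newick",
    "write_newick",
    "wagner_down_pass",
    "sankoff_linear",
    "assign_states",
    "reconstruct_character",
    "brute_force_parsimony",
]


@dataclass
class PhyloNode:
    label: str
    branch_length: float | None = None
    children: list["PhyloNode"] = field(default_factory=list)
    parent: "PhyloNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """A rooted, labeled, possibly multifurcating tree.

    Every node carries a unique label (leaves: taxon names; internal nodes:
    auto-assigned ``n2``, ``n3``, ... in preorder when unnamed in the source
    newick). Branch lengths are optional, per non-root node.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        labels = [n.label for n in self.preorder()]
        leaf_labels = [n.label for n in self.leaves()]
        if len(set(leaf_labels)) != len(leaf_labels):
            dup = sorted({x for x in leaf_labels if leaf_labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate node labels: {dup}")
        self._by_label = {n.label: n for n in self.preorder()}

    def preorder(self) -> list[PhyloNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[PhyloNode]:
        return list(reversed([n for n in self._postorder_rev()]))

    def _postorder_rev(self) -> Iterable[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def branches(self) -> list[tuple[PhyloNode, PhyloNode]]:
        """(parent, child) pairs in preorder of the child."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    def node(self, label: str) -> PhyloNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labeled {label!r} in tree") from None

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def __contains__(self, label: str) -> bool:
        return label in self._by_label


@dataclass(frozen=True)
class StateInterval:
    """Farris interval [lo, hi] of equally parsimonious states."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("interval lo must be <= hi")

    def intersects(self, other: "StateInterval") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass
class AncestralAssignment:
    """One most-parsimonious assignment of counts to every node."""

    domain: str
    state: dict[str, int]
    cost: int


def _autoname(root: PhyloNode) -> None:
    used = set()
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    for node in order:
        if node.label:
            used.add(node.label)
    k = 2
    for node in order:
        if not node.is_leaf and not node.label:
            while f"n{k}" in used:
                k += 1
            node.label = f"n{k}"
            used.add(node.label)
            k += 1


def parse_newick(s: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Branch lengths and internal labels are preserved; unlabeled internal
    nodes are auto-named n2, n3, ... in preorder. Raises ``ValueError`` on
    malformed newick, empty input, or duplicate leaf labels.
    """
    if not s or not s.strip():
        raise ValueError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=s,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from None

    def convert(dnode: dendropy.Node) -> PhyloNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label or ""
        node = PhyloNode(label=label, branch_length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    _autoname(root)
    return Phylogeny(root)


def _fmt_length(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(x)


def write_newick(t: Phylogeny) -> str:
    """Serialize preserving labels, child order, and branch lengths."""

    def render(node: PhyloNode) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")" + node.label
        if node.branch_length is not None:
            s += f":{_fmt_length(node.branch_length)}"
        return s

    return render(t.root) + ";"


def _check_leaf_states(t: Phylogeny, x: Mapping[str, int]) -> None:
    missing = [leaf.label for leaf in t.leaves() if leaf.label not in x]
    if missing:
        raise ValueError(f"missing leaf states for: {missing}")
    bad = {k: v for k, v in x.items() if k in t and int(v) < 0}
    if bad:
        raise ValueError(f"negative leaf states: {bad}")


def wagner_down_pass(
    t: Phylogeny, x: Mapping[str, int]
) -> tuple[dict[str, StateInterval], int]:
    """Farris interval down-pass on a strictly binary tree.

    Leaf intervals are [x, x]; an internal interval is the intersection of
    its children's intervals when non-empty, otherwise the gap between them
    with the parsimony cost incremented by the gap width. The returned cost
    is the minimum total |change| over all ancestral assignments.
    """
    _check_leaf_states(t, x)
    intervals: dict[str, StateInterval] = {}
    cost = 0
    for node in t.postorder():
        if node.is_leaf:
            s = int(x[node.label])
            intervals[node.label] = StateInterval(s, s)
        else:
            if len(node.children) != 2:
                raise ValueError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "wagner_down_pass requires a binary tree (use sankoff_linear)"
                )
            a = intervals[node.children[0].label]
            b = intervals[node.children[1].label]
            if a.intersects(b):
                intervals[node.label] = StateInterval(max(a.lo, b.lo), min(a.hi, b.hi))
            else:
                lo, hi = min(a.hi, b.hi), max(a.lo, b.lo)
                intervals[node.label] = StateInterval(lo, hi)
                cost += hi - lo
    return intervals, cost


def sankoff_linear(
    t: Phylogeny, x: Mapping[str, int], max_state: int | None = None
) -> tuple[dict[str, np.ndarray], int]:
    """Linear-cost Sankoff dynamic programme; multifurcations allowed.

    ``vec[node][s]`` is the minimum cost of the subtree rooted at the node
    given the node holds state ``s``; the overall parsimony cost is the
    minimum of the root vector. States run 0..max_state, which defaults to
    the maximum observed leaf state (provably sufficient for linear cost).
    """
    _check_leaf_states(t, x)
    leaf_states = {leaf.label: int(x[leaf.label]) for leaf in t.leaves()}
    observed_max = max(leaf_states.values(), default=0)
    if max_state is None:
        max_state = observed_max
    if max_state < observed_max:
        raise ValueError(f"max_state {max_state} is below max leaf state {observed_max}")
    n_states = max_state + 1
    dist = np.abs(np.subtract.outer(np.arange(n_states), np.arange(n_states)))
    vecs: dict[str, np.ndarray] = {}
    for node in t.postorder():
        if node.is_leaf:
            v = np.full(n_states, np.inf)
            v[leaf_states[node.label]] = 0.0
        else:
            v = np.zeros(n_states)
            for child in node.children:
                v += (vecs[child.label][None, :] + dist).min(axis=1)
        vecs[node.label] = v
    return vecs, int(vecs[t.root.label].min())


def assign_states(
    t: Phylogeny,
    down: Mapping[str, np.ndarray],
    policy: str = "root-smallest",
    domain: str = "",
) -> AncestralAssignment:
    """Extract one canonical most-parsimonious assignment from DP vectors.

    The root takes the smallest (policy ``root-smallest``, default) or
    largest (``root-largest``) state in its optimal set; every other node
    takes the state in its conditional optimal set closest to its parent's
    assigned state, ties broken toward the smaller state. The realized
    assignment achieves the DP minimum exactly.
    """
    if policy not in ("root-smallest", "root-largest"):
        raise ValueError(f"unknown tie-break policy {policy!r}")
    root_vec = np.asarray(down[t.root.label])
    best = root_vec.min()
    optimal = np.flatnonzero(root_vec == best)
    root_state = int(optimal[0] if policy == "root-smallest" else optimal[-1])
    state: dict[str, int] = {t.root.label: root_state}
    for node in t.preorder():
        if node.parent is None:
            continue
        p = state[node.parent.label]
        vec = np.asarray(down[node.label])
        totals = vec + np.abs(np.arange(len(vec)) - p)
        m = totals.min()
        candidates = np.flatnonzero(totals == m)
        state[node.label] = int(min(candidates, key=lambda s: (abs(int(s) - p), int(s))))
    cost = sum(abs(state[c.label] - state[p.label]) for p, c in t.branches())
    return AncestralAssignment(domain=domain, state=state, cost=cost)


def reconstruct_character(
    t: Phylogeny,
    x: Mapping[str, int],
    domain: str = "",
    policy: str = "root-smallest",
) -> AncestralAssignment:
    """Convenience wrapper: Sankoff DP + canonical assignment for one domain."""
    vecs, _ = sankoff_linear(t, x)
    return assign_states(t, vecs, policy=policy, domain=domain)


def brute_force_parsimony(
    t: Phylogeny, x: Mapping[str, int], max_state: int | None = None
) -> int:
    """Exhaustive-enumeration parsimony cost; test oracle for small trees."""
    _check_leaf_states(t, x)
    internal = [n for n in t.preorder() if not n.is_leaf]
    if len(internal) > 8:
        raise ValueError(f"{len(internal)} internal nodes: too large for brute force")
    leaf_states = {leaf.label: int(x[leaf.label]) for leaf in t.leaves()}
    observed_max = max(leaf_states.values(), default=0)
    if max_state is None:
        max_state = observed_max
    if max_state < observed_max:
        raise ValueError(f"max_state {max_state} is below max leaf state {observed_max}")
    branches = t.branches()
    best = None
    for combo in product(range(max_state + 1), repeat=len(internal)):
        state = dict(leaf_states)
        for node, s in zip(internal, combo):
            state[node.label] = s
        cost = sum(abs(state[c.label] - state[p.label]) for p, c in branches)
        if best is None or cost < best:
            best = cost
    return int(best)


def write_asr_report(
    assignments: Iterable[AncestralAssignment], stream: TextIO
) -> None:
    """TSV report: domain, node, reconstructed state, per-domain cost."""
    stream.write("domain\tnode\tstate\tcost\n")
    for a in assignments:
        for node, s in a.state.items():
            stream.write(f"{a.domain}\t{node}\t{s}\t{a.cost}\n")


def read_tree_file(path: str) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())
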