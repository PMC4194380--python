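"""Rooted phylogenetic trees: Newick I/O, bipartitions, tree distances, node ages.

The tree is the coordinate system for all downstream character analysis.
Trees are stored rooted with child order preserved from the input, but the
comparison metrics (Robinson--Foulds, branch score) follow the standard
convention of treating trees as unrooted: a degree-2 root contributes a
single unrooted edge, never two.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterator

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "NodeAges",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "robinson_foulds",
    "branch_score",
    "assign_node_ages",
]


class NewickParseError(ValueError):
    """Raised for syntactically invalid Newick input."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class Node:
    """A tree node. ``length`` is the branch length to the parent.

    The root carries ``length = None``; every other node has a float
    length (missing lengths in the input default to 0.0).
    """

    __slots__ = ("name", "length", "parent", "children")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind} len={self.length}>"


class PhyloTree:
    """Rooted tree with branch lengths and uniquely labeled tips."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        if self.root.parent is not None:
            raise TreeValidationError("root must have no parent")
        seen: set[str] = set()
        for node in self.preorder():
            if node is not self.root and node.parent is None:
                raise TreeValidationError(f"non-root node {node.name!r} has no parent")
            if node.is_tip:
                if not node.name:
                    raise TreeValidationError("tip with empty label")
                if node.name in seen:
                    raise TreeValidationError(f"duplicate tip label {node.name!r}")
                seen.add(node.name)
            if node is not self.root and node.length is None:
                node.length = 0.0

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.name for n in self.tips()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return write_newick(self) == write_newick(other)

    def __hash__(self) -> int:  # pragma: no cover
        return hash(write_newick(self))


@dataclass
class NodeAges:
    """Node ages on the scaled clock: root at ``root_age``, extant tips at 0."""

    ages: dict[Node, float]
    root_age: float = 100.0

    def __getitem__(self, node: Node) -> float:
        return self.ages[node]

    def by_name(self) -> dict[str, float]:
        """Ages keyed by node name (unnamed internal nodes are skipped)."""
        return {n.name: a for n, a in self.ages.items() if n.name}


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Supports quoted labels, missing branch lengths (defaulting to 0.0 with a
    warning) and multifurcations. Child order is preserved.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick string must end in ';' (offset {len(stripped)})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    missing = 0

    def convert(dnode) -> Node:
        nonlocal missing
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            name = dnode.label
        length = dnode.edge.length
        node = Node(name=name, length=length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        if dnode.parent_node is not None and length is None:
            missing += 1
            node.length = 0.0
        return node

    root = convert(dtree.seed_node)
    root.length = dtree.seed_node.edge.length  # usually None
    if missing:
        logger.warning("%d branch length(s) missing; defaulting to 0.0", missing)
    return PhyloTree(root)


_NEEDS_QUOTES = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(name: str) -> str:
    if name == "" or _NEEDS_QUOTES.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(length: float) -> str:
    # repr gives the shortest decimal that round-trips the float exactly
    return repr(float(length))


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; round-trips through :func:`parse_newick`."""

    def serialize(node: Node) -> str:
        if node.is_tip:
            out = _format_label(node.name or "")
        else:
            out = "(" + ",".join(serialize(c) for c in node.children) + ")"
            if node.name:
                out += _format_label(node.name)
        if node.parent is not None and node.length is not None:
            out += ":" + _format_length(node.length)
        return out

    root = tree.root
    text = serialize(root)
    if root.length:
        text += ":" + _format_length(root.length)
    return text + ";"


# ---------------------------------------------------------------------------
# Bipartitions and tree distances
# ---------------------------------------------------------------------------

def _canonical_split(side: frozenset, all_tips: frozenset) -> frozenset | None:
    """Canonical (smaller-side) form of a split; None if trivial."""
    other = all_tips - side
    if len(side) < 2 or len(other) < 2:
        return None
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    # equal sizes: take the side holding the lexicographically smallest label
    return side if min(all_tips) in side else other


def _split_lengths(tree: PhyloTree) -> dict[frozenset, float]:
    """Canonical split -> summed branch length over the unrooted tree.

    Both child edges of a degree-2 root induce the same unrooted edge; the
    dict accumulation merges their lengths, so the root edge is counted once.
    """
    all_tips = frozenset(tree.tip_labels())
    below: dict[Node, frozenset] = {}
    lengths: dict[frozenset, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[node] = frozenset([node.name])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        if node.parent is None or node.is_tip:
            continue
        canon = _canonical_split(below[node], all_tips)
        if canon is not None:
            lengths[canon] = lengths.get(canon, 0.0) + float(node.length or 0.0)
    return lengths


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions of the unrooted version of the tree.

    Each bipartition is the canonical (smaller) tip-label side of an internal
    edge. Trees with fewer than 4 tips have none.
    """
    if tree.n_tips < 4:
        return set()
    return set(_split_lengths(tree))


def _check_same_tips(t1: PhyloTree, t2: PhyloTree) -> None:
    s1, s2 = set(t1.tip_labels()), set(t2.tip_labels())
    if s1 != s2:
        only1 = sorted(s1 - s2)
        only2 = sorted(s2 - s1)
        raise TreeValidationError(
            f"tip sets differ: only in first {only1}; only in second {only2}"
        )


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson--Foulds distance: bipartitions implied by one tree, not the other."""
    _check_same_tips(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def branch_score(t1: PhyloTree, t2: PhyloTree) -> float:
    """Branch score: Euclidean norm of matched internal branch-length differences.

    Internal branches are matched by bipartition; a bipartition absent from
    one tree contributes that tree's length as 0.
    """
    _check_same_tips(t1, t2)
    l1 = _split_lengths(t1)
    l2 = _split_lengths(t2)
    total = 0.0
    for split in set(l1) | set(l2):
        d = l1.get(split, 0.0) - l2.get(split, 0.0)
        total += d * d
    return math.sqrt(total)


# ---------------------------------------------------------------------------
# Node ages (mean-path-length dating)
# ---------------------------------------------------------------------------

def assign_node_ages(tree: PhyloTree, root_age: float = 100.0) -> NodeAges:
    """Assign scaled ages: mean path length to tips, clamped, rescaled.

    Raw age of a node is the mean branch-length path from it to its
    descendant tips. Ages are then clamped so every parent is at least as
    old as its oldest child, and finally rescaled linearly so the root sits
    at ``root_age`` and extant tips at 0.
    """
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    if tree.n_tips < 2:
        raise TreeValidationError("need at least 2 tips to assign ages")

    path_sum: dict[Node, float] = {}
    n_below: dict[Node, int] = {}
    raw: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            path_sum[node], n_below[node], raw[node] = 0.0, 1, 0.0
            continue
        s = 0.0
        k = 0
        for child in node.children:
            s += path_sum[child] + float(child.length or 0.0) * n_below[child]
            k += n_below[child]
        path_sum[node], n_below[node] = s, k
        raw[node] = s / k
        # clamp: a parent can never be younger than a child
        raw[node] = max(raw[node], max(raw[c] for c in node.children))

    root_raw = raw[tree.root]
    if root_raw <= 0:
        raise TreeValidationError("degenerate tree: zero total depth, cannot date")
    scale = root_age / root_raw
    ages = {n: (0.0 if n.is_tip else raw[n] * scale) for n in tree.preorder()}
    return NodeAges(ages=ages, root_age=root_age)
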