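"""Reduced, colored subtrees summarizing where a pathway lives on the tree.

Every maximal clade in which the pathway is absent from all tips collapses
to a single placeholder tip, leaving a compact subtree that shows the
pathway's gains (red nodes), losses (blue nodes) and the lineages carrying
it (green edges). The root is colored by its reconstructed state only and is
never counted as a change, so the number of non-root colored nodes equals
the parsimony score of the character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .parsimony_analysis import AncestralStates, BinaryCharacter
from .tree_core import Node, PhyloTree, write_newick

logger = logging.getLogger(__name__)

__all__ = ["ReducedSubtree", "reduce_subtree", "subtree_sidecar_rows"]


@dataclass
class ReducedSubtree:
    """A collapsed subtree plus its node coloring.

    ``colors`` maps node id -> "red" | "blue" | "none"; ``green_edges`` holds
    the child-node ids of edges descending from presence-state nodes;
    ``states`` is the reconstructed state per retained node.
    """

    tree: PhyloTree
    colors: dict[str, str]
    states: dict[str, int]
    green_edges: set[str]
    root_state: int
    degenerate: bool = False

    @property
    def n_colored_nonroot(self) -> int:
        root_id = self.tree.root.name
        return sum(
            1 for nid, c in self.colors.items() if c != "none" and nid != root_id
        )

    def to_newick(self) -> str:
        return write_newick(self.tree)


def _max_tip_depth(node: Node) -> float:
    if node.is_tip:
        return 0.0
    return max(_max_tip_depth(c) + float(c.length or 0.0) for c in node.children)


def _first_tip_label(node: Node) -> str:
    while not node.is_tip:
        node = node.children[0]
    return node.name or ""


def reduce_subtree(
    tree: PhyloTree, ch: BinaryCharacter, anc: AncestralStates
) -> ReducedSubtree:
    """Collapse maximal all-absent clades and color state changes.

    A collapsed clade becomes one tip labeled ``<size>_absent_<first tip>``
    whose branch length spans from the attachment point to the clade's
    farthest original tip. If the pathway is absent from every tip the
    result is a degenerate single-tip tree (with a warning).
    """
    tip_state = {t: ch.states[t.name] for t in tree.tips()}
    all_absent: dict[Node, bool] = {}
    n_tips_below: dict[Node, int] = {}
    for node in tree.postorder():
        if node.is_tip:
            all_absent[node] = tip_state[node] == 0
            n_tips_below[node] = 1
        else:
            all_absent[node] = all(all_absent[c] for c in node.children)
            n_tips_below[node] = sum(n_tips_below[c] for c in node.children)

    colors: dict[str, str] = {}
    states: dict[str, int] = {}
    green: set[str] = set()
    counter = 0

    def next_internal_id() -> str:
        nonlocal counter
        counter += 1
        return f"N{counter}"

    def collapsed_tip(orig: Node) -> Node:
        label = f"{n_tips_below[orig]}_absent_{_first_tip_label(orig)}"
        length = float(orig.length or 0.0) + _max_tip_depth(orig)
        return Node(name=label, length=length)

    if all_absent[tree.root]:
        logger.warning(
            "pathway %r absent from all tips; degenerate single-tip subtree",
            ch.pathway_id,
        )
        tip = collapsed_tip(tree.root)
        tip.length = None  # it is the root of the reduced tree
        reduced = PhyloTree(tip)
        colors[tip.name] = "blue"
        states[tip.name] = 0
        return ReducedSubtree(
            tree=reduced,
            colors=colors,
            states=states,
            green_edges=green,
            root_state=0,
            degenerate=True,
        )

    def build(orig: Node) -> Node:
        if orig.is_tip:
            new = Node(name=orig.name, length=orig.length)
        else:
            new = Node(name=next_internal_id(), length=orig.length)
            for child in orig.children:
                sub = collapsed_tip(child) if all_absent[child] else build(child)
                new.add_child(sub)
                # collapsed clades carry state 0 at their root
                states[sub.name] = 0 if all_absent[child] else anc.state[child]
        states_self = anc.state[orig]
        states[new.name] = states_self
        return new

    new_root = build(tree.root)
    new_root.length = None
    reduced = PhyloTree(new_root)

    root_state = states[new_root.name]
    colors[new_root.name] = "red" if root_state == 1 else "blue"
    for node in reduced.preorder():
        if node.parent is None:
            continue
        s, sp = states[node.name], states[node.parent.name]
        if s > sp:
            colors[node.name] = "red"
        elif s < sp:
            colors[node.name] = "blue"
        else:
            colors[node.name] = "none"
        if sp == 1:
            green.add(node.name)

    return ReducedSubtree(
        tree=reduced,
        colors=colors,
        states=states,
        green_edges=green,
        root_state=root_state,
    )


def subtree_sidecar_rows(sub: ReducedSubtree) -> list[dict]:
    """Tabular sidecar for the annotated Newick: one row per retained node."""
    rows = []
    for node in sub.tree.preorder():
        nid = node.name or ""
        rows.append(
            {
                "node_id": nid,
                "color": sub.colors.get(nid, "none"),
                "state": sub.states.get(nid, ""),
                "green_edge": int(nid in sub.green_edges),
            }
        )
    return rows
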