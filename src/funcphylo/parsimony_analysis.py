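"""Parsimony scoring, ancestral states, retention index and gain/loss clocking.

A metabolic pathway is treated as a binary character on the tips of the
genome tree (1 = pathway inferred present, 0 = absent). The parsimony score
``s`` is the minimum number of presence/absence switches along branches that
explains the tip pattern; the retention index

    RI = (g - s) / (g - m)

normalizes ``s`` by the character's own bounds: ``g`` is the maximum number
of changes possible (the minority-state tip count for a binary character) and
``m`` the minimum (1 if both states occur, else 0). RI = 1 means the pathway
maps perfectly onto one clade structure; low RI indicates homoplasy, the
classic signature of horizontal transfer or repeated independent gain/loss.

Multifurcating nodes are handled with Hartigan's generalization of the Fitch
recurrence (majority-vote state sets), which keeps the score minimal on
non-binary trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .tree_core import Node, NodeAges, PhyloTree

__all__ = [
    "BinaryCharacter",
    "AncestralStates",
    "RIResult",
    "ChangeEvent",
    "fitch_score",
    "fitch_ancestral",
    "retention_index",
    "classify_consistency",
    "occurrence_percentage",
    "change_events",
]


@dataclass
class BinaryCharacter:
    """Presence/absence of one pathway across genomes (tree tips)."""

    pathway_id: str
    states: dict[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.states.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary states: {bad}")

    @property
    def n_present(self) -> int:
        return sum(self.states.values())

    @property
    def n_absent(self) -> int:
        return len(self.states) - self.n_present


@dataclass
class AncestralStates:
    """One most-parsimonious internal labeling plus the first-pass state sets."""

    character: BinaryCharacter
    state: dict[Node, int]
    preliminary: dict[Node, frozenset]

    def n_changes(self, tree: PhyloTree) -> int:
        """Number of edges whose endpoint states differ under this labeling."""
        return sum(
            1
            for node in tree.preorder()
            if node.parent is not None and self.state[node] != self.state[node.parent]
        )


@dataclass
class RIResult:
    """Retention-index bookkeeping for one character.

    ``g`` = max possible changes, ``s`` = parsimony score, ``m`` = min
    possible changes. Constant characters (g = 0) take RI = 1.0 by
    convention, flagged so downstream reports can mark them.
    """

    pathway_id: str
    n_present: int
    n_total: int
    g: int
    s: int
    m: int
    ri: float
    constant: bool = False

    @property
    def ri_rounded(self) -> float:
        """RI rounded half-up to two decimals, the reporting convention."""
        return float(Decimal(repr(self.ri)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class ChangeEvent:
    """A gain (0→1) or loss (1→0) on one branch, on the scaled clock."""

    pathway_id: str
    parent: Node
    child: Node
    direction: str  # "gain" | "loss"
    age_hi: float  # parent age (older end of the interval)
    age_lo: float  # child age
    age_mid: float


def _tip_states(tree: PhyloTree, ch: BinaryCharacter) -> dict[Node, int]:
    missing = [t.name for t in tree.tips() if t.name not in ch.states]
    if missing:
        raise ValueError(
            f"character {ch.pathway_id!r} missing states for tips: {sorted(missing)}"
        )
    return {t: ch.states[t.name] for t in tree.tips()}


def _fitch_down_pass(
    tree: PhyloTree, ch: BinaryCharacter
) -> tuple[int, dict[Node, frozenset]]:
    """Hartigan down pass: (score, preliminary state sets)."""
    tips = _tip_states(tree, ch)
    prelim: dict[Node, frozenset] = {}
    score = 0
    for node in tree.postorder():
        if node.is_tip:
            prelim[node] = frozenset([tips[node]])
            continue
        votes = {0: 0, 1: 0}
        for child in node.children:
            for state in prelim[child]:
                votes[state] += 1
        best = max(votes.values())
        prelim[node] = frozenset(s for s, v in votes.items() if v == best)
        score += len(node.children) - best
    return score, prelim


def fitch_score(tree: PhyloTree, ch: BinaryCharacter) -> int:
    """Minimum number of state changes explaining the tip pattern."""
    score, _ = _fitch_down_pass(tree, ch)
    return score


def fitch_ancestral(
    tree: PhyloTree, ch: BinaryCharacter, root_tie: int | str = 0
) -> AncestralStates:
    """One most-parsimonious labeling of the internal nodes.

    ``root_tie`` resolves an ambiguous root ({0, 1} preliminary set):
    0 (default, conservative about inferring ancient presence), 1, or
    "majority" (the more frequent tip state, 0 on a tie).
    """
    _, prelim = _fitch_down_pass(tree, ch)
    state: dict[Node, int] = {}
    for node in tree.preorder():
        options = prelim[node]
        if len(options) == 1:
            (state[node],) = options
        elif node.parent is not None and state[node.parent] in options:
            state[node] = state[node.parent]
        elif node.parent is None:
            if root_tie == "majority":
                state[node] = 1 if ch.n_present > ch.n_absent else 0
            elif root_tie in (0, 1):
                state[node] = int(root_tie)
            else:
                raise ValueError(f"invalid root_tie {root_tie!r}")
        else:
            # parent's state not available at this node: pick the smaller
            # state for determinism (cannot happen with binary Hartigan sets
            # of size 2, where both states are always options)
            state[node] = min(options)
    return AncestralStates(character=ch, state=state, preliminary=prelim)


def retention_index(
    n_present: int, n_total: int, s: int, pathway_id: str = ""
) -> RIResult:
    """RI = (g - s)/(g - m) with g = minority-state count, m = 1 if non-constant.

    Constant characters make the formula 0/0; by convention they return
    RI = 1.0 with ``constant=True`` so classification stays total.
    """
    if not 0 <= n_present <= n_total:
        raise ValueError(f"need 0 <= n_present <= n_total, got {n_present}/{n_total}")
    g = min(n_present, n_total - n_present)
    m = 1 if 0 < n_present < n_total else 0
    if g == 0:
        if s != 0:
            raise ValueError(f"constant character cannot have score {s}")
        return RIResult(pathway_id, n_present, n_total, g, s, m, ri=1.0, constant=True)
    if s > g:
        raise ValueError(f"impossible parsimony score: s={s} > g={g}")
    if s < m:
        raise ValueError(f"impossible parsimony score: s={s} < m={m}")
    if g == m:
        # one minority tip: s is forced to 1 = m = g, a perfect fit
        return RIResult(pathway_id, n_present, n_total, g, s, m, ri=1.0)
    ri = (g - s) / (g - m)
    return RIResult(pathway_id, n_present, n_total, g, s, m, ri=ri)


def classify_consistency(
    ri: float, consistent_above: float = 0.9, inconsistent_below: float = 0.7
) -> str:
    """Consistent (RI > 0.9), inconsistent (RI < 0.7), else intermediate."""
    if not 0.0 <= ri <= 1.0:
        raise ValueError(f"RI out of range: {ri}")
    if ri > consistent_above:
        return "consistent"
    if ri < inconsistent_below:
        return "inconsistent"
    return "intermediate"


def occurrence_percentage(n_present: int, n_total: int, ndigits: int = 1) -> float:
    """Genome occurrence frequency as a percentage, rounded half-up."""
    if n_total <= 0 or not 0 <= n_present <= n_total:
        raise ValueError("invalid counts")
    pct = Decimal(n_present) / Decimal(n_total) * 100
    q = Decimal(1).scaleb(-ndigits)
    return float(pct.quantize(q, ROUND_HALF_UP))


def change_events(
    tree: PhyloTree, anc: AncestralStates, ages: NodeAges
) -> list[ChangeEvent]:
    """One event per branch whose endpoint states differ, clocked by node ages.

    The point age of an event is the branch midpoint (the reconstruction only
    localizes a change to a branch, not to a position on it). Events are
    sorted oldest-first by point age.
    """
    events: list[ChangeEvent] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        s_child, s_parent = anc.state[node], anc.state[node.parent]
        if s_child == s_parent:
            continue
        hi, lo = ages[node.parent], ages[node]
        events.append(
            ChangeEvent(
                pathway_id=anc.character.pathway_id,
                parent=node.parent,
                child=node,
                direction="gain" if s_child == 1 else "loss",
                age_hi=hi,
                age_lo=lo,
                age_mid=(hi + lo) / 2.0,
            )
        )
    events.sort(key=lambda e: (-e.age_mid, e.child.name or ""))
    return events
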