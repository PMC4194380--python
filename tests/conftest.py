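"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

import funcphylo as fp


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """One deterministic fixture corpus shared by the pipeline-level tests."""
    cfg = fp.SimConfig(seed=11, n_tips=60, genus_size=4, gain_rate=0.02, loss_rate=0.06)
    return fp.generate_fixture_corpus(cfg, tmp_path_factory.mktemp("corpus"))


# ---------------------------------------------------------------------------
# Independent oracles (never call the implementation paths they check)
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree: fp.PhyloTree, states: dict[str, int]) -> int:
    """Minimum change count over all 2^(internal nodes) labelings."""
    internals = [n for n in tree.preorder() if not n.is_tip]
    tips = tree.tips()
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        label = dict(zip(internals, combo))
        for t in tips:
            label[t] = states[t.name]
        changes = sum(
            1
            for n in tree.preorder()
            if n.parent is not None and label[n] != label[n.parent]
        )
        if best is None or changes < best:
            best = changes
    return best


def brute_force_splits(tree: fp.PhyloTree) -> set[frozenset]:
    """Non-trivial splits via graph components after deleting each edge."""
    g = nx.Graph()
    nodes = list(tree.preorder())
    idx = {n: i for i, n in enumerate(nodes)}
    for n in nodes:
        if n.parent is not None:
            g.add_edge(idx[n.parent], idx[n])
    # unrooted view: contract a degree-2 root
    root = tree.root
    if len(root.children) == 2:
        a, b = (idx[c] for c in root.children)
        g.remove_node(idx[root])
        g.add_edge(a, b)
    tip_of = {idx[n]: n.name for n in nodes if n.is_tip}
    all_tips = frozenset(tip_of.values())
    splits = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(tip_of[i] for i in comp if i in tip_of)
        g.add_edge(u, v)
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            small = min(side, other, key=lambda s: (len(s), sorted(s)))
            splits.add(small)
    return splits


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(max(k, 0, n + K - N), min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def random_tree(rng: np.random.Generator, n_tips: int) -> fp.PhyloTree:
    """A random Yule tree with the given tip count."""
    cfg = fp.SimConfig(seed=0, n_tips=n_tips, scattered_k=0)
    return fp.simulate_yule_tree(cfg, rng=rng)
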