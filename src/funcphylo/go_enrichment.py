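"""GO term over-representation with the classic Fisher test and elim decorrelation.

The ontology is a DAG over terms (is_a edges only); annotation obeys the
true-path rule, so a gene annotated to a term is implicitly annotated to all
its ancestors. The classic test is the one-sided hypergeometric
over-representation test per term. The elim procedure decorrelates the DAG:
terms are tested leaves-first, and whenever a term comes out significant its
annotated genes are removed from all of its ancestors before those are
tested, so broad terms are not dragged along by one specific signal below
them.

Reporting follows two filters: only terms annotated to more than 10 genes in
the background are reported, and terms with elim p-value above 0.01 are
discarded as too general.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import networkx as nx
import obonet
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GoDag",
    "EnrichmentResult",
    "EnrichmentConfig",
    "OntologyError",
    "load_obo",
    "annotate_up",
    "fisher_classic",
    "elim_enrichment",
    "filter_and_rank",
]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (e.g. an is_a cycle)."""


@dataclass
class GoDag:
    """Ontology DAG: term -> is_a parents, plus names and namespaces."""

    parents: dict[str, frozenset[str]]
    name: dict[str, str]
    namespace: dict[str, str]

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by is_a edges, excluding the term itself."""
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out

    def depth(self, term: str) -> int:
        """Longest is_a path from the term up to a root."""
        memo: dict[str, int] = {}

        def d(t: str) -> int:
            if t not in memo:
                ps = self.parents.get(t, frozenset())
                memo[t] = 0 if not ps else 1 + max(d(p) for p in ps)
            return memo[t]

        return d(term)

    def depths(self) -> dict[str, int]:
        memo: dict[str, int] = {}
        for term in sorted(self.parents):
            stack = [term]
            while stack:
                t = stack[-1]
                ps = self.parents.get(t, frozenset())
                pending = [p for p in ps if p not in memo]
                if pending:
                    stack.extend(pending)
                    continue
                memo[t] = 0 if not ps else 1 + max(memo[p] for p in ps)
                stack.pop()
        return memo


@dataclass
class EnrichmentResult:
    """Per-term test outcome (counts and both p-values)."""

    term: str
    name: str
    study_annotated: int  # k
    study_size: int  # n
    background_annotated: int  # K
    background_size: int  # N
    p_classic: float
    p_elim: float


@dataclass
class EnrichmentConfig:
    """Reporting filters: background annotation floor, elim cutoff, top-k."""

    min_genes: int = 10  # strict: a term needs MORE than this many genes
    elim_threshold: float = 0.01
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.elim_threshold <= 0:
            raise ValueError("thresholds must be positive")


def load_obo(source: str | Path | IO[str]) -> GoDag:
    """Load an OBO 1.2 ontology, keeping non-obsolete terms and is_a edges."""
    graph = obonet.read_obo(source, ignore_obsolete=True)
    parents: dict[str, frozenset[str]] = {}
    name: dict[str, str] = {}
    namespace: dict[str, str] = {}
    isa = nx.DiGraph()
    for term, data in graph.nodes(data=True):
        ps = frozenset(
            parent
            for _, parent, key in graph.out_edges(term, keys=True)
            if key == "is_a"
        )
        parents[term] = ps
        name[term] = data.get("name", term)
        namespace[term] = data.get("namespace", "")
        isa.add_node(term)
        for p in ps:
            isa.add_edge(term, p)
    dangling = {p for ps in parents.values() for p in ps if p not in parents}
    if dangling:
        raise OntologyError(f"is_a parents not defined in file: {sorted(dangling)}")
    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise OntologyError(f"is_a cycle involving {cycle[0][0]}")
    return GoDag(parents=parents, name=name, namespace=namespace)


def annotate_up(
    dag: GoDag, direct: dict[str, set[str]]
) -> dict[str, set[str]]:
    """True-path propagation: each gene gains all ancestors of its terms."""
    full: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        expanded: set[str] = set()
        for term in terms:
            if term not in dag:
                logger.warning("gene %s: unknown GO term %s skipped", gene, term)
                continue
            expanded.add(term)
            expanded |= dag.ancestors(term)
        full[gene] = expanded
    return full


def fisher_classic(k: int, n: int, K: int, N: int) -> float:
    """One-sided over-representation p-value: P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N and k >= max(0, n + K - N)):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def elim_enrichment(
    dag: GoDag,
    study: set[str],
    annotations: dict[str, set[str]],
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Classic and elim p-values for every annotated term.

    ``annotations`` is the propagated gene -> term-set map over the whole
    background (its keys are the gene universe); ``study`` must be a subset.
    Terms are processed deepest level first; when a term's elim p-value is
    at or below the threshold, its annotated genes are removed from all of
    its ancestors before they are tested.
    """
    cfg = cfg or EnrichmentConfig()
    background = set(annotations)
    if not study <= background:
        raise ValueError(f"study genes outside background: {sorted(study - background)}")
    N = len(background)
    n = len(study)

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    depths = dag.depths()
    order = sorted(term_genes, key=lambda t: (-depths.get(t, 0), t))

    removed: dict[str, set[str]] = {t: set() for t in term_genes}
    results: list[EnrichmentResult] = []
    for term in order:
        genes = term_genes[term]
        K = len(genes)
        k = len(genes & study)
        p_classic = fisher_classic(k, n, K, N)
        kept = genes - removed[term]
        k_e = len(kept & study)
        K_e = len(kept)
        p_elim = fisher_classic(k_e, n, K_e, N)
        results.append(
            EnrichmentResult(
                term=term,
                name=dag.name.get(term, term),
                study_annotated=k,
                study_size=n,
                background_annotated=K,
                background_size=N,
                p_classic=p_classic,
                p_elim=p_elim,
            )
        )
        if p_elim <= cfg.elim_threshold:
            for anc in dag.ancestors(term):
                if anc in removed:
                    removed[anc] |= genes
    results.sort(key=lambda r: r.term)
    return results


def filter_and_rank(
    results: list[EnrichmentResult], cfg: EnrichmentConfig | None = None
) -> list[EnrichmentResult]:
    """Apply the reporting filters and rank by elim p-value.

    Terms annotated to ``min_genes`` background genes or fewer are dropped;
    terms with elim p above the threshold are dropped; remaining terms are
    sorted by ascending elim p (ties by term id) and truncated to top-k.
    """
    cfg = cfg or EnrichmentConfig()
    kept = [
        r
        for r in results
        if r.background_annotated > cfg.min_genes and r.p_elim <= cfg.elim_threshold
    ]
    kept.sort(key=lambda r: (r.p_elim, r.term))
    if cfg.top_k is not None:
        kept = kept[: cfg.top_k]
    return kept
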