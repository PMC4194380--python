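"""Synthetic corpora with the statistical structure the analysis assumes.

Stands in for a real genome collection: a Yule (pure-birth) genome tree,
binary pathway characters evolved under a vertical 2-state Markov model
(clade-borne functions maintained by inheritance) or scattered uniformly
across tips (the limiting signature of rampant horizontal transfer), genome
metadata with genus assignments, and fixture files for every input format
the pipeline consumes. Every generator is a pure function of (config, seed):
nothing draws randomness implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parsimony_analysis import BinaryCharacter
from .profile_matrix import GenomeRecord
from .tree_core import Node, PhyloTree, write_newick

__all__ = [
    "SimConfig",
    "TrueEvent",
    "FixtureCorpus",
    "simulate_yule_tree",
    "simulate_character_vertical",
    "simulate_character_scattered",
    "assign_genera",
    "generate_fixture_corpus",
]


@dataclass
class SimConfig:
    """Simulation parameters; the seed is mandatory.

    Rates are per unit branch length: ``gain_rate`` is the 0->1 rate and
    ``loss_rate`` the 1->0 rate of the vertical Markov model.
    ``scattered_k`` is the number of presence tips planted by the scattered
    (horizontal) model. ``genus_size`` genomes form one genus, taken as
    contiguous blocks in tree traversal order so genera carry phylogenetic
    signal.
    """

    seed: int
    n_tips: int = 200
    birth_rate: float = 1.0
    gain_rate: float = 0.002
    loss_rate: float = 0.0075
    root_state: int = 1
    scattered_k: int = 30
    genus_size: int = 5

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.root_state not in (0, 1):
            raise ValueError("root state must be 0 or 1")
        if not 0 <= self.scattered_k <= self.n_tips:
            raise ValueError("scattered_k must be within [0, n_tips]")
        if self.genus_size < 1:
            raise ValueError("genus size must be >= 1")


@dataclass
class TrueEvent:
    """A simulated state switch: the branch (child node), direction, and the
    time from the start of that branch."""

    child: Node
    direction: str  # "gain" | "loss"
    offset: float


def simulate_yule_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Pure-birth tree: uniformly chosen lineages split at exponential times.

    All extant branches are extended by each waiting time, so the tree is
    ultrametric. Tips are labeled G00001..G<n> in traversal order.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    root = Node()
    lineages = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while True:
        wait = rng.exponential(1.0 / (cfg.birth_rate * len(lineages)))
        for node in lineages:
            node.length += wait
        if len(lineages) >= cfg.n_tips:
            break
        idx = int(rng.integers(len(lineages)))
        parent = lineages[idx]
        children = [parent.add_child(Node(length=0.0)) for _ in range(2)]
        lineages[idx : idx + 1] = children
    leaves: list[Node] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(reversed(node.children))
        else:
            leaves.append(node)
    for i, tip in enumerate(leaves, start=1):
        tip.name = f"G{i:05d}"
    return PhyloTree(root)


def simulate_character_vertical(
    tree: PhyloTree,
    cfg: SimConfig,
    pathway_id: str = "PWY-V",
    rng: np.random.Generator | None = None,
) -> tuple[BinaryCharacter, list[TrueEvent]]:
    """Evolve a binary character down the tree under a 2-state Markov chain.

    Exact exponential waiting times are drawn along each branch, so the full
    list of true switch events exists; the parsimony score of the resulting
    tip pattern is a lower bound on the number of true events.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    events: list[TrueEvent] = []
    state_at: dict[Node, int] = {tree.root: cfg.root_state}
    for node in tree.preorder():
        if node.parent is None:
            continue
        state = state_at[node.parent]
        remaining = float(node.length or 0.0)
        offset = 0.0
        while True:
            rate = cfg.loss_rate if state == 1 else cfg.gain_rate
            if rate <= 0:
                break
            t = rng.exponential(1.0 / rate)
            if t > remaining:
                break
            offset += t
            remaining -= t
            state = 1 - state
            events.append(
                TrueEvent(
                    child=node,
                    direction="gain" if state == 1 else "loss",
                    offset=offset,
                )
            )
        state_at[node] = state
    states = {t.name: state_at[t] for t in tree.tips()}
    return BinaryCharacter(pathway_id=pathway_id, states=states), events


def simulate_character_scattered(
    tree: PhyloTree,
    k: int,
    pathway_id: str = "PWY-S",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BinaryCharacter:
    """Presence planted in k tips drawn uniformly without replacement."""
    labels = tree.tip_labels()
    if not 0 <= k <= len(labels):
        raise ValueError(f"k={k} outside [0, {len(labels)}]")
    if rng is None:
        if seed is None:
            raise ValueError("need an rng or a seed")
        rng = np.random.default_rng(seed)
    chosen = set(rng.choice(sorted(labels), size=k, replace=False)) if k else set()
    states = {lab: int(lab in chosen) for lab in labels}
    return BinaryCharacter(pathway_id=pathway_id, states=states)


def assign_genera(tree: PhyloTree, genus_size: int) -> dict[str, str]:
    """Genome -> genus, chunking tips in tree order into contiguous blocks."""
    labels = tree.tip_labels()
    return {
        lab: f"genus{(i // genus_size) + 1:03d}" for i, lab in enumerate(labels)
    }


# ---------------------------------------------------------------------------
# Fixture corpus: files for every format the pipeline reads
# ---------------------------------------------------------------------------

@dataclass
class FixtureCorpus:
    """Paths and planted ground truth of a generated fixture corpus."""

    tree_path: Path
    metadata_path: Path
    report_paths: list[Path]
    domtbl_path: Path
    gene2go_path: Path
    obo_path: Path
    tree: PhyloTree
    records: list[GenomeRecord]
    characters: dict[str, BinaryCharacter]
    qc_bad_genomes: dict[str, str]  # genome id -> violated rule
    domtbl_truth: dict[str, str | None]  # query -> expected best family (None = filtered)
    enriched_term: str
    enriched_phylum: str


_OBO_STUB = """format-version: 1.2
ontology: synthetic-bp

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0006807
name: nitrogen compound metabolic process
namespace: biological_process
is_a: GO:0008152 ! metabolic process

[Term]
id: GO:0009058
name: biosynthetic process
namespace: biological_process
is_a: GO:0008152 ! metabolic process

[Term]
id: GO:0050896
name: response to stimulus
namespace: biological_process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0000001
name: obsolete placeholder process
namespace: biological_process
is_obsolete: true
"""


def _write_domtbl_fixture(path: Path) -> dict[str, str | None]:
    """A small domtblout with one planted hit per filter clause.

    Returns query -> family expected to survive filtering (None if the
    query's hits are all planted to fail).
    """
    # columns: target acc tlen query acc qlen full_eval score bias # of
    #          c-eval i-eval dscore dbias hmm_from hmm_to ali_from ali_to
    #          env_from env_to acc description
    rows = []

    def row(fam, tlen, query, qlen, ev, hf, ht, af, at, desc):
        rows.append(
            f"{fam} - {tlen} {query} - {qlen} {ev} 50.0 0.1 1 1 "
            f"{ev} {ev} 49.0 0.1 {hf} {ht} {af} {at} {af} {at} 0.95 {desc}"
        )

    truth: dict[str, str | None] = {}
    # q_pass: passes everything
    row("FAM00001", 200, "q_pass", 180, "1e-50", 1, 190, 1, 170, "clean pass")
    truth["q_pass"] = "FAM00001"
    # q_eval: e-value exactly at / above the threshold -> filtered
    row("FAM00002", 200, "q_eval", 180, "1e-3", 1, 190, 1, 170, "evalue at threshold")
    truth["q_eval"] = None
    # q_qcov: query coverage below 50%
    row("FAM00003", 200, "q_qcov", 400, "1e-20", 1, 190, 1, 150, "low query coverage")
    truth["q_qcov"] = None
    # q_hcov: HMM coverage below 50%
    row("FAM00004", 400, "q_hcov", 180, "1e-20", 1, 150, 1, 170, "low hmm coverage")
    truth["q_hcov"] = None
    # q_best: two passing families; smaller e-value must win
    row("FAM00005", 200, "q_best", 180, "1e-4", 1, 190, 1, 170, "weaker hit")
    row("FAM00006", 200, "q_best", 180, "1e-9", 1, 190, 1, 170, "stronger hit")
    truth["q_best"] = "FAM00006"
    # q_split: two non-contiguous domains that only jointly reach 50%
    row("FAM00007", 200, "q_split", 200, "1e-8", 1, 60, 1, 55, "domain 1 of 2")
    row("FAM00007", 200, "q_split", 200, "1e-8", 100, 160, 100, 150, "domain 2 of 2")
    truth["q_split"] = "FAM00007"

    header = "# synthetic domtblout fixture\n#\n"
    path.write_text(header + "\n".join(rows) + "\n")
    return truth


def generate_fixture_corpus(
    cfg: SimConfig,
    out_dir: str | Path,
    n_vertical: int = 6,
    n_scattered: int = 6,
) -> FixtureCorpus:
    """Write a complete, schema-conformant fixture corpus under ``out_dir``.

    Plants: two genomes violating each QC rule (present in the metadata but
    not in the tree), sub-threshold confidence rows in the pathway reports,
    one constant pathway, one domtblout hit per filter clause, and a GO term
    enriched in the genomes of one phylum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_yule_tree(cfg, rng=rng)
    labels = tree.tip_labels()
    genus_of = assign_genera(tree, cfg.genus_size)

    # phyla: contiguous halves of the genus list; first phylum archaeal
    genera = sorted(set(genus_of.values()))
    phylum_of_genus = {
        g: ("Phylum_A" if i < len(genera) / 2 else "Phylum_B")
        for i, g in enumerate(genera)
    }
    records: list[GenomeRecord] = []
    for lab in labels:
        genus = genus_of[lab]
        phylum = phylum_of_genus[genus]
        records.append(
            GenomeRecord(
                genome_id=lab,
                genus=genus,
                phylum=phylum,
                domain="Archaea" if phylum == "Phylum_A" else "Bacteria",
                status="finished" if rng.random() < 0.3 else "draft",
                n_contigs=int(rng.integers(1, 500)),
                n_genes=int(rng.integers(1500, 5000)),
            )
        )
    qc_bad = {
        "BAD_CONTIGS": "contigs",
        "BAD_GENES": "genes",
    }
    bad_records = [
        GenomeRecord("BAD_CONTIGS", "genusBAD", "Phylum_B", "Bacteria", "draft", 1500, 3000),
        GenomeRecord("BAD_GENES", "genusBAD", "Phylum_B", "Bacteria", "draft", 10, 120),
    ]

    # characters: vertical, scattered, one constant
    characters: dict[str, BinaryCharacter] = {}
    for i in range(n_vertical):
        ch, _ = simulate_character_vertical(
            tree, cfg, pathway_id=f"PWY-V{i + 1:03d}", rng=rng
        )
        characters[ch.pathway_id] = ch
    for i in range(n_scattered):
        ch = simulate_character_scattered(
            tree, cfg.scattered_k, pathway_id=f"PWY-S{i + 1:03d}", rng=rng
        )
        characters[ch.pathway_id] = ch
    characters["PWY-CONST"] = BinaryCharacter(
        pathway_id="PWY-CONST", states={lab: 1 for lab in labels}
    )

    # pathway reports: confidence >= 70 for present, sub-threshold noise rows
    # (and a duplicate low+high pair) for a sample of absent cells
    report_path = out / "pathway_reports.tsv"
    lines = ["genome_id\tpathway_id\tconfidence"]
    for lab in labels:
        for pid in sorted(characters):
            present = characters[pid].states[lab]
            if present:
                conf = 70.0 + float(rng.integers(0, 31))
                lines.append(f"{lab}\t{pid}\t{conf:.1f}")
                if rng.random() < 0.05:  # duplicate row, lower confidence
                    lines.append(f"{lab}\t{pid}\t{float(rng.integers(10, 70)):.1f}")
            elif rng.random() < 0.10:  # planted sub-threshold call
                lines.append(f"{lab}\t{pid}\t{float(rng.integers(10, 70)):.1f}")
    report_path.write_text("\n".join(lines) + "\n")

    # metadata (good genomes in tree order + planted QC violators)
    metadata_path = out / "metadata.tsv"
    md_lines = ["\t".join(METADATA_HEADER)]
    for rec in records + bad_records:
        md_lines.append(
            f"{rec.genome_id}\t{rec.genus}\t{rec.phylum}\t{rec.domain}\t"
            f"{rec.status}\t{rec.n_contigs}\t{rec.n_genes}"
        )
    metadata_path.write_text("\n".join(md_lines) + "\n")

    tree_path = out / "tree.nwk"
    tree_path.write_text(write_newick(tree) + "\n")

    domtbl_path = out / "hits.domtbl"
    domtbl_truth = _write_domtbl_fixture(domtbl_path)

    obo_path = out / "ontology.obo"
    obo_path.write_text(_OBO_STUB)

    # gene -> GO: genes are "<genome>:g<i>"; Phylum_A genomes enriched for
    # the nitrogen term, everything else mostly biosynthesis/response
    enriched_term = "GO:0006807"
    gene2go_path = out / "gene2go.tsv"
    g2g = ["genome_id\tgene_id\tgo_terms"]
    for rec in records:
        archaeal = rec.phylum == "Phylum_A"
        for j in range(1, 6):  # 5 annotated genes per genome
            gene = f"{rec.genome_id}:g{j}"
            if archaeal and j <= 3:
                terms = enriched_term
            elif rng.random() < 0.15:
                terms = enriched_term
            else:
                terms = "GO:0009058" if rng.random() < 0.5 else "GO:0050896"
            g2g.append(f"{rec.genome_id}\t{gene}\t{terms}")
    gene2go_path.write_text("\n".join(g2g) + "\n")

    return FixtureCorpus(
        tree_path=tree_path,
        metadata_path=metadata_path,
        report_paths=[report_path],
        domtbl_path=domtbl_path,
        gene2go_path=gene2go_path,
        obo_path=obo_path,
        tree=tree,
        records=records,
        characters=characters,
        qc_bad_genomes=qc_bad,
        domtbl_truth=domtbl_truth,
        enriched_term=enriched_term,
        enriched_phylum="Phylum_A",
    )


METADATA_HEADER = [
    "genome_id",
    "genus",
    "phylum",
    "domain",
    "status",
    "n_contigs",
    "n_genes",
]
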