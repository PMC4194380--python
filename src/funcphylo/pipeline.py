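"""End-to-end orchestration: from input files to the per-pathway result bundle.

Reads the genome tree, metadata, pathway reports and (optionally) GO inputs;
applies QC; scores every pathway as a binary character (parsimony score,
retention index, consistency class); clocks gain/loss events; reduces
subtrees for requested pathways; clusters genus-level profiles; and runs GO
enrichment for requested taxa. All outputs are deterministic functions of the
inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .go_enrichment import (
    EnrichmentConfig,
    annotate_up,
    elim_enrichment,
    filter_and_rank,
    load_obo,
)
from .parsimony_analysis import (
    change_events,
    classify_consistency,
    fitch_ancestral,
    fitch_score,
    retention_index,
    BinaryCharacter,
)
from .profile_matrix import (
    QCConfig,
    aggregate_by_genus,
    hierarchical_cluster,
    load_pathway_reports,
    qc_filter_genomes,
    read_metadata,
    write_matrix,
)
from .subtree_reduction import reduce_subtree, subtree_sidecar_rows
from .tree_core import assign_node_ages, parse_newick

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "ValidationError", "run_function_phylogenomics"]


class ValidationError(ValueError):
    """Input contract violation (id mismatches, empty matrices, ...)."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and requests for one pipeline run."""

    tree_path: str | Path
    metadata_path: str | Path
    report_paths: list[str | Path]
    out_dir: str | Path
    gene2go_path: str | Path | None = None
    obo_path: str | Path | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    ri_consistent: float = 0.9
    ri_inconsistent: float = 0.7
    root_age: float = 100.0
    root_tie: int | str = 0
    linkage_method: str = "complete"
    subtree_pathways: list[str] = field(default_factory=list)
    enrich_taxa: list[str] = field(default_factory=list)
    taxon_rank: str = "phylum"  # metadata column naming the taxon

    def __post_init__(self) -> None:
        if not self.ri_inconsistent < self.ri_consistent:
            raise ValidationError("thresholds must satisfy inconsistent < consistent")


@dataclass
class PipelineResult:
    """In-memory bundle of everything the run produced."""

    pathway_table: pd.DataFrame
    events_table: pd.DataFrame
    summary: dict
    genus_matrix: pd.DataFrame
    genera_dendrogram: str
    pathways_dendrogram: str
    subtrees: dict[str, object]
    enrichment: dict[str, pd.DataFrame]
    manifest: list[str]


def _enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "k": r.study_annotated,
                "n": r.study_size,
                "K": r.background_annotated,
                "N": r.background_size,
                "p_classic": r.p_classic,
                "p_elim": r.p_elim,
            }
            for r in results
        ],
        columns=["term", "name", "k", "n", "K", "N", "p_classic", "p_elim"],
    )


def run_function_phylogenomics(cfg: PipelineConfig) -> PipelineResult:
    """Run the whole analysis and write the result bundle under ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    tree = parse_newick(Path(cfg.tree_path).read_text())
    records = read_metadata(cfg.metadata_path)
    kept, rejected = qc_filter_genomes(records, cfg.qc)
    logger.info("QC kept %d of %d genomes", len(kept), len(records))

    kept_ids = {r.genome_id for r in kept}
    tip_ids = set(tree.tip_labels())
    if kept_ids != tip_ids:
        only_meta = sorted(kept_ids - tip_ids)
        only_tree = sorted(tip_ids - kept_ids)
        raise ValidationError(
            f"tip/genome id mismatch: metadata-only {only_meta[:20]}, "
            f"tree-only {only_tree[:20]}"
        )

    matrix = load_pathway_reports(cfg.report_paths, cfg.qc)
    matrix = matrix.reindex(index=sorted(tip_ids), fill_value=0).astype("int8")
    if matrix.shape[1] == 0:
        raise ValidationError("empty pathway matrix: no pathway passed loading")

    ages = assign_node_ages(tree, root_age=cfg.root_age)

    pathway_rows = []
    event_rows = []
    ancestral = {}
    n_total = matrix.shape[0]
    for pid in matrix.columns:
        states = {g: int(v) for g, v in matrix[pid].items()}
        ch = BinaryCharacter(pathway_id=pid, states=states)
        s = fitch_score(tree, ch)
        ri = retention_index(ch.n_present, n_total, s, pathway_id=pid)
        label = classify_consistency(ri.ri, cfg.ri_consistent, cfg.ri_inconsistent)
        anc = fitch_ancestral(tree, ch, root_tie=cfg.root_tie)
        ancestral[pid] = (ch, anc)
        pathway_rows.append(
            {
                "pathway_id": pid,
                "n_present": ri.n_present,
                "n_total": ri.n_total,
                "g": ri.g,
                "s": ri.s,
                "m": ri.m,
                "ri": ri.ri,
                "ri_2dp": ri.ri_rounded,
                "class": "constant" if ri.constant else label,
            }
        )
        for ev in change_events(tree, anc, ages):
            event_rows.append(
                {
                    "pathway_id": pid,
                    "parent": ev.parent.name or "",
                    "child": ev.child.name or "",
                    "direction": ev.direction,
                    "age_lo": ev.age_lo,
                    "age_hi": ev.age_hi,
                    "age_mid": ev.age_mid,
                }
            )

    pathway_table = pd.DataFrame(pathway_rows).set_index("pathway_id")
    events_table = pd.DataFrame(
        event_rows,
        columns=["pathway_id", "parent", "child", "direction", "age_lo", "age_hi", "age_mid"],
    )

    non_constant = pathway_table[pathway_table["class"] != "constant"]
    n_pathways = len(pathway_table)
    summary = {
        "n_genomes": n_total,
        "n_pathways": n_pathways,
        "n_constant": int((pathway_table["class"] == "constant").sum()),
        "frac_consistent": float((pathway_table["class"] == "consistent").sum()) / n_pathways,
        "frac_inconsistent": float((pathway_table["class"] == "inconsistent").sum()) / n_pathways,
        "frac_intermediate": float((pathway_table["class"] == "intermediate").sum()) / n_pathways,
    }

    # genus-level clustering (Figure-2-style machinery)
    genus_matrix = aggregate_by_genus(matrix, kept)
    genera_cl = hierarchical_cluster(genus_matrix, axis="rows", method=cfg.linkage_method)
    pathways_cl = hierarchical_cluster(genus_matrix, axis="columns", method=cfg.linkage_method)

    # reduced subtrees for requested pathways
    subtrees = {}
    for pid in cfg.subtree_pathways:
        if pid not in ancestral:
            raise ValidationError(f"subtree requested for unknown pathway {pid!r}")
        ch, anc = ancestral[pid]
        subtrees[pid] = reduce_subtree(tree, ch, anc)

    # GO enrichment per requested taxon
    enrichment: dict[str, pd.DataFrame] = {}
    if cfg.enrich_taxa:
        if cfg.gene2go_path is None or cfg.obo_path is None:
            raise ValidationError("enrichment requested but gene2go/obo paths missing")
        dag = load_obo(str(cfg.obo_path))
        g2g = pd.read_csv(cfg.gene2go_path, sep="\t", dtype=str)
        for col in ("genome_id", "gene_id", "go_terms"):
            if col not in g2g.columns:
                raise ValidationError(f"{cfg.gene2go_path}: missing column {col}")
        g2g = g2g[g2g["genome_id"].isin(kept_ids)]
        direct = {
            row.gene_id: set(str(row.go_terms).split(";"))
            for row in g2g.itertuples(index=False)
        }
        full = annotate_up(dag, direct)
        genome_of_gene = dict(zip(g2g["gene_id"], g2g["genome_id"]))
        taxon_of = {r.genome_id: getattr(r, cfg.taxon_rank) for r in kept}
        for taxon in cfg.enrich_taxa:
            study = {
                gene
                for gene, genome in genome_of_gene.items()
                if taxon_of.get(genome) == taxon
            }
            if not study:
                raise ValidationError(f"no genes found for taxon {taxon!r}")
            results = elim_enrichment(dag, study, full, cfg.enrichment)
            enrichment[taxon] = _enrichment_frame(
                filter_and_rank(results, cfg.enrichment)
            )

    # ---- write the bundle -------------------------------------------------
    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest.append(name)

    emit("pathways.tsv", lambda p: pathway_table.to_csv(p, sep="\t"))
    emit("events.tsv", lambda p: events_table.to_csv(p, sep="\t", index=False))
    emit(
        "summary.tsv",
        lambda p: pd.Series(summary).to_csv(p, sep="\t", header=False),
    )
    emit("genus_matrix.tsv", lambda p: write_matrix(genus_matrix, p))
    emit("genera_dendrogram.nwk", lambda p: p.write_text(genera_cl.newick + "\n"))
    emit("pathways_dendrogram.nwk", lambda p: p.write_text(pathways_cl.newick + "\n"))
    if rejected:
        emit(
            "qc_rejections.tsv",
            lambda p: pd.DataFrame(rejected, columns=["genome_id", "reason"]).to_csv(
                p, sep="\t", index=False
            ),
        )
    for pid, sub in subtrees.items():
        safe = pid.replace("/", "_")
        emit(f"subtree_{safe}.nwk", lambda p, s=sub: p.write_text(s.to_newick() + "\n"))
        emit(
            f"subtree_{safe}_colors.tsv",
            lambda p, s=sub: pd.DataFrame(subtree_sidecar_rows(s)).to_csv(
                p, sep="\t", index=False
            ),
        )
    for taxon, table in enrichment.items():
        emit(
            f"enrichment_{taxon}.tsv",
            lambda p, t=table: t.to_csv(p, sep="\t", index=False),
        )
    (out / "MANIFEST").write_text("\n".join(sorted(manifest)) + "\n")

    return PipelineResult(
        pathway_table=pathway_table,
        events_table=events_table,
        summary=summary,
        genus_matrix=genus_matrix,
        genera_dendrogram=genera_cl.newick,
        pathways_dendrogram=pathways_cl.newick,
        subtrees=subtrees,
        enrichment=enrichment,
        manifest=sorted(manifest),
    )
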