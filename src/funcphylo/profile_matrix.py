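"""Pathway presence/absence profiles: QC, loading, genus aggregation, clustering.

A genome's metabolic profile is a 0/1 vector over the pathway universe
(1 = pathway inferred with sufficient confidence). Profiles are aggregated
to genus pan-genome profiles (a pathway is present in a genus if present in
any member genome) and clustered hierarchically with Manhattan distance,
which for binary vectors counts the number of differing pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeRecord",
    "QCConfig",
    "FormatError",
    "read_metadata",
    "qc_filter_genomes",
    "load_pathway_reports",
    "aggregate_by_genus",
    "manhattan_distance",
    "ClusterResult",
    "hierarchical_cluster",
    "write_matrix",
]

METADATA_COLUMNS = [
    "genome_id",
    "genus",
    "phylum",
    "domain",
    "status",
    "n_contigs",
    "n_genes",
]

REPORT_COLUMNS = ["genome_id", "pathway_id", "confidence"]


class FormatError(ValueError):
    """Raised when an input table is missing required columns."""


@dataclass
class GenomeRecord:
    """One genome's metadata row."""

    genome_id: str
    genus: str
    phylum: str
    domain: str
    status: str
    n_contigs: int
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError(f"{self.genome_id}: contig count must be >= 1")
        if self.n_genes < 0:
            raise ValueError(f"{self.genome_id}: gene count must be >= 0")


@dataclass
class QCConfig:
    """Genome and pathway acceptance thresholds.

    Genomes with more than ``max_contigs`` contigs (highly fragmented) or
    fewer than ``min_genes`` predicted genes are discarded; pathway calls
    need confidence >= ``min_confidence``.
    """

    max_contigs: int = 1000
    min_genes: int = 400
    min_confidence: float = 70.0

    def __post_init__(self) -> None:
        if self.max_contigs <= 0 or self.min_genes <= 0 or self.min_confidence <= 0:
            raise ValueError("all QC thresholds must be positive")


def read_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read the genome metadata TSV into records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GenomeRecord(
                genome_id=row.genome_id,
                genus=row.genus,
                phylum=row.phylum,
                domain=row.domain,
                status=row.status,
                n_contigs=int(row.n_contigs),
                n_genes=int(row.n_genes),
            )
        )
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate genome ids {dupes}")
    return records


def qc_filter_genomes(
    records: list[GenomeRecord], cfg: QCConfig | None = None
) -> tuple[list[GenomeRecord], list[tuple[str, str]]]:
    """Keep genomes with <= max_contigs contigs and >= min_genes genes.

    Returns (kept records, rejection log of (genome_id, reason)).
    """
    cfg = cfg or QCConfig()
    kept: list[GenomeRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        if rec.n_contigs > cfg.max_contigs:
            rejected.append(
                (rec.genome_id, f"contigs {rec.n_contigs} > {cfg.max_contigs}")
            )
        elif rec.n_genes < cfg.min_genes:
            rejected.append((rec.genome_id, f"genes {rec.n_genes} < {cfg.min_genes}"))
        else:
            kept.append(rec)
    for genome_id, reason in rejected:
        logger.info("QC rejected %s: %s", genome_id, reason)
    return kept, rejected


def load_pathway_reports(
    files: list[str | Path], cfg: QCConfig | None = None
) -> pd.DataFrame:
    """Build the genome x pathway 0/1 matrix from pathway-report TSVs.

    A cell is 1 iff some report row for that (genome, pathway) has
    confidence >= the threshold; duplicate rows collapse by maximum
    confidence (presence is an existential claim). Columns are the union of
    pathways seen across all files; rows and columns are sorted by id.
    """
    cfg = cfg or QCConfig()
    frames = []
    for path in files:
        df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "pathway_id": str})
        missing = [c for c in REPORT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing report columns {missing}")
        frames.append(df[REPORT_COLUMNS])
    if not frames:
        raise ValueError("no pathway report files given")
    allrows = pd.concat(frames, ignore_index=True)
    allrows["confidence"] = allrows["confidence"].astype(float)
    best = allrows.groupby(["genome_id", "pathway_id"])["confidence"].max()
    present = (best >= cfg.min_confidence).astype(np.int8)
    matrix = present.unstack(fill_value=0).astype(np.int8)
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    matrix.index.name = "genome_id"
    matrix.columns.name = "pathway_id"
    return matrix


def aggregate_by_genus(
    matrix: pd.DataFrame, records: list[GenomeRecord]
) -> pd.DataFrame:
    """Genus pan-genome profiles: OR over the member genomes of each genus."""
    genus_of = {r.genome_id: r.genus for r in records}
    missing = [g for g in matrix.index if g not in genus_of]
    if missing:
        raise ValueError(f"genomes without metadata: {sorted(missing)}")
    genera = pd.Series([genus_of[g] for g in matrix.index], index=matrix.index)
    agg = matrix.groupby(genera).max().astype(np.int8)
    agg = agg.sort_index(axis=0)
    agg.index.name = "genus"
    return agg


def manhattan_distance(v1, v2) -> int:
    """Number of differing entries between two 0/1 vectors."""
    a = np.asarray(v1)
    b = np.asarray(v2)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.abs(a - b).sum())


@dataclass
class ClusterResult:
    """Agglomeration output: scipy linkage matrix, leaf order, Newick dendrogram."""

    ids: list[str]
    linkage_matrix: np.ndarray | None
    leaf_order: list[str]
    newick: str


def _linkage_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Dendrogram as Newick, merge heights as cumulative node heights."""
    n = len(ids)
    height = {i: 0.0 for i in range(n)}
    label = {i: ids[i] for i in range(n)}

    def fmt(i: int, parent_h: float) -> str:
        return f"{label[i]}:{parent_h - height[i]!r}" if i < n else _sub(i, parent_h)

    def _sub(i: int, parent_h: float) -> str:
        a, b = children[i]
        inner = f"({fmt(a, height[i])},{fmt(b, height[i])})"
        return f"{inner}:{parent_h - height[i]!r}"

    children: dict[int, tuple[int, int]] = {}
    for k, row in enumerate(Z):
        node = n + k
        children[node] = (int(row[0]), int(row[1]))
        height[node] = float(row[2])
    root = n + len(Z) - 1
    a, b = children[root]
    return f"({fmt(a, height[root])},{fmt(b, height[root])});"


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: str = "rows", method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering with Manhattan distance.

    ``method`` is the linkage rule (complete by default; single and average
    also supported). Rows (or columns) are sorted lexicographically by id
    before clustering, so the result is invariant to input permutation and
    ties break deterministically.
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if method not in ("complete", "single", "average"):
        raise ValueError(f"unsupported linkage method {method!r}")
    data = matrix if axis == "rows" else matrix.T
    ids = sorted(str(i) for i in data.index)
    data = data.loc[ids]
    if len(ids) == 0:
        raise ValueError("nothing to cluster")
    if len(ids) == 1:
        return ClusterResult(
            ids=ids, linkage_matrix=None, leaf_order=ids, newick=f"{ids[0]}:0.0;"
        )
    dist = pdist(data.to_numpy(dtype=float), metric="cityblock")
    Z = linkage(dist, method=method)
    order = [ids[i] for i in leaves_list(Z)]
    return ClusterResult(
        ids=ids,
        linkage_matrix=Z,
        leaf_order=order,
        newick=_linkage_to_newick(Z, ids),
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Export a 0/1 matrix as TSV with row ids in the first column."""
    matrix.to_csv(path, sep="\t")
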