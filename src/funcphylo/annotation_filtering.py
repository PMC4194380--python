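"""Homology-hit filtering and protein-family annotation transfer.

Proteins are matched against profile HMMs of curated protein families; the
per-domain tabular output (domtblout) of that search is parsed here and the
annotation-transfer rules applied: a hit must have whole-sequence e-value
strictly below 1e-3 and its aligned regions (merged across domains, which
need not be contiguous) must cover at least 50% of both the HMM and the
query protein. Each query then receives the annotation of its best surviving
family, ranked by whole-sequence e-value.

Family annotations themselves are unions over the curated member proteins of
a cluster; cluster validity follows the build rules (>80% identity to the
centroid, shortest sequence >80% as long as the longest).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

__all__ = [
    "HmmerHit",
    "AnnotationFilterConfig",
    "FamilyAnnotation",
    "ClusterRuleConfig",
    "DomtblFormatError",
    "parse_domtbl",
    "coverage",
    "filter_hits",
    "merge_family_annotations",
    "validate_cluster",
]

GO_ID_RE = re.compile(r"^GO:\d{7}$")

# domtblout has 23 whitespace-separated columns; the last (description) may
# contain spaces, so rows are split with maxsplit=22.
_N_COLUMNS = 23


class DomtblFormatError(ValueError):
    """Raised for malformed domtblout rows, with the offending line number."""


@dataclass
class HmmerHit:
    """All domain alignments of one (query protein, HMM family) pair.

    Intervals are 1-based inclusive, on the query and on the HMM match
    states respectively; the e-value is the whole-sequence one.
    """

    query_id: str
    family_id: str
    evalue: float
    query_len: int
    hmm_len: int
    query_intervals: list[tuple[int, int]] = field(default_factory=list)
    hmm_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"e-value must be > 0, got {self.evalue}")
        for lo, hi in self.query_intervals:
            if not 1 <= lo <= hi <= self.query_len:
                raise ValueError(f"query interval [{lo},{hi}] outside [1,{self.query_len}]")
        for lo, hi in self.hmm_intervals:
            if not 1 <= lo <= hi <= self.hmm_len:
                raise ValueError(f"HMM interval [{lo},{hi}] outside [1,{self.hmm_len}]")


@dataclass
class AnnotationFilterConfig:
    """Annotation-transfer thresholds.

    ``max_evalue`` is exclusive (e-value must be strictly lower);
    ``min_coverage`` is inclusive and applies to both the query and the HMM.
    """

    max_evalue: float = 1.0e-3
    min_coverage: float = 0.50

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("e-value threshold must be positive")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("coverage fraction must be in (0, 1]")


@dataclass
class FamilyAnnotation:
    """Annotation payload transferred from a protein family to its hits."""

    family_id: str
    product_names: frozenset[str] = frozenset()
    ec_numbers: frozenset[str] = frozenset()
    gene_names: frozenset[str] = frozenset()
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = [t for t in self.go_terms if not GO_ID_RE.match(t)]
        if bad:
            raise ValueError(f"malformed GO ids: {sorted(bad)}")


@dataclass
class ClusterRuleConfig:
    """Cluster-membership rules (both thresholds are strict '>')."""

    min_identity: float = 0.80
    min_length_ratio: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_length_ratio <= 1:
            raise ValueError("cluster thresholds must be in (0, 1]")


def parse_domtbl(source: str | Path | IO[str] | Iterable[str]) -> list[HmmerHit]:
    """Parse HMMER3 per-domain tabular output into per-(query, family) hits.

    Follows the hmmscan convention: the target is the HMM family, the query
    the protein. Domain rows of the same pair aggregate into one hit. Lines
    starting with '#' are comments. Malformed rows raise
    :class:`DomtblFormatError` naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_domtbl(fh)

    hits: dict[tuple[str, str], HmmerHit] = {}
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split(None, _N_COLUMNS - 1)
        if len(fields) < _N_COLUMNS - 1:  # description may be empty
            raise DomtblFormatError(
                f"line {lineno}: expected {_N_COLUMNS} columns, got {len(fields)}"
            )
        family_id, query_id = fields[0], fields[3]
        try:
            hmm_len = int(fields[2])
            query_len = int(fields[5])
            evalue = float(fields[6])
            hmm_from, hmm_to = int(fields[15]), int(fields[16])
            ali_from, ali_to = int(fields[17]), int(fields[18])
        except ValueError as exc:
            raise DomtblFormatError(f"line {lineno}: {exc}") from exc
        key = (query_id, family_id)
        if key not in hits:
            try:
                hits[key] = HmmerHit(
                    query_id=query_id,
                    family_id=family_id,
                    evalue=evalue,
                    query_len=query_len,
                    hmm_len=hmm_len,
                )
            except ValueError as exc:
                raise DomtblFormatError(f"line {lineno}: {exc}") from exc
        hit = hits[key]
        if not (1 <= ali_from <= ali_to <= query_len):
            raise DomtblFormatError(
                f"line {lineno}: query interval [{ali_from},{ali_to}] "
                f"outside [1,{query_len}]"
            )
        if not (1 <= hmm_from <= hmm_to <= hmm_len):
            raise DomtblFormatError(
                f"line {lineno}: HMM interval [{hmm_from},{hmm_to}] "
                f"outside [1,{hmm_len}]"
            )
        hit.query_intervals.append((ali_from, ali_to))
        hit.hmm_intervals.append((hmm_from, hmm_to))
    return list(hits.values())


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total residues covered by 1-based inclusive intervals, overlaps merged."""
    if not intervals:
        return 0
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in sorted(intervals):
        if cur_hi is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi + 1:  # overlapping or adjacent
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    total += cur_hi - cur_lo + 1
    return total


def coverage(hit: HmmerHit) -> tuple[float, float]:
    """(query coverage, HMM coverage) as fractions of merged aligned length."""
    qcov = _merged_length(hit.query_intervals) / hit.query_len
    hcov = _merged_length(hit.hmm_intervals) / hit.hmm_len
    return qcov, hcov


def filter_hits(
    hits: list[HmmerHit], cfg: AnnotationFilterConfig | None = None
) -> tuple[dict[str, HmmerHit], list[str]]:
    """Best surviving hit per query under the e-value and coverage thresholds.

    Returns (query -> best hit, queries left unannotated). The best hit is
    the surviving one with the smallest e-value; equal e-values break by
    lexicographically smallest family id.
    """
    cfg = cfg or AnnotationFilterConfig()
    surviving: dict[str, list[HmmerHit]] = {}
    all_queries: set[str] = set()
    for hit in hits:
        all_queries.add(hit.query_id)
        if hit.evalue >= cfg.max_evalue:
            continue
        qcov, hcov = coverage(hit)
        if qcov < cfg.min_coverage or hcov < cfg.min_coverage:
            continue
        surviving.setdefault(hit.query_id, []).append(hit)
    best = {
        q: min(cands, key=lambda h: (h.evalue, h.family_id))
        for q, cands in surviving.items()
    }
    unannotated = sorted(all_queries - set(best))
    return best, unannotated


def merge_family_annotations(members: list[FamilyAnnotation]) -> FamilyAnnotation:
    """Field-wise union of member annotations (the cluster's annotation)."""
    if not members:
        raise ValueError("cannot merge an empty member list")
    return FamilyAnnotation(
        family_id=members[0].family_id,
        product_names=frozenset().union(*(m.product_names for m in members)),
        ec_numbers=frozenset().union(*(m.ec_numbers for m in members)),
        gene_names=frozenset().union(*(m.gene_names for m in members)),
        go_terms=frozenset().union(*(m.go_terms for m in members)),
    )


def validate_cluster(
    members: list[tuple[float, int]], cfg: ClusterRuleConfig | None = None
) -> tuple[bool, list[str]]:
    """Check (identity-to-centroid, length) pairs against the cluster rules.

    Valid iff every identity exceeds ``min_identity`` and the shortest
    sequence exceeds ``min_length_ratio`` of the longest.
    """
    if not members:
        raise ValueError("cluster has no members")
    cfg = cfg or ClusterRuleConfig()
    violations: list[str] = []
    for i, (identity, length) in enumerate(members):
        if identity <= cfg.min_identity:
            violations.append(
                f"member {i}: identity {identity} <= {cfg.min_identity}"
            )
        if length <= 0:
            violations.append(f"member {i}: non-positive length {length}")
    lengths = [length for _, length in members]
    ratio = min(lengths) / max(lengths) if max(lengths) > 0 else 0.0
    if ratio <= cfg.min_length_ratio:
        violations.append(
            f"length ratio {ratio:.4f} <= {cfg.min_length_ratio} "
            f"(shortest {min(lengths)}, longest {max(lengths)})"
        )
    return (not violations), violations
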