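# funcphylo

Functional phylogenomics of prokaryotes: how well do cellular functions —
metabolic pathways inferred from genome annotation — track the phylogeny of
the genomes that carry them?

A pathway is treated as a **binary character** on the tips of a rooted
genome tree (1 = inferred present, 0 = absent). For each pathway the package
computes:

- the **parsimony score** `s`: the minimum number of presence/absence
  switches along branches that explains the tip pattern (Fitch's two-pass
  algorithm, with Hartigan's majority-vote generalization on
  multifurcations);
- the **retention index** `RI = (g − s) / (g − m)`, where `g` is the
  maximum possible number of changes (the minority-state tip count for a
  binary character) and `m` the minimum possible (1 if both states occur,
  else 0). `RI = 1` means the pathway fits the tree perfectly (a single
  clade); low RI is the signature of homoplasy — horizontal gene transfer
  or repeated independent gain and loss. Pathways with `RI > 0.9` are
  classified *consistent* with the phylogeny, `RI < 0.7` *inconsistent*;
- a single most-parsimonious **ancestral reconstruction**, from which every
  gain (0→1) and loss (1→0) is **clocked** on a scaled node-age axis
  (mean-path-length dating, root age fixed at 100, extant tips at 0);
- **reduced subtrees**: maximal clades lacking the pathway collapse to
  placeholder tips, and nodes are colored red (gain) / blue (loss), so the
  number of non-root colored nodes equals the parsimony score.

Around this core the package provides the supporting machinery such an
analysis needs: Newick I/O and tree comparison (Robinson–Foulds distance,
branch score), genome QC and pathway-confidence filtering, genus-level
profile aggregation with Manhattan-distance hierarchical clustering,
HMMER-domtblout-based annotation transfer with e-value/coverage filters,
GO biological-process enrichment (classic Fisher + the elim decorrelation),
and a fully seeded synthetic-data generator so the entire pipeline is
testable without any external corpus.

Intended users: microbial comparative genomicists and method developers who
want a tested, scriptable implementation of pathway-character analysis on
large genome trees.

## Worked example

Score one pathway on a six-genome tree:

```python
import funcphylo as fp
from funcphylo.parsimony_analysis import retention_index

tree = fp.parse_newick("(((G1:1,G2:1):1,(G3:1,G4:1):1):1,(G5:2,G6:2):1);")
ch = fp.BinaryCharacter(
    "PWY-EX", {"G1": 1, "G2": 1, "G3": 1, "G4": 0, "G5": 0, "G6": 0}
)
s = fp.fitch_score(tree, ch)              # 2
res = retention_index(ch.n_present, 6, s)
print(s, res.g, res.m, res.ri)            # 2 3 1 0.5
print(fp.classify_consistency(res.ri))    # inconsistent

anc = fp.fitch_ancestral(tree, ch)
ages = fp.assign_node_ages(tree)          # root at 100, tips at 0
for ev in fp.change_events(tree, anc, ages):
    print(ev.direction, ev.age_mid)
```

prints

```
2 3 1 0.5
inconsistent
gain 83.33333333333334
loss 16.666666666666668
```

The pathway needs two changes (`s = 2`); three genomes carry it, so up to
`g = 3` changes could have been needed, and `m = 1` since both states occur:
`RI = (3 − 2)/(3 − 1) = 0.5`, an inconsistent (homoplastic) character. The
reconstruction places an old gain (midpoint age 83 on the 0–100 clock)
and a recent loss on the branch to G4. Reducing the subtree collapses the
pathway-free clade (G5, G6) to one placeholder tip:

```python
sub = fp.reduce_subtree(tree, ch, anc)
print(sub.to_newick())
# (((G1:1.0,G2:1.0)N3:1.0,(G3:1.0,1_absent_G4:1.0)N4:1.0)N2:1.0,2_absent_G5:3.0)N1;
print(sub.n_colored_nonroot)  # 2 == parsimony score
```

The same analysis runs end-to-end from files (tree Newick, metadata TSV,
pathway-report TSVs) via `funcphylo score-pathways ...`, and
`funcphylo simulate --seed 1 --out corpus/` writes a complete synthetic
corpus to experiment with. See `funcphylo --help` for the other
subcommands (`compare-trees`, `cluster-genera`, `enrich`, `reduce-subtree`).

## Layout

- `src/funcphylo/tree_core.py` — tree model, Newick I/O, bipartitions,
  RF/branch-score, node ages
- `src/funcphylo/parsimony_analysis.py` — Fitch/Hartigan, retention index,
  classification, event clocking
- `src/funcphylo/subtree_reduction.py` — collapsed, colored subtrees
- `src/funcphylo/profile_matrix.py` — QC, pathway matrices, genus
  aggregation, clustering
- `src/funcphylo/annotation_filtering.py` — domtblout parsing, coverage and
  e-value filters, family-annotation rules
- `src/funcphylo/go_enrichment.py` — OBO loading, Fisher, elim
- `src/funcphylo/synthetic_data.py` — seeded generators and fixture corpora
- `src/funcphylo/pipeline.py`, `src/funcphylo/cli.py` — orchestration and
  the `funcphylo` command

Methodological details and design choices are documented in
[`docs/methods.md`](docs/methods.md).
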