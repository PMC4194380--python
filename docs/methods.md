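# Methods

## Characters on trees

Every metabolic pathway is a binary character observed at the tips of a
rooted genome tree: state 1 if the pathway was inferred for that genome
with sufficient confidence, 0 otherwise. Trees are stored rooted with child
order preserved from the Newick input; branch lengths are substitutions per
site and may be 0 (missing lengths parse as 0 with a warning, since Newick
dialects disagree about omitted lengths).

### Parsimony score

The parsimony score `s` of a character is computed with Fitch's two-pass
algorithm. The downward pass uses Hartigan's majority-vote generalization:
at a node with children whose state sets vote `c(x)` times for state `x`,
the node's preliminary set is the argmax set and the score increases by
(number of children − max vote). On strictly bifurcating trees this reduces
to the classical intersection/union rule; on multifurcations it keeps the
score minimal, which matters because published genome trees routinely
contain polytomies.

The upward pass commits one most-parsimonious labeling: each node takes its
parent's state when that state is in its preliminary set, otherwise its
unique preliminary state. We deliberately report a single reconstruction
rather than the full set of most-parsimonious reconstructions — downstream
event clocking and subtree drawing need one concrete history. When the
root's preliminary set is ambiguous (`{0, 1}`), the root is assigned 0
(absent) by default: absent-at-root is the conservative choice when a
character's deep history is genuinely undecidable, and it avoids inferring
ancient presence for characters that may have arisen late and spread
horizontally. The tie rule is configurable (`root_tie=1` or
`root_tie="majority"`).

### Retention index

For a binary character present in `p` of `N` genomes,

    g  = min(p, N − p)          maximum changes any tree could require
    m  = 1 if 0 < p < N else 0  minimum changes any tree could require
    RI = (g − s) / (g − m)

`RI = 1` means the character is compatible with a single clade; values near
0 mean the character is as homoplastic as its frequency allows. Two
degenerate cases are closed by convention: constant characters (`g = 0`,
formula 0/0) return `RI = 1.0` with a `constant` flag so classification
stays total; characters with a single minority tip (`g = m = 1`, again 0/0)
also return 1.0, since `s` is forced to the minimum. Reported RI values are
rounded half-up to two decimals, matching the convention of the reference
corpus statistics; full precision is kept internally. Classification uses
`RI > 0.9` (consistent) and `RI < 0.7` (inconsistent), with everything
between labeled intermediate.

### Node ages and event clocking

Rate-smoothing dating tools are deliberately out of scope; only the
*relative order* of events is analyzed downstream, so a simple estimator
suffices. Each internal node's raw age is its mean path length (MPL) to its
descendant tips; ages are then clamped upward so no parent is younger than
a child (clamp first, then rescale), and finally rescaled linearly so the
root sits at 100 and extant tips at 0. On ultrametric trees MPL equals the
true node depth; on non-clock trees it is a standard first-order
approximation.

A reconstruction places each change on one branch but not at a point, so an
event's age is the interval between its branch's endpoint ages; the
reported point age is the interval midpoint. The number of events always
equals the parsimony score of the reconstruction.

### Reduced subtrees

To visualize where a pathway lives, every maximal clade whose tips all lack
it collapses to a single placeholder tip labeled
`<size>_absent_<first tip>`, with branch length spanning from the
attachment point to the clade's farthest original tip (so the drawing
preserves depth). The root is colored by its state (red = present,
blue = absent); every other retained node is colored red/blue exactly when
its state differs from its parent's. Because a maximal all-absent clade is
internally change-free under parsimony, the non-root colored nodes are in
bijection with the reconstruction's changes — their count equals `s`. The
root's color conveys state only and is never counted as a change: a root
state is not a change on any branch, so for root-present characters a
figure that counted the red root would read one higher than the score.
Output is plain Newick plus a TSV sidecar (node id, color, state, green
flag for edges descending from presence-state nodes), since color-bearing
Newick comment dialects are not portable.

## Tree comparison

Bipartitions are computed on the unrooted view of the tree: one non-trivial
split per internal edge, with a degree-2 root contributing a single edge
(its two child edges merge, lengths summed). The Robinson–Foulds distance
is the size of the symmetric difference of the two split sets; the branch
score is the Euclidean norm of length differences over the union of splits
(absent splits count length 0), over internal branches only, mirroring
comparisons against total internal branch length.

## Profiles, aggregation, clustering

Genome QC discards assemblies with more than 1000 contigs (fragmentation)
or fewer than 400 predicted genes (implausibly small for a prokaryote).
Pathway calls with confidence below 70 are dropped; the confidence factor
is treated as an opaque score from the upstream pathway-inference tool.
Duplicate report rows for the same (genome, pathway) collapse by maximum
confidence — presence is an existential claim. The pathway universe is the
union observed across input files.

A genus profile is the element-wise OR over its member genomes (a pan-genome
profile), which damps the heavy sequencing bias toward a few genera.
Clustering of genera and of pathways uses Manhattan distance — on 0/1
vectors, the count of differing pathways — with complete linkage by default
(single and average are available). Rows are sorted lexicographically by id
before clustering, making the output invariant to input order with a
deterministic tie-break. Dendrograms are exported as Newick with
merge-height differences as branch lengths.

## Annotation transfer

Protein-to-family matches come from HMMER3 per-domain tabular output
(domtblout, hmmscan orientation: target = HMM family, query = protein).
Domain rows of one (query, family) pair aggregate into one hit. A hit
survives if its whole-sequence e-value is strictly below 1e-3 and its
aligned regions cover at least 50% of both the query and the HMM; the
regions need not be contiguous, so intervals are merged (overlaps and
adjacencies coalesced) before summation, and coverage is computed over all
domains of the hit rather than the best single domain. Each query receives
its best surviving family by smallest e-value, ties broken by
lexicographically smallest family id (a documented determinism choice; the
threshold semantics are: e-value strict `<`, coverage inclusive `≥`).
Family annotations are field-wise set unions (product names, EC numbers,
gene names, GO terms) over curated member proteins; cluster validity
requires every member to exceed 80% identity to the centroid and the
shortest member to exceed 80% of the longest member's length (both strict).

## GO enrichment

The ontology is restricted to non-obsolete terms and `is_a` edges;
annotation follows the true-path rule (a gene annotated to a term is
annotated to all ancestors). The per-term test is the one-sided
hypergeometric over-representation p-value. The elim procedure processes
terms deepest-first (longest path to a root); when a term's p-value is
≤ 0.01, its annotated genes are removed from all ancestors before those
are tested, preventing one specific signal from dragging its general
ancestors into the report. Reported terms must be annotated to more than 10
background genes and have elim p ≤ 0.01; ranking is by ascending elim
p-value with term-id tie-break. (Ranking by the "weight" decorrelation
algorithm is not implemented; elim ordering is the package's documented
substitute.) Whether the sampling unit is genes or genomes is ambiguous in
aggregate taxon comparisons; the pipeline pools genes (study set = all
genes of the taxon's genomes, universe = all genes of all kept genomes) and
reports are labeled accordingly.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular organism collection:

- **Tree**: Yule (pure-birth), splitting a uniformly chosen extant lineage
  at exponential waiting times, all extant branches extended by each wait —
  hence ultrametric. Default 200 tips, birth rate 1. Extinction is omitted:
  it changes branch-length profiles but adds nothing to what these tests
  can falsify.
- **Vertical characters**: a 2-state continuous-time Markov chain run down
  every branch with exact exponential waiting times, so the full true event
  list exists and the parsimony score can be checked as a lower bound on
  it. Defaults: root present, loss rate 0.0075 and gain rate 0.002 per unit
  branch length. On the default tree (total length ≈ 200) this yields ~1.5
  loss events per character — the change-per-genome rate of a stably
  maintained, widely distributed pathway, scaled down to 200 tips. Note a
  homogeneous chain on an ultrametric Yule tree places about half of all
  events on pendant branches, so simulated "consistent" characters are
  noisier than real clade-borne pathways, whose losses concentrate on
  deeper branches; regime-separation checks are therefore statistical
  majorities at a fixed seed, not per-character guarantees.
- **Scattered characters**: presence planted in k tips drawn uniformly
  without replacement (default k = 30, ~15% occupancy) — the limiting
  pattern of rampant horizontal transfer, with no phylogenetic signal by
  construction.
- **Genera**: contiguous blocks of tips in tree traversal order (default 5
  genomes per genus), an approximation of clade-structured taxonomy that
  gives genus aggregation real signal without exact clade partitioning.
- **Fixture corpora**: schema-conformant files for every consumed format
  (tree Newick, metadata TSV, pathway reports, domtblout, gene→GO TSV, OBO
  stub), with planted violations of each QC and filter clause and a planted
  enriched term, so filter tests can assert exact recovery.

All generators are pure functions of (config, seed); identical seeds give
byte-identical fixture files.

What passing these tests does **not** show: real pathway calls carry
correlated errors (annotation coverage, draft-genome fragmentation) that
the independent-noise fixtures do not model; real trees are non-ultrametric
with reconstruction error; and real HGT is biased toward ecological
neighbors rather than uniform over tips.

## Numerical and scale choices

- Fisher p-values use the exact hypergeometric survival function; tests
  cross-check against full fraction-arithmetic enumeration for all tables
  with universe ≤ 40.
- Newick serialization prints shortest round-trip decimals (`repr`), so
  parse∘write is the identity on lengths.
- Test problem sizes: brute-force parsimony oracles run on 200 trees of
  ≤ 10 tips (exhaustive over internal labelings), reconstruction identities
  on 500 characters over a 100-tip tree, regime separation on 50 + 50
  characters over a 200-tip tree, split oracles on all same-size pairs of
  52 trees of 5–8 tips. These sizes fully exercise the combinatorics while
  keeping the default suite fast.
- Degenerate inputs: trees with < 4 tips have no bipartitions; zero-depth
  trees cannot be dated (error); all-absent pathways reduce to a warned
  single-tip subtree; constant characters are flagged rather than dropped.

## Known limitations

- Single most-parsimonious reconstruction (no MPR enumeration, no Dollo or
  weighted parsimony, no likelihood/Bayesian ancestral states).
- MPL dating is a crude clock; absolute ages are not meaningful, only
  relative order.
- The elim implementation covers the reporting path used here; the "weight"
  algorithm and non-`is_a` edge types are not implemented.
- Genus assignment in simulations is block-contiguous, not strictly
  clade-defined.
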