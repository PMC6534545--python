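# Methods

## Ontology model and ingestion

Terms and their child→parent relations form a rooted directed acyclic
graph (`OntologyDAG`). The OBO reader supports the format-1.2 tags `id`,
`name`, `namespace`, `is_a`, `relationship`, `is_obsolete` and `alt_id`;
relationship types are filtered against a caller-supplied whitelist at
parse time (typically only `is_a` for biological process, all types for
cellular component). Obsolete terms are recorded but contribute no
relations; relations with undefined endpoints are dropped with a warning;
cycles are a hard error, because the ontology is a DAG by definition.
Annotation tables follow the NCBI `gene2go` column layout (`tax_id`,
`GeneID`, `GO_ID`, `Evidence`, optional `Qualifier`); all evidence codes
are kept by default, with an optional evidence filter, and `NOT`-qualified
rows are dropped by default (qualifier semantics beyond a wholesale
keep/drop flag are out of scope — the flag is exposed because curation
practice on NOT annotations varies between analyses).

True-path propagation computes, in a children-before-parents topological
order, `genes(t) = direct(t) ∪ ⋃_child genes(child)`. Unions are
order-free, so the result is independent of traversal details, and the
operation is idempotent. The resulting parent-superset invariant is what
every downstream algorithm relies on; it is validated explicitly where it
is load-bearing (the buoyant layout refuses to run without it and names
the offending edge).

## DAG refinement and size filtering

A parent whose propagated gene set equals that of one of its children
would produce an identical term-level test statistic, inflating the
multiplicity burden with no information gain. Refinement removes such
parents iteratively until none remain. The iteration schedule is a design
choice here: at each step the *deepest* redundant parent is removed (ties
broken by term id), with edges added from each of its parents to each of
its children before deduplication. Depth-first removal plus reconnection
makes the procedure deterministic and preserves every ancestor relation
among the survivors, which tests verify against a brute-force
transitive-closure oracle. The output is a fixed point: refining twice
equals refining once.

Node-size filtering keeps terms whose size lies in `[min_size, max_size]`
and applies the same reconnection rule, so dropping an intermediate term
never severs kept ancestors from kept descendants. (Under the superset
invariant a contiguous size window can never actually break a chain — the
middle of a chain is never outside a window containing both ends — but the
reconnection is kept so the operation behaves sensibly on any size
assignment.)

## Context and focus subDAGs

Context anchors select a subDAG: a `root` anchor contributes its
descendants, a `leaf` anchor its ancestors, a `waypoint` anchor both, each
including the anchor; multiple anchors of mixed roles combine by union
(the weakest combination rule consistent with per-anchor role semantics).
Focus extraction works within a context and keeps the display bounded:
anchors are limited to `max_anchors` (default 10), all context-ancestors
of each anchor are always shown, and a waypoint anchor's full descendant
closure is expanded only when that closure has at most `expansion_cap`
nodes (default 50) — otherwise only its immediate children appear. The
cap test is per anchor, on the closure including the anchor itself. When
no focus anchors are given, the context anchors are reused in the leaf
role. Both defaults are configurable; they are display-budget choices,
not statistical ones.

## Leveled layouts

*Root-bound*: level = longest path length from any root. *Leaf-bound*:
longest path length to any leaf, flipped so leaves sit on the bottom level
and level 0 stays at the top. Both satisfy the topological constraint
(parents strictly above children) and are computed by dynamic programming
over a topological order.

*Buoyant*: additionally requires that a term with fewer annotated genes is
never placed above a term with more. The bubble float algorithm first
sorts all nodes lexicographically by (node size descending, longest root
distance ascending, term id ascending — the last key is a determinism
tie-break). Under the superset invariant every ancestor precedes its
descendants in this order: an ancestor is at least as large, and strictly
closer to the root at equal size. The scan then walks the order from the
bottom, keeping one open (bottom-most) layer; the next node joins it
unless one of its strict descendants is already in the layer (which would
violate the topological constraint, directly or transitively) or the
layer's size span would exceed `max_span`; otherwise the layer closes and
a new one opens above. Levels are therefore contiguous blocks of the
initialization order, which makes the descending-size constraint hold by
construction, and greedy maximal merging minimizes the level count
subject to that scan order. `max_span` is the absolute difference of gene
counts allowed within one level (off by default); it trades fewer levels
for tighter within-level size homogeneity. Exhaustive enumeration on
small instances confirms the output is always a constraint-valid
contiguous-block partition and equals independent re-derivations of the
greedy merge.

*Within-level ordering*: anchors sharing a common ancestor below the roots
are grouped; non-anchor nodes related (ancestor or descendant) to exactly
one group are absorbed into it, iterating to a fixed point so relatives
reached only through absorbed members are captured. Within each level the
primary sort key is the group, keeping groups contiguous; the secondary
key is the barycenter of neighbor positions in the adjacent level,
refined by up to four alternating downward/upward sweeps (crossing
minimization is NP-hard, so a bounded heuristic is used); term id breaks
remaining ties, making the order deterministic.

*Silhouette and binder order*: the context silhouette counts terms per
level, plus the per-level count of terms ancestral or descendent to a
highlight set (highlighted terms count themselves). The binder order
arranges terms linearly by non-increasing node size, ties by buoyant
level then term id, and reports the indices where the level changes so a
renderer can draw alternating level bands.

## Power simulation

Ground truth: for each chosen term, `ceil(fraction · size)` genes are
sampled uniformly without replacement (seeded); the union over terms is
the DE set. Non-null classification follows the two standard frameworks;
the competitive definition uses a strict inequality for non-nullness (a
term whose inside-DE fraction merely equals the outside fraction is null),
and terms annotated with the whole universe are excluded from competitive
testing since they have no complement.

Expression: controls ~ N(0, I), cases ~ N(μ, I) over the g universe
genes, μ = β_effect at DE genes. An optional equicorrelation parameter ρ
replaces I with an exchangeable covariance (a shared per-sample factor),
default 0. Gene p-values use the pooled-variance two-sample t-test — the
generative model has equal unit variances, so pooling is the matched
choice rather than Welch. A zero-pooled-variance gene (possible only in
degenerate inputs) is reported as p = 1 with a warning.

Term statistics: Simes for self-contained tests; for competitive tests
genes are first called significant at a gene-wide threshold — Bonferroni
at 0.05/g by default, configurable — and the term's overlap with the
significant set is tested against the hypergeometric upper tail.
Multiplicity is corrected over the family of all tested terms with BH by
default (Bonferroni available; the correction argument accepts any
callable with the same signature, so other procedures can be plugged in).
Refinement upstream is recommended so no two tested terms are identical.
Simes p-values under positive dependence are known to be conservative in
combination with BH in practice; the simulator reports empirical FDP
rather than claiming finite-sample control for every configuration.

Replications: one master `SeedSequence` spawns independent child streams
per grid point and per replication, so grid points are statistically
independent, reproducible, and insensitive to evaluation order.

## Synthetic fixtures

The generator lays `n_terms` terms on a random topological order with
exactly `n_roots` roots; each non-root term draws 1..`max_parents` parents
among earlier terms. Every gene in the `n_genes` pool annotates one term
drawn with leaf-weighted (depth-proportional) probability — mimicking the
concentration of curation at specific terms — and a second term with
probability `direct_annotation_rate`; every leaf additionally receives at
least one gene. The propagated annotations therefore satisfy the superset
invariant by construction and the gene universe equals the pool size.
Default scale is 60 terms over 600 genes, the size regime used throughout
the examples and the reproduction script; small enough to iterate on,
large enough that the hypothesis family and DE fractions are non-trivial.

What the fixtures do **not** emulate: the real GO's degree distribution
and depth profile, annotation noise, inter-gene expression correlation
(unless ρ is set), and library-size or batch structure in the single-cell
model. Passing tests demonstrate algorithmic correctness and calibration
under the stated generative models, not performance on any particular GO
release.

## Single-cell simulator

Counts are zero-inflated negative binomial: NB with mean m and size
(dispersion) r — variance m + m²/r — then zeroed with probability
`dropout_prob`, giving marginal mean (1 − dropout_prob)·m. Signature
genes are sampled per chosen term (10 per term by default, disjoint across
terms: a gene annotating several chosen terms belongs to the first term
that samples it); a signature gene uses `signature_mean` (default 8.0) in
cells of its own type and `baseline_mean` (default 1.0) elsewhere;
`dispersion` defaults to 2.0 and `dropout_prob` to 0.3; cell counts
default to (120, 150, 100) per signature type plus 300 baseline cells.
The structure (three signatures over a baseline population, 10 genes
each) is the canonical use case; the rate parameters are package defaults
chosen to give clearly separable cell types at realistic sparsity.
Dropout is uniform across genes and cells by default; a mean-dependent
dropout curve can be supplied via configuration but is off by default.

## Numerical and degenerate-case choices

- All stochastic functions take either a seed or a `numpy` Generator;
  equal seeds give bitwise-equal outputs.
- Empty DAGs and single-node DAGs are valid inputs everywhere; an empty
  p-value list for Simes is an error (the term should have been excluded
  from the family upstream).
- Set unions and sorted term ids are used at every ordering decision, so
  no output depends on hash order.
- The acceptance script and the test-suite simulations use 50–100
  replications on the 60-term / 600-gene fixture; these sizes give
  Monte-Carlo standard errors around 0.002–0.06 on the reported
  means, which is the resolution the checks require.

## Known limitations

- The refinement schedule (deepest-first, one removal at a time) is one
  deterministic member of the family of fixed-point schedules; other
  orders can yield different but equally valid refined DAGs when multiple
  redundant parents overlap.
- Barycenter sweeps do not guarantee crossing-minimal orderings (the
  problem is NP-hard); four sweeps is a display heuristic.
- The competitive pipeline's gene-significance threshold materially
  affects power; the Bonferroni default is conservative.
- The expression model is Gaussian with homoscedastic noise; it is a
  design-stage approximation, not an RNA-seq count model (the single-cell
  ZINB module is the count-model counterpart).
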