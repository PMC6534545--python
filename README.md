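# goscope

Tools for navigating the Gene Ontology (GO) as a graph and for planning GO
enrichment studies. The package is aimed at computational biologists who
work with the GO DAG directly: it ingests OBO ontologies and NCBI
`gene2go`-style annotation tables, propagates annotations under the
true-path rule, collapses statistically redundant terms, extracts
anchor-based subDAGs for display, computes annotation-aware leveled graph
layouts, and runs a power/FDR simulator for term-level enrichment tests.
A zero-inflated negative binomial single-cell count simulator with
GO-signature cell types is included for building structured test data.

## What it computes

**DAG model.** GO terms form a rooted DAG with child→parent "is a"-style
edges. After true-path propagation, the gene set of a term t is

    genes(t) = direct(t) ∪ ⋃_{c child of t} genes(c)

so `genes(parent) ⊇ genes(child)` on every edge; `|genes(t)|` is the *node
size* of t. *DAG refinement* iteratively removes any parent annotated with
exactly the gene set of one of its children (their test statistics would be
identical), reconnecting the removed parent's parents to its children so
every ancestor relation among surviving terms is preserved.

**Buoyant layout.** Classical topological levelings (*root-bound*: level =
longest distance from a root; *leaf-bound*: mirror on the reversed graph)
can place a term with few annotated genes above a much larger term. The
*buoyant* leveling enforces two constraints at once:

1. topological — every parent strictly above its children;
2. descending node size — a smaller term is never above a larger one.

It is computed by the *bubble float* algorithm: sort nodes by (size
descending, longest root distance ascending, term id), then scan from the
bottom, greedily merging consecutive nodes into the current layer while
both constraints (and an optional per-level size-span cap) hold. The
result always has at least as many levels as the root-bound layout.

**Power simulation.** Given truly differentially expressed (DE) genes
(chosen as all or a fraction of the annotation of selected terms), each
term is non-null

* *self-contained*: iff its annotation intersects the DE set;
* *competitive*: iff its genes are DE strictly more often than the genes
  outside it.

Expression data are drawn as controls ~ N(0, I), cases ~ N(μ, I) with
μ = β_effect at DE genes; gene p-values come from a pooled two-sample
t-test; term p-values from Simes' rule
`p_term = min_k (m · p_(k) / k)` (self-contained) or an upper-tail
hypergeometric over-representation test on the significant-gene overlap
(competitive); Benjamini–Hochberg (or Bonferroni) at level q selects the
rejection set R. With non-null set A₁,

    Power = |A₁ ∩ R| / max(|A₁|, 1),   FDP = |R \ A₁| / max(|R|, 1)

and mean FDP over replications estimates the FDR.

## Worked example

Everything runs on synthetic GO-like fixtures, so no downloads are needed:

```python
from goscope import fixtures as fx
from goscope.dag import refine_dag
from goscope.ontology_io import propagate_annotations
from goscope.layout import buoyant_levels, root_bound_levels
from goscope.power import SimulationConfig, designate_ground_truth, run_power_study

dag, direct = fx.random_godag(fx.FixtureSpec(n_terms=60, n_genes=600, seed=1))
ann = propagate_annotations(dag, direct)
refined = refine_dag(dag, ann)
rann = ann.restrict(refined.terms)

lv = buoyant_levels(refined, rann)
print("buoyant levels:", lv.n_levels,
      " root-bound levels:", root_bound_levels(refined).n_levels)

mid = sorted(refined.terms, key=rann.size)[len(refined.terms) // 2]
de = designate_ground_truth(refined, rann, {mid}, 1.0, seed=1)
cfg = SimulationConfig(beta_effect=1.0, q=0.1, reps=100, seed=1)
report = run_power_study(refined, rann, de, cfg, grid=[(10, 10), (50, 50)])
print(report.summary().to_string(index=False))
```

prints

```
buoyant levels: 12  root-bound levels: 11
 n_control  n_case  mean_power  mean_fdp  sd_power   sd_fdp
        10      10    0.604792  0.018753  0.214542 0.022323
        50      50    0.995208  0.019230  0.013843 0.019893
```

The buoyant layout needs one extra level to respect the node-size ordering.
All 61 genes of the mid-size term `T0040` are designated DE; at n = 10
per group the BH-adjusted self-contained (Simes) tests recover about 60 %
of the non-null terms, at n = 50 essentially all of them, while the mean
false discovery proportion stays near 0.02 — well inside the nominal
q = 0.1.

The same pipeline is scriptable from a shell:

```sh
goscope fixture --spec-seed 1 --out fix/
goscope layout --bundle fix/dag.json --kind buoyant --svg --out lay/
goscope power --bundle fix/dag.json --reps 100 --grid 10:10,50:50 --out pw/
goscope simulate-sc --bundle fix/dag.json --out sc/
```

Each output directory contains a `manifest.json` with the seed, the
configuration hash and the input-source identity; identical configurations
give byte-identical outputs.

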