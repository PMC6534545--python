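"""Synthetic GO-like fixtures: random rooted DAGs with true-path-consistent
annotations, plus small hand-checkable instances.

The random generator lays terms on a random topological order, gives each
non-root term one to ``max_parents`` parents among earlier terms, and places
direct annotations with a leaf-weighted bias (most curation in real
ontologies attaches to specific terms), guaranteeing every leaf at least one
gene.  After true-path propagation the parent-superset invariant holds by
construction, so the fixtures exercise refinement and the buoyant layout
with realistic size gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dag import OntologyDAG
from .ontology_io import DirectAnnotations

__all__ = ["FixtureSpec", "random_godag", "worked_fixtures"]


@dataclass(frozen=True)
class FixtureSpec:
    n_terms: int = 60
    n_genes: int = 600
    n_roots: int = 1
    max_parents: int = 3
    direct_annotation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1 or self.max_parents < 1:
            raise ValueError("need n_roots >= 1 and max_parents >= 1")
        if self.n_terms < self.n_roots:
            raise ValueError("n_terms must be >= n_roots")


def random_godag(spec: FixtureSpec) -> tuple[OntologyDAG, DirectAnnotations]:
    """Generate a random rooted DAG plus direct annotations (seeded)."""
    rng = np.random.default_rng(spec.seed)
    ids = [f"T{i:04d}" for i in range(spec.n_terms)]
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    edges: list[tuple[str, str]] = []
    for i in range(spec.n_roots, spec.n_terms):
        k = int(rng.integers(1, spec.max_parents + 1))
        k = min(k, i)
        parents = rng.choice(i, size=k, replace=False)
        edges.extend((ids[i], ids[int(p)]) for p in parents)
    dag = OntologyDAG({t: f"term {t}" for t in ids}, sorted(edges))

    # leaf-weighted direct annotation: every gene annotates one term drawn
    # with depth-proportional weight (specific terms get most curation), and
    # with probability `direct_annotation_rate` a second term as well
    depth: dict[str, int] = {}
    for t in reversed(dag.topological_order()):
        ps = dag.parents(t)
        depth[t] = 1 + max(depth[p] for p in ps) if ps else 0
    w = np.array([1.0 + depth[t] for t in ids])
    w /= w.sum()
    pairs: set[tuple[str, str]] = set()
    leaves = sorted(dag.leaves)
    for j, leaf in enumerate(leaves):  # every leaf gets at least one gene
        pairs.add((genes[j % len(genes)], leaf))
    for g in genes:
        pairs.add((g, ids[int(rng.choice(spec.n_terms, p=w))]))
        if rng.random() < spec.direct_annotation_rate:
            pairs.add((g, ids[int(rng.choice(spec.n_terms, p=w))]))
    return dag, DirectAnnotations(pairs)


def worked_fixtures() -> dict[str, tuple[OntologyDAG, DirectAnnotations]]:
    """Tiny hand-checkable DAG + annotation bundles.

    * ``chain3`` — A←B←C with one gene at C; propagation gives every term
      {g1}.
    * ``diamond`` — A←B, A←C, B←D, C←D with distinct propagated sets
      (refinement is a no-op).
    * ``buoyant4`` — R{5 genes} with children A{4} and B{1}; A has child
      C{2}.  Buoyant levels are [R], [A], [C, B]: B may not sit above C
      because 1 < 2.
    * ``refine-chain`` — A←B←C all propagating to {g1}; refinement collapses
      the chain to the deepest term C.
    * ``star`` — root R, children c1..c5, three grandchildren each (21
      terms), for focus-graph expansion-cap checks.
    """
    fixtures: dict[str, tuple[OntologyDAG, DirectAnnotations]] = {}

    chain = OntologyDAG({"A": "a", "B": "b", "C": "c"}, [("B", "A"), ("C", "B")])
    fixtures["chain3"] = (chain, DirectAnnotations({("g1", "C")}))
    fixtures["refine-chain"] = (chain, DirectAnnotations({("g1", "C")}))

    diamond = OntologyDAG(
        {"A": "a", "B": "b", "C": "c", "D": "d"},
        [("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")],
    )
    fixtures["diamond"] = (
        diamond,
        DirectAnnotations({("g1", "D"), ("g2", "B"), ("g3", "C"), ("g4", "A")}),
    )

    buoyant = OntologyDAG(
        {"R": "root", "A": "a", "B": "b", "C": "c"},
        [("A", "R"), ("B", "R"), ("C", "A")],
    )
    fixtures["buoyant4"] = (
        buoyant,
        DirectAnnotations(
            {("g1", "C"), ("g2", "C"), ("g3", "A"), ("g4", "A"), ("g5", "B")}
        ),
    )

    star_terms = {"R": "root"}
    star_edges = []
    pairs: set[tuple[str, str]] = set()
    gi = 0
    for i in range(1, 6):
        c = f"c{i}"
        star_terms[c] = c
        star_edges.append((c, "R"))
        for j in range(1, 4):
            gc = f"c{i}x{j}"
            star_terms[gc] = gc
            star_edges.append((gc, c))
            pairs.add((f"g{gi}", gc))
            gi += 1
    fixtures["star"] = (OntologyDAG(star_terms, star_edges), DirectAnnotations(pairs))
    return fixtures
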