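"""Leveled graph layouts for ontology DAGs.

Three levelings are provided.  The *root-bound* and *leaf-bound* layouts are
standard Sugiyama-style topological levelings: a node's level is its longest
distance to the roots, respectively to the leaves.  The *buoyant* layout is
annotation-aware and satisfies two constraints simultaneously:

* **topological constraint** — every parent sits strictly above all of its
  children;
* **descending node size constraint** — a term annotated with fewer genes is
  never placed above a term annotated with more genes.

The buoyant leveling is computed by the *bubble float* algorithm: nodes are
first sorted lexicographically by (descending node size, ascending longest
distance to the root, term id); then, scanning that order from the bottom, a
*float* operation greedily merges consecutive nodes into the current bottom
layer as long as both constraints (and an optional node-size span cap per
level) remain satisfied.  Because ancestors always precede their descendants
in the initialization order (annotation supersets guarantee ancestors are at
least as large, and strictly closer to the root at equal size), the greedy
scan only ever needs to check descendants already placed in the open layer,
and the resulting levels are contiguous blocks of the initialization order.

Also here: within-level ordering (anchor grouping + barycenter crossing
reduction), the per-level context silhouette, and the linear binder-plot
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dag import Anchor, AnchorSpec, AnnotationMap, OntologyDAG

__all__ = [
    "LeveledLayout",
    "ContextSilhouette",
    "BinderOrder",
    "root_bound_levels",
    "leaf_bound_levels",
    "buoyant_levels",
    "initialization_order",
    "order_within_levels",
    "context_silhouette",
    "binder_order",
]


@dataclass
class LeveledLayout:
    """A level assignment plus within-level order; level 0 is the top (roots)."""

    level_of: dict[str, int]
    levels: list[list[str]]
    kind: str  # root_bound | leaf_bound | buoyant

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def check_topological(self, dag: OntologyDAG) -> bool:
        """Every parent strictly above (smaller level than) each child."""
        return all(self.level_of[p] < self.level_of[c] for c, p in dag.edges)

    def check_descending_size(self, ann: AnnotationMap) -> bool:
        """No smaller term ever above a larger one.

        Checking adjacent levels suffices: min(level i) >= max(level i+1)
        chains into the condition for every pair of levels.
        """
        hi = [max(ann.size(t) for t in lv) for lv in self.levels]
        lo = [min(ann.size(t) for t in lv) for lv in self.levels]
        return all(lo[i] >= hi[i + 1] for i in range(len(self.levels) - 1))


@dataclass
class ContextSilhouette:
    """Per-level node counts of a context DAG, with a highlighted subset."""

    total_per_level: list[int]
    highlighted_per_level: list[int]


@dataclass
class BinderOrder:
    """Linear node order by descending annotation count with level bands."""

    sequence: list[str]
    level_of: dict[str, int]
    band_boundaries: list[int] = field(default_factory=list)  # index where level changes


# ---------------------------------------------------------------------------
# topological levelings
# ---------------------------------------------------------------------------


def _longest_to_root(dag: OntologyDAG) -> dict[str, int]:
    dist: dict[str, int] = {}
    for t in reversed(dag.topological_order()):  # parents first
        ps = dag.parents(t)
        dist[t] = 1 + max(dist[p] for p in ps) if ps else 0
    return dist


def _longest_to_leaf(dag: OntologyDAG) -> dict[str, int]:
    dist: dict[str, int] = {}
    for t in dag.topological_order():  # children first
        cs = dag.children(t)
        dist[t] = 1 + max(dist[c] for c in cs) if cs else 0
    return dist


def _levels_from_assignment(level_of: dict[str, int], order: Sequence[str]) -> list[list[str]]:
    n = max(level_of.values(), default=-1) + 1
    levels: list[list[str]] = [[] for _ in range(n)]
    for t in order:
        levels[level_of[t]].append(t)
    return levels


def root_bound_levels(dag: OntologyDAG) -> LeveledLayout:
    """Level = longest path length from any root to the node."""
    level_of = _longest_to_root(dag)
    return LeveledLayout(level_of, _levels_from_assignment(level_of, dag.terms), "root_bound")


def leaf_bound_levels(dag: OntologyDAG) -> LeveledLayout:
    """Level = (height of the DAG) − (longest path length to any leaf).

    Leaves sit on the bottommost level; the topological constraint still
    holds with level 0 at the top.
    """
    to_leaf = _longest_to_leaf(dag)
    height = max(to_leaf.values(), default=0)
    level_of = {t: height - d for t, d in to_leaf.items()}
    return LeveledLayout(level_of, _levels_from_assignment(level_of, dag.terms), "leaf_bound")


# ---------------------------------------------------------------------------
# buoyant leveling (bubble float)
# ---------------------------------------------------------------------------


def initialization_order(dag: OntologyDAG, ann: AnnotationMap) -> list[str]:
    """Lexicographic order: size descending, root distance ascending, id."""
    dist = _longest_to_root(dag)
    return sorted(dag.terms, key=lambda t: (-ann.size(t), dist[t], t))


def buoyant_levels(
    dag: OntologyDAG, ann: AnnotationMap, max_span: float | None = None
) -> LeveledLayout:
    """Bubble float algorithm: greedy bottom-up maximal layer merging.

    Walking the initialization order from the bottom, the next node joins the
    current (bottom-most open) layer unless one of its descendants is already
    in that layer (which would break the topological constraint) or the
    layer's node-size span would exceed ``max_span``; otherwise the layer is
    closed and a new one starts above it.  Levels are therefore contiguous
    blocks of the initialization order, which makes the descending-size
    constraint hold by construction.
    """
    ann.check_superset_invariant(dag)
    order = initialization_order(dag, ann)
    layers_bottom_up: list[list[str]] = []
    current: list[str] = []
    for u in reversed(order):
        ok = bool(current)
        if ok:
            desc = dag.descendants(u, include_self=False)
            if desc & set(current):
                ok = False
            elif max_span is not None:
                sizes = [ann.size(t) for t in current] + [ann.size(u)]
                if max(sizes) - min(sizes) > max_span:
                    ok = False
        if ok:
            current.append(u)
        else:
            if current:
                layers_bottom_up.append(current)
            current = [u]
    if current:
        layers_bottom_up.append(current)

    levels = [list(reversed(layer)) for layer in reversed(layers_bottom_up)]
    level_of = {t: i for i, lv in enumerate(levels) for t in lv}
    return LeveledLayout(level_of, levels, "buoyant")


# ---------------------------------------------------------------------------
# within-level ordering
# ---------------------------------------------------------------------------


def _anchor_groups(dag: OntologyDAG, anchors: AnchorSpec) -> dict[str, int]:
    """Group semantically related anchors and their exclusive relatives.

    Two anchors belong to the same group when they share a common ancestor
    that is not a root of the DAG (a most recent common ancestor below the
    top).  Non-anchor nodes related (ancestor or descendant) to exactly one
    group join it.  Returns node → group index; ungrouped nodes are absent.
    """
    terms = [a.term for a in anchors if a.term in dag]
    if not terms:
        return {}
    roots = dag.roots
    anc = {t: dag.ancestors(t) - roots for t in terms}
    # union-find over anchors
    parent = {t: t for t in terms}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if anc[a] & anc[b]:
                parent[find(a)] = find(b)
    reps: dict[str, int] = {}
    group_of: dict[str, int] = {}
    for t in terms:  # anchor order fixes group numbering
        r = find(t)
        if r not in reps:
            reps[r] = len(reps)
        group_of[t] = reps[r]

    # exclusive relatives join the unique group they relate to; iterate so a
    # node related only through an already-absorbed member is picked up too
    changed = True
    while changed:
        changed = False
        for n in dag.terms:
            if n in group_of:
                continue
            gs = {
                group_of[m]
                for m in (dag.ancestors(n) | dag.descendants(n)) - {n}
                if m in group_of
            }
            if len(gs) == 1:
                group_of[n] = gs.pop()
                changed = True
    return group_of


def order_within_levels(
    dag: OntologyDAG,
    layout: LeveledLayout,
    anchors: AnchorSpec | None = None,
    sweeps: int = 4,
) -> LeveledLayout:
    """Order nodes within each level: anchor-group contiguity, then
    barycenter crossing reduction (alternating downward/upward sweeps).

    Level assignment is never changed.  Within each level the primary key is
    the anchor group (related anchors and their exclusive relatives stay
    contiguous), the secondary key the barycenter of already-placed neighbor
    positions, with term id breaking ties.  Deterministic for a given input.
    """
    group_of = _anchor_groups(dag, anchors) if anchors else {}
    ngroups = (max(group_of.values()) + 1) if group_of else 0
    levels = [sorted(lv) for lv in layout.levels]

    def position() -> dict[str, float]:
        return {t: j for lv in levels for j, t in enumerate(lv)}

    def key(t: str, bary: float) -> tuple:
        return (group_of.get(t, ngroups), bary, t)

    def sweep(downward: bool) -> None:
        pos = position()
        rng = range(1, len(levels)) if downward else range(len(levels) - 2, -1, -1)
        for i in rng:
            neigh = dag.parents if downward else dag.children
            def bary(t: str) -> float:
                ns = [pos[n] for n in neigh(t) if layout.level_of[n] == i + (-1 if downward else 1)]
                return sum(ns) / len(ns) if ns else pos[t]
            levels[i] = sorted(levels[i], key=lambda t: key(t, bary(t)))
            pos = position()

    for _ in range(sweeps):
        before = [list(lv) for lv in levels]
        sweep(downward=True)
        sweep(downward=False)
        if levels == before:
            break
    return LeveledLayout(dict(layout.level_of), levels, layout.kind)


def crossing_count(dag: OntologyDAG, layout: LeveledLayout) -> int:
    """Number of edge crossings between consecutive levels (quadratic scan)."""
    pos = {t: j for lv in layout.levels for j, t in enumerate(lv)}
    total = 0
    edges = [(c, p) for c, p in dag.edges if layout.level_of[c] == layout.level_of[p] + 1]
    for i, (c1, p1) in enumerate(edges):
        for c2, p2 in edges[i + 1 :]:
            if layout.level_of[c1] != layout.level_of[c2]:
                continue
            if (pos[p1] - pos[p2]) * (pos[c1] - pos[c2]) < 0:
                total += 1
    return total


# ---------------------------------------------------------------------------
# silhouette and binder order
# ---------------------------------------------------------------------------


def context_silhouette(
    context: OntologyDAG, layout: LeveledLayout, highlight: Iterable[str] = ()
) -> ContextSilhouette:
    """Per-level totals, plus counts of nodes ancestral or descendent to the
    highlight set (the highlighted nodes count themselves)."""
    hi = set(highlight)
    for t in hi:
        if t not in context:
            raise KeyError(f"highlight term outside context: {t!r}")
    related: set[str] = set()
    for t in hi:
        related |= context.ancestors(t) | context.descendants(t)
    totals = [len(lv) for lv in layout.levels]
    marked = [sum(1 for t in lv if t in related) for lv in layout.levels]
    return ContextSilhouette(totals, marked)


def binder_order(
    terms: Iterable[str], ann: AnnotationMap, layout: LeveledLayout
) -> BinderOrder:
    """Linear order by non-increasing node size, ties by level then term id.

    Level boundaries are emitted so renderers can draw alternating level
    bands behind the sequence.
    """
    seq = sorted(terms, key=lambda t: (-ann.size(t), layout.level_of[t], t))
    bounds = [
        i
        for i in range(1, len(seq))
        if layout.level_of[seq[i]] != layout.level_of[seq[i - 1]]
    ]
    return BinderOrder(seq, {t: layout.level_of[t] for t in seq}, bounds)
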