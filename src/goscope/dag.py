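"""Core ontology DAG model and structural operations.

The central object is :class:`OntologyDAG`, a rooted directed acyclic graph
of ontology terms with child-to-parent ``is a``-style edges, together with
:class:`AnnotationMap`, the per-term gene sets obtained by true-path
propagation (every parent's gene set contains each child's).

Structural operations provided here:

* :func:`refine_dag` — collapse redundant parents annotated with exactly a
  child's gene set, reconnecting so ancestry is preserved;
* :func:`filter_by_size` — restrict to terms in a node-size window, with the
  same ancestry-preserving reconnection;
* :func:`induce_context` — anchor-based subDAG induction (root / leaf /
  waypoint roles);
* :func:`focus_subdag` — bounded focus-graph extraction within a context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping

import networkx as nx

__all__ = [
    "OntologyDAG",
    "AnnotationMap",
    "Anchor",
    "AnchorSpec",
    "CycleError",
    "UnknownTermError",
    "FocusCapacityError",
    "refine_dag",
    "filter_by_size",
    "induce_context",
    "focus_subdag",
]

Role = Literal["root", "leaf", "waypoint"]


class CycleError(ValueError):
    """The input relations contain a directed cycle (an ontology must be a DAG)."""


class UnknownTermError(KeyError):
    """A referenced term id is not present in the DAG."""


class FocusCapacityError(ValueError):
    """Too many focus anchors were requested."""


class OntologyDAG:
    """Immutable rooted DAG of terms with child→parent edges.

    Parameters
    ----------
    terms
        Mapping of term id to human-readable name.  Iteration order of the
        mapping fixes the canonical term order.
    edges
        Iterable of ``(child_id, parent_id)`` pairs.  Both endpoints must be
        known terms and the resulting graph must be acyclic.
    """

    __slots__ = ("_names", "_g")

    def __init__(self, terms: Mapping[str, str], edges: Iterable[tuple[str, str]]):
        self._names: dict[str, str] = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(self._names)
        for child, parent in edges:
            if child not in self._names:
                raise UnknownTermError(child)
            if parent not in self._names:
                raise UnknownTermError(parent)
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"relation cycle detected: {cyc}")
        self._g = g

    # -- basic accessors -------------------------------------------------

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self._names)

    @property
    def names(self) -> dict[str, str]:
        return dict(self._names)

    def name(self, term: str) -> str:
        return self._names[term]

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, term: str) -> bool:
        return term in self._names

    def __iter__(self) -> Iterator[str]:
        return iter(self._names)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """All ``(child, parent)`` pairs."""
        return set(self._g.edges())

    def parents(self, term: str) -> set[str]:
        self._check(term)
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        self._check(term)
        return set(self._g.predecessors(term))

    @property
    def roots(self) -> set[str]:
        return {t for t in self._names if self._g.out_degree(t) == 0}

    @property
    def leaves(self) -> set[str]:
        return {t for t in self._names if self._g.in_degree(t) == 0}

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """Terms reachable root-ward from ``term`` (self included by default)."""
        self._check(term)
        anc = nx.descendants(self._g, term)  # edges point child→parent
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        """Terms reachable leaf-ward from ``term`` (self included by default)."""
        self._check(term)
        des = nx.ancestors(self._g, term)
        if include_self:
            des.add(term)
        return des

    def topological_order(self) -> list[str]:
        """Children-before-parents order, deterministic (ties by term order)."""
        index = {t: i for i, t in enumerate(self._names)}
        return list(nx.lexicographical_topological_sort(self._g, key=index.get))

    def subgraph(self, nodes: Iterable[str]) -> "OntologyDAG":
        """Induced subDAG on ``nodes``, keeping the canonical term order."""
        keep = set(nodes)
        for n in keep:
            self._check(n)
        terms = {t: self._names[t] for t in self._names if t in keep}
        edges = [(c, p) for c, p in self._g.edges() if c in keep and p in keep]
        return OntologyDAG(terms, edges)

    def _check(self, term: str) -> None:
        if term not in self._names:
            raise UnknownTermError(f"unknown term: {term!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"OntologyDAG({len(self)} terms, {self._g.number_of_edges()} edges)"


@dataclass(frozen=True)
class AnnotationMap:
    """Per-term gene sets after true-path propagation.

    ``genes_of[t]`` is the full (propagated) gene set of term ``t``; the node
    size of ``t`` is ``len(genes_of[t])``.  ``universe`` is the full gene
    background used by competitive tests.
    """

    genes_of: dict[str, frozenset[str]]
    universe: frozenset[str]

    def size(self, term: str) -> int:
        return len(self.genes_of[term])

    def restrict(self, terms: Iterable[str]) -> "AnnotationMap":
        keep = set(terms)
        return AnnotationMap(
            {t: g for t, g in self.genes_of.items() if t in keep}, self.universe
        )

    def check_superset_invariant(self, dag: OntologyDAG) -> None:
        """Raise if some parent's gene set does not contain a child's."""
        for child, parent in dag.edges:
            if not self.genes_of[parent] >= self.genes_of[child]:
                raise ValueError(
                    f"annotation superset invariant violated on edge "
                    f"({child!r} -> {parent!r})"
                )


@dataclass(frozen=True)
class Anchor:
    term: str
    role: Role

    def __post_init__(self) -> None:
        if self.role not in ("root", "leaf", "waypoint"):
            raise ValueError(f"invalid anchor role: {self.role!r}")


@dataclass(frozen=True)
class AnchorSpec:
    """An ordered collection of anchors used for subDAG induction."""

    anchors: tuple[Anchor, ...] = field(default_factory=tuple)

    @classmethod
    def parse(cls, tokens: Iterable[str]) -> "AnchorSpec":
        """Build from ``TERM:ROLE`` strings (e.g. ``GO:0000082:waypoint``)."""
        anchors = []
        for tok in tokens:
            term, _, role = tok.rpartition(":")
            if not term:
                raise ValueError(f"malformed anchor token: {tok!r}")
            anchors.append(Anchor(term, role))  # type: ignore[arg-type]
        return cls(tuple(anchors))

    def __iter__(self) -> Iterator[Anchor]:
        return iter(self.anchors)

    def __len__(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# reconnection helper
# ---------------------------------------------------------------------------


def _contract(dag: OntologyDAG, removed: set[str]) -> OntologyDAG:
    """Drop ``removed`` terms, adding an edge (u, v) between surviving terms
    whenever the original DAG has a root-ward path from u to v whose interior
    nodes are all removed.  This preserves every ancestor relation among the
    survivors."""
    g = dag._g
    keep = [t for t in dag.terms if t not in removed]
    edges: set[tuple[str, str]] = set()
    for u in keep:
        # walk root-ward through removed nodes only
        stack = [p for p in g.successors(u)]
        seen: set[str] = set()
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            if v in removed:
                stack.extend(g.successors(v))
            else:
                edges.add((u, v))
    return OntologyDAG({t: dag.name(t) for t in keep}, sorted(edges))


# ---------------------------------------------------------------------------
# refinement and filtering
# ---------------------------------------------------------------------------


def refine_dag(dag: OntologyDAG, ann: AnnotationMap) -> OntologyDAG:
    """Collapse redundant parents.

    A parent is redundant if one of its children is annotated with exactly the
    same gene set; the corresponding term-level test statistics would be
    identical, so the parent is removed and its parents are reconnected to its
    children.  Removal iterates to a fixed point, taking the deepest redundant
    parent first (ties broken by term id) so the result is deterministic.
    """
    current = dag
    while True:
        depth = _root_depths(current)
        candidates = [
            p
            for p in current.terms
            if any(ann.genes_of[c] == ann.genes_of[p] for c in current.children(p))
        ]
        if not candidates:
            return current
        victim = max(candidates, key=lambda t: (depth[t], _neg_id(t)))
        current = _contract(current, {victim})


def _neg_id(term: str) -> tuple[int, ...]:
    # lexicographically *smallest* id wins under max(): invert byte order
    return tuple(-b for b in term.encode())


def _root_depths(dag: OntologyDAG) -> dict[str, int]:
    """Longest distance from any root, following parent→child direction."""
    depth: dict[str, int] = {}
    for t in reversed(dag.topological_order()):  # parents before children
        ps = dag.parents(t)
        depth[t] = 1 + max(depth[p] for p in ps) if ps else 0
    return depth


def filter_by_size(
    dag: OntologyDAG, ann: AnnotationMap, min_size: int, max_size: int
) -> OntologyDAG:
    """Keep terms whose node size lies in ``[min_size, max_size]``.

    Transitive connections among kept terms are preserved by the same
    reconnection rule as :func:`refine_dag`, so dropping an intermediate term
    never severs its surviving ancestors from its surviving descendants.
    """
    if not 0 <= min_size <= max_size:
        raise ValueError("require 0 <= min_size <= max_size")
    removed = {t for t in dag.terms if not min_size <= ann.size(t) <= max_size}
    return _contract(dag, removed)


# ---------------------------------------------------------------------------
# context and focus induction
# ---------------------------------------------------------------------------


def induce_context(dag: OntologyDAG, spec: AnchorSpec) -> OntologyDAG:
    """SubDAG induced by context anchors.

    Root anchors contribute their descendants, leaf anchors their ancestors,
    waypoint anchors both; each contribution includes the anchor itself.  The
    node sets of all anchors are unioned and edges are induced.
    """
    nodes: set[str] = set()
    for a in spec:
        if a.term not in dag:
            raise UnknownTermError(f"anchor term not in DAG: {a.term!r}")
        if a.role in ("root", "waypoint"):
            nodes |= dag.descendants(a.term)
        if a.role in ("leaf", "waypoint"):
            nodes |= dag.ancestors(a.term)
    return dag.subgraph(nodes)


def focus_subdag(
    context: OntologyDAG,
    focus_anchors: AnchorSpec,
    max_anchors: int = 10,
    expansion_cap: int = 50,
    default_anchors: AnchorSpec | None = None,
) -> OntologyDAG:
    """Bounded focus graph within a context DAG.

    Focus anchors are restricted to the ``waypoint`` and ``leaf`` roles.  The
    focus graph always contains all ancestors (within the context) of every
    anchor.  A waypoint anchor additionally contributes its immediate
    children, and its full descendant closure only when that closure has at
    most ``expansion_cap`` nodes — keeping the display small.  When no focus
    anchors are given, ``default_anchors`` (normally the context anchors) are
    used in the leaf role.
    """
    anchors = list(focus_anchors)
    if not anchors:
        if default_anchors is None or not len(default_anchors):
            raise ValueError("no focus anchors given and no default available")
        anchors = [Anchor(a.term, "leaf") for a in default_anchors]
    if len(anchors) > max_anchors:
        raise FocusCapacityError(
            f"{len(anchors)} focus anchors exceed the limit of {max_anchors}"
        )
    nodes: set[str] = set()
    for a in anchors:
        if a.role not in ("waypoint", "leaf"):
            raise ValueError(f"focus anchors must be waypoint or leaf, got {a.role!r}")
        if a.term not in context:
            raise UnknownTermError(f"focus anchor outside context: {a.term!r}")
        nodes |= context.ancestors(a.term)
        if a.role == "waypoint":
            closure = context.descendants(a.term)
            if len(closure) <= expansion_cap:
                nodes |= closure
            else:
                nodes |= context.children(a.term)
                nodes.add(a.term)
    return context.subgraph(nodes)
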