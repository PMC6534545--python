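"""Reading ontology and annotation files, and true-path propagation.

Supports the minimal slice of the OBO flat-file format (version 1.2) needed
for term/relationship ingestion — the tags ``id``, ``name``, ``namespace``,
``is_a``, ``relationship``, ``is_obsolete`` and ``alt_id`` — plus NCBI
``gene2go``-style tab-separated annotation tables.  Relationship types are
filtered against a caller-supplied whitelist at parse time (e.g. only
``is_a`` for the biological-process ontology, all types for cellular
component).

Annotations are propagated up the DAG under the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor, so after
propagation each parent's gene set is a superset of each child's.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd

from .dag import AnnotationMap, OntologyDAG

__all__ = [
    "RawOntology",
    "DirectAnnotations",
    "OboParseError",
    "Gene2GoFormatError",
    "parse_obo",
    "parse_gene2go",
    "raw_to_dag",
    "propagate_annotations",
    "write_obo",
    "write_gene2go",
    "save_bundle",
    "load_bundle",
]

logger = logging.getLogger(__name__)


class OboParseError(ValueError):
    """Malformed OBO input."""


class Gene2GoFormatError(ValueError):
    """Malformed gene2go-style table."""


@dataclass
class RawOntology:
    """Parsed OBO content before DAG construction.

    ``terms`` holds ``(term_id, name, namespace)`` triples for non-obsolete
    terms; ``relations`` holds ``(child_id, parent_id, relation_type)``
    triples whose type passed the whitelist; ``alt_ids`` maps alias ids to
    their canonical term id.
    """

    terms: list[tuple[str, str, str]] = field(default_factory=list)
    relations: list[tuple[str, str, str]] = field(default_factory=list)
    obsolete_ids: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def resolve(self, term_id: str) -> str:
        return self.alt_ids.get(term_id, term_id)


@dataclass
class DirectAnnotations:
    """Deduplicated direct (gene, term) annotation pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    taxon: int | None = None

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}


def parse_obo(stream: IO[str] | Iterable[str], relation_whitelist: set[str]) -> RawOntology:
    """Parse OBO 1.2 text, keeping only whitelisted relationship types.

    ``is_a`` lines count as relations of type ``"is_a"``; ``relationship:``
    lines carry their stated type.  Obsolete terms are recorded in
    ``obsolete_ids`` and emit no relations.  Relations whose endpoints are
    never defined as terms are dropped with a warning.
    """
    if not relation_whitelist:
        raise ValueError("relation whitelist must be non-empty")
    terms: list[tuple[str, str, str]] = []
    relations: list[tuple[str, str, str]] = []
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}

    in_term = False
    stanza_start = 0
    cur: dict[str, str] = {}
    cur_rel: list[tuple[str, str]] = []  # (parent_id, rel_type)
    cur_alt: list[str] = []

    def flush() -> None:
        if not in_term:
            return
        if "id" not in cur:
            raise OboParseError(f"[Term] stanza at line {stanza_start} has no id")
        tid = cur["id"]
        if cur.get("is_obsolete") == "true":
            obsolete.add(tid)
            return
        terms.append((tid, cur.get("name", ""), cur.get("namespace", "")))
        for alias in cur_alt:
            alt_ids[alias] = tid
        for parent, rtype in cur_rel:
            if rtype in relation_whitelist:
                relations.append((tid, parent, rtype))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza_start = lineno
            cur, cur_rel, cur_alt = {}, [], []
            continue
        if not in_term:
            continue
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag in ("id", "name", "namespace", "is_obsolete"):
            cur.setdefault(tag, value)
        elif tag == "alt_id":
            cur_alt.append(value)
        elif tag == "is_a":
            cur_rel.append((value.split()[0], "is_a"))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) >= 2:
                cur_rel.append((parts[1], parts[0]))
    flush()

    known = {t[0] for t in terms}
    kept: list[tuple[str, str, str]] = []
    for child, parent, rtype in relations:
        if child in known and parent in known:
            kept.append((child, parent, rtype))
        else:
            logger.warning("dropping relation with unknown endpoint: %s %s %s", child, rtype, parent)
    return RawOntology(terms, kept, obsolete, alt_ids)


_GENE2GO_REQUIRED = ["tax_id", "GeneID", "GO_ID", "Evidence"]


def parse_gene2go(
    stream: IO[str] | str,
    taxon: int | None = None,
    evidence_filter: set[str] | None = None,
    drop_not_qualified: bool = True,
) -> DirectAnnotations:
    """Parse a gene2go-style tab-separated table into (gene, term) pairs.

    All evidence codes are kept by default; pass ``evidence_filter`` to
    restrict.  ``NOT``-qualified rows are dropped by default when a
    ``Qualifier`` column is present.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, comment=None)
    if df.columns.size and df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    for col in _GENE2GO_REQUIRED:
        if col not in df.columns:
            raise Gene2GoFormatError(f"missing required column: {col}")
    if taxon is not None:
        df = df[df["tax_id"].astype(int) == taxon]
    if evidence_filter is not None:
        df = df[df["Evidence"].isin(evidence_filter)]
    if drop_not_qualified and "Qualifier" in df.columns:
        df = df[~df["Qualifier"].fillna("").str.startswith("NOT")]
    pairs = {(str(g), str(t)) for g, t in zip(df["GeneID"], df["GO_ID"])}
    return DirectAnnotations(pairs, taxon)


def raw_to_dag(raw: RawOntology) -> OntologyDAG:
    """Build an :class:`OntologyDAG` from parsed OBO content (types merged)."""
    terms = {tid: name for tid, name, _ns in raw.terms}
    edges = sorted({(c, p) for c, p, _t in raw.relations})
    return OntologyDAG(terms, edges)


def propagate_annotations(dag: OntologyDAG, direct: DirectAnnotations) -> AnnotationMap:
    """True-path propagation: each term inherits all its descendants' genes.

    Annotations to terms absent from the DAG are skipped with a warning
    (their count is logged).  The result satisfies the superset invariant:
    for every edge (child, parent), genes(parent) ⊇ genes(child).
    """
    direct_of: dict[str, set[str]] = {t: set() for t in dag.terms}
    skipped = 0
    for gene, term in direct.pairs:
        if term in direct_of:
            direct_of[term].add(gene)
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d annotations to unknown terms", skipped)

    genes_of: dict[str, frozenset[str]] = {}
    for t in dag.topological_order():  # children before parents
        acc = set(direct_of[t])
        for c in dag.children(t):
            acc |= genes_of[c]
        genes_of[t] = frozenset(acc)
    universe = frozenset(g for s in genes_of.values() for g in s)
    return AnnotationMap(genes_of, universe)


# ---------------------------------------------------------------------------
# writers (round-trip support for fixtures and the CLI)
# ---------------------------------------------------------------------------


def write_obo(dag: OntologyDAG, stream: IO[str], namespace: str = "biological_process") -> None:
    """Serialize a DAG as minimal OBO 1.2 text with ``is_a`` relations."""
    stream.write("format-version: 1.2\n")
    for t in dag.terms:
        stream.write(f"\n[Term]\nid: {t}\nname: {dag.name(t)}\nnamespace: {namespace}\n")
        for p in sorted(dag.parents(t)):
            stream.write(f"is_a: {p}\n")


def write_gene2go(direct: DirectAnnotations, stream: IO[str], taxon: int = 9606) -> None:
    """Serialize direct annotations as a gene2go-style table."""
    stream.write("#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\n")
    for gene, term in sorted(direct.pairs):
        stream.write(f"{taxon}\t{gene}\t{term}\tIEA\t-\n")


_SCHEMA = "goscope-dag/1"


def save_bundle(
    dag: OntologyDAG, direct: DirectAnnotations, stream: IO[str], meta: Mapping | None = None
) -> None:
    """Write the internal versioned JSON document (terms, edges, annotations)."""
    doc = {
        "schema": _SCHEMA,
        "meta": dict(meta or {}),
        "terms": [{"id": t, "name": dag.name(t)} for t in dag.terms],
        "edges": sorted(dag.edges),
        "annotations": sorted(direct.pairs),
    }
    json.dump(doc, stream, indent=1)


def load_bundle(stream: IO[str]) -> tuple[OntologyDAG, DirectAnnotations]:
    doc = json.load(stream)
    if doc.get("schema") != _SCHEMA:
        raise ValueError(f"unrecognized document schema: {doc.get('schema')!r}")
    dag = OntologyDAG(
        {t["id"]: t["name"] for t in doc["terms"]},
        [tuple(e) for e in doc["edges"]],
    )
    direct = DirectAnnotations({(g, t) for g, t in doc["annotations"]})
    return dag, direct
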