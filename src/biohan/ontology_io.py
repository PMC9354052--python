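"""Reading and writing ontologies and alignments.

Ontologies are parsed from RDF/XML or Turtle with :mod:`rdflib` into the
package's :class:`~biohan.model.Ontology` container.  Alignments use the OAEI
Alignment Format (RDF/XML with ``Cell``/``entity1``/``entity2``/``measure``
elements), the de-facto exchange format of the Ontology Alignment Evaluation
Initiative.

Blank nodes are renamed to stable synthetic IRIs derived from rdflib's
canonical graph labelling, so that parsing is independent of triple order in
the source file and enrichment diffs are reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import rdflib
from rdflib import BNode, URIRef
from rdflib import Literal as RLiteral
from rdflib.compare import to_canonical_graph

from .errors import FormatError, MalformedAlignmentError, ValidationError
from .model import (
    OWL,
    RDF,
    RDFS,
    SKOS,
    XSD,
    Alignment,
    Correspondence,
    Literal,
    Ontology,
    Relation,
    Triple,
)

logger = logging.getLogger(__name__)

#: Namespace prefix for synthetic IRIs assigned to blank nodes.
BNODE_PREFIX = "urn:biohan:bn:"

ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment#"

#: Label predicates in priority order: the first bucket holds primary labels.
LABEL_PREDICATES = (
    RDFS + "label",
    SKOS + "prefLabel",
    SKOS + "altLabel",
    "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym",
)

#: Literal-valued predicates routed to the annotation store.
ANNOTATION_PREDICATES = (
    RDFS + "comment",
    SKOS + "definition",
    SKOS + "note",
    "http://www.geneontology.org/formats/oboInOwl#hasDefinition",
)

#: Ontology-header / versioning predicates dropped on load (they describe the
#: document, not the domain).
_METADATA_PREDICATES = {
    OWL + "versionInfo",
    OWL + "versionIRI",
    OWL + "imports",
    OWL + "priorVersion",
    OWL + "backwardCompatibleWith",
}

_RESERVED_NS = (RDF, RDFS, OWL, XSD)

_PROPERTY_TYPES = {
    OWL + "ObjectProperty",
    OWL + "DatatypeProperty",
    OWL + "AnnotationProperty",
    OWL + "SymmetricProperty",
    OWL + "TransitiveProperty",
    OWL + "FunctionalProperty",
    OWL + "InverseFunctionalProperty",
    RDF + "Property",
}

# rdf:first and container-membership predicates may legitimately carry literal
# objects (list members); those triples must stay in the triple set so the
# flattening rule can see them.
_STRUCTURAL_LITERAL_OK = (RDF + "first", RDF + "li")


def _is_reserved(iri: str) -> bool:
    return iri.startswith(_RESERVED_NS)


def _is_container_membership(iri: str) -> bool:
    return iri.startswith(RDF + "_") or iri == RDF + "li"


def _node_to_internal(node) -> str | Literal:
    if isinstance(node, URIRef):
        return str(node)
    if isinstance(node, BNode):
        return BNODE_PREFIX + str(node)
    if isinstance(node, RLiteral):
        return Literal(
            lexical=str(node),
            datatype=str(node.datatype) if node.datatype else None,
            language=node.language,
        )
    raise FormatError(f"unsupported RDF node {node!r}")


def _guess_format(path: Path, format: str) -> str:
    if format == "rdfxml":
        return "xml"
    if format == "turtle":
        return "turtle"
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in {".ttl", ".turtle", ".n3"}:
            return "turtle"
        return "xml"
    raise FormatError(f"unknown ontology format {format!r}")


def load_ontology(path: str | Path, format: str = "auto") -> Ontology:
    """Parse an RDF/XML or Turtle file into an :class:`Ontology`.

    All asserted triples are kept verbatim (rdf:List and container structures
    included — flattening is the enrichment module's job), except label and
    annotation statements, which are routed to the label/annotation stores,
    and ontology-header metadata, which is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"ontology file not found: {path}")
    graph = rdflib.Graph()
    try:
        graph.parse(location=str(path), format=_guess_format(path, format))
    except Exception as exc:  # rdflib raises many concrete parse errors
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if any(isinstance(n, BNode) for n in graph.all_nodes()):
        graph = to_canonical_graph(graph)
    return _graph_to_ontology(graph)


def _graph_to_ontology(graph: rdflib.Graph) -> Ontology:
    onto = Ontology()
    # Per-predicate label buckets, flattened in priority order afterwards.
    label_buckets: dict[str, dict[str, list[str]]] = {p: {} for p in LABEL_PREDICATES}

    header_subjects = {
        _node_to_internal(s) for s in graph.subjects(URIRef(RDF + "type"), URIRef(OWL + "Ontology"))
    }
    typed_properties: set[str] = set()
    for ptype in _PROPERTY_TYPES:
        for s in graph.subjects(URIRef(RDF + "type"), URIRef(ptype)):
            typed_properties.add(str(s) if isinstance(s, URIRef) else BNODE_PREFIX + str(s))

    pending: list[Triple] = []
    for s, p, o in graph:
        subj = _node_to_internal(s)
        pred = str(p)
        if subj in header_subjects or pred in _METADATA_PREDICATES:
            continue
        obj = _node_to_internal(o)
        if isinstance(obj, Literal):
            if pred in LABEL_PREDICATES:
                label_buckets[pred].setdefault(subj, []).append(obj.lexical)
                continue
            if pred not in _STRUCTURAL_LITERAL_OK and not _is_container_membership(pred):
                onto.annotations.setdefault(subj, []).append((pred, obj.lexical))
                continue
        pending.append(Triple(subj, pred, obj))

    relations = set(typed_properties)
    for t in pending:
        if not _is_reserved(t.predicate):
            relations.add(t.predicate)
    onto.relations = relations

    for t in pending:
        onto.triples.add(t)
        if t.subject not in relations:
            onto.concepts.add(t.subject)
        if isinstance(t.object, str) and t.object not in relations and not _is_reserved(t.object):
            onto.concepts.add(t.object)

    # Concepts known only through their labels/annotations still count.
    for pred in LABEL_PREDICATES:
        for subj in label_buckets[pred]:
            if subj not in relations:
                onto.concepts.add(subj)
    for subj in onto.annotations:
        if subj not in relations and subj not in onto.concepts:
            onto.concepts.add(subj)

    for pred in LABEL_PREDICATES:  # priority order, deterministic within bucket
        for subj, texts in label_buckets[pred].items():
            for text in sorted(texts):
                onto.add_label(subj, text)
    for subj in onto.annotations:
        onto.annotations[subj] = sorted(onto.annotations[subj])
    return onto


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    """Serialize an :class:`Ontology` to Turtle.

    The first label of a concept is written as ``rdfs:label``, further labels
    as ``skos:altLabel``; annotations keep their original property.
    """
    graph = rdflib.Graph()
    graph.bind("rdfs", RDFS)
    graph.bind("owl", OWL)
    graph.bind("skos", SKOS)

    def as_node(value):
        if isinstance(value, Literal):
            return RLiteral(
                value.lexical,
                datatype=URIRef(value.datatype) if value.datatype else None,
                lang=value.language,
            )
        return URIRef(value)

    for t in sorted(ontology.triples, key=lambda t: (t.subject, t.predicate, str(t.object))):
        graph.add((URIRef(t.subject), URIRef(t.predicate), as_node(t.object)))
    for iri in sorted(ontology.labels):
        for i, text in enumerate(ontology.labels[iri]):
            pred = LABEL_PREDICATES[0] if i == 0 else SKOS + "altLabel"
            graph.add((URIRef(iri), URIRef(pred), RLiteral(text)))
    for iri in sorted(ontology.annotations):
        for pred, text in ontology.annotations[iri]:
            graph.add((URIRef(iri), URIRef(pred), RLiteral(text)))
    Path(path).write_text(graph.serialize(format="turtle"), encoding="utf-8")


# ---------------------------------------------------------------------------
# OAEI Alignment Format
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> Alignment:
    """Read an OAEI Alignment Format file (one Correspondence per Cell)."""
    path = Path(path)
    graph = rdflib.Graph()
    try:
        graph.parse(location=str(path), format="xml")
    except Exception as exc:
        raise FormatError(f"cannot parse alignment {path}: {exc}") from exc

    ent1 = URIRef(ALIGN_NS + "entity1")
    ent2 = URIRef(ALIGN_NS + "entity2")
    meas = URIRef(ALIGN_NS + "measure")
    onto1 = URIRef(ALIGN_NS + "onto1")
    onto2 = URIRef(ALIGN_NS + "onto2")

    alignment = Alignment()
    for _, _, o in graph.triples((None, onto1, None)):
        alignment.source_ontology = str(o)
    for _, _, o in graph.triples((None, onto2, None)):
        alignment.target_ontology = str(o)

    for cell in graph.subjects(URIRef(RDF + "type"), URIRef(ALIGN_NS + "Cell")):
        e1 = graph.value(cell, ent1)
        e2 = graph.value(cell, ent2)
        if e1 is None or e2 is None:
            raise MalformedAlignmentError(f"Cell {cell} lacks entity1/entity2 in {path}")
        measure = graph.value(cell, meas)
        score = float(measure) if measure is not None else 1.0
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"measure {score} outside [0, 1] in {path}")
        alignment.correspondences.add(
            Correspondence(source=str(e1), target=str(e2), relation=Relation.EQUIVALENCE, score=score)
        )
    return alignment


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write OAEI Alignment Format RDF/XML.

    Cells are emitted in sorted (source IRI, target IRI) order and scores with
    full round-trip precision, so identical alignments produce byte-identical
    files.
    """
    lines = [
        "<?xml version='1.0' encoding='utf-8'?>",
        "<rdf:RDF xmlns='%s'" % ALIGN_NS,
        "         xmlns:rdf='%s'" % RDF,
        "         xmlns:xsd='%s'>" % XSD,
        "<Alignment>",
        "  <xml>yes</xml>",
        "  <level>0</level>",
        "  <type>11</type>",
    ]
    if alignment.source_ontology:
        lines.append("  <onto1>%s</onto1>" % escape(alignment.source_ontology))
    if alignment.target_ontology:
        lines.append("  <onto2>%s</onto2>" % escape(alignment.target_ontology))
    for corr in sorted(alignment.correspondences, key=lambda c: (c.source, c.target)):
        lines += [
            "  <map>",
            "    <Cell>",
            "      <entity1 rdf:resource=%s/>" % quoteattr(corr.source),
            "      <entity2 rdf:resource=%s/>" % quoteattr(corr.target),
            "      <relation>%s</relation>" % escape(corr.relation.value),
            "      <measure rdf:datatype='%sfloat'>%s</measure>" % (XSD, repr(float(corr.score))),
            "    </Cell>",
            "  </map>",
        ]
    lines += ["</Alignment>", "</rdf:RDF>", ""]
    try:
        Path(path).write_text("\n".join(lines), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write alignment to {path}: {exc}") from exc
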