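"""Core domain types for ontology matching.

An ontology is modelled as ``O = (C, R, T)``: a set of concepts, a set of
relations (properties), and a set of triples over them, plus a side store of
human-readable labels and annotations.  An alignment is a set of scored
equivalence correspondences between the concepts of two ontologies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Union

# Well-known IRIs used across the package.
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"
SKOS = "http://www.w3.org/2004/02/skos/core#"

RDF_TYPE = RDF + "type"
RDFS_SUBCLASSOF = RDFS + "subClassOf"
RDFS_SUBPROPERTYOF = RDFS + "subPropertyOf"
RDFS_DOMAIN = RDFS + "domain"
RDFS_RANGE = RDFS + "range"
RDFS_LABEL = RDFS + "label"
RDFS_COMMENT = RDFS + "comment"
OWL_CLASS = OWL + "Class"
OWL_EQUIVALENT_CLASS = OWL + "equivalentClass"
OWL_EQUIVALENT_PROPERTY = OWL + "equivalentProperty"
OWL_SAMEAS = OWL + "sameAs"
OWL_INTERSECTION_OF = OWL + "intersectionOf"
OWL_UNION_OF = OWL + "unionOf"
OWL_ONE_OF = OWL + "oneOf"
OWL_SYMMETRIC = OWL + "SymmetricProperty"
OWL_TRANSITIVE = OWL + "TransitiveProperty"


@dataclass(frozen=True)
class Literal:
    """An RDF literal kept with its datatype and language tag.

    Label matching elsewhere uses only :attr:`lexical`.
    """

    lexical: str
    datatype: str | None = None
    language: str | None = None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.lexical


#: A triple object is either a concept/relation IRI (str) or a Literal.
Node = Union[str, Literal]


@dataclass(frozen=True)
class Triple:
    """A single RDF statement ``<subject, predicate, object>``.

    The subject and predicate are IRIs; the object may be an IRI or a
    :class:`Literal`.
    """

    subject: str
    predicate: str
    object: Node

    def __post_init__(self) -> None:
        if isinstance(self.subject, Literal):
            raise ValueError("triple subject must not be a literal")


@dataclass
class Ontology:
    """In-memory ontology ``O = (C, R, T)`` with label/annotation stores."""

    concepts: set[str] = field(default_factory=set)
    relations: set[str] = field(default_factory=set)
    triples: set[Triple] = field(default_factory=set)
    labels: dict[str, list[str]] = field(default_factory=dict)
    annotations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------------

    def labels_of(self, iri: str) -> list[str]:
        return self.labels.get(iri, [])

    def add_label(self, iri: str, text: str) -> None:
        bucket = self.labels.setdefault(iri, [])
        if text not in bucket:
            bucket.append(text)

    def neighbors(self, iri: str) -> set[str]:
        """Concepts linked to ``iri`` by any triple, in either direction."""
        out: set[str] = set()
        for t in self.triples:
            if t.subject == iri and isinstance(t.object, str) and t.object in self.concepts:
                out.add(t.object)
            elif t.object == iri and t.subject in self.concepts:
                out.add(t.subject)
        out.discard(iri)
        return out

    def subclass_edges(self) -> set[tuple[str, str]]:
        """All asserted ``(child, parent)`` subClassOf pairs between IRIs."""
        return {
            (t.subject, t.object)
            for t in self.triples
            if t.predicate == RDFS_SUBCLASSOF and isinstance(t.object, str)
        }

    def copy(self) -> "Ontology":
        return Ontology(
            concepts=set(self.concepts),
            relations=set(self.relations),
            triples=set(self.triples),
            labels={k: list(v) for k, v in self.labels.items()},
            annotations={k: list(v) for k, v in self.annotations.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.concepts == other.concepts
            and self.relations == other.relations
            and self.triples == other.triples
            and {k: sorted(v) for k, v in self.labels.items() if v}
            == {k: sorted(v) for k, v in other.labels.items() if v}
            and {k: sorted(v) for k, v in self.annotations.items() if v}
            == {k: sorted(v) for k, v in other.annotations.items() if v}
        )


class Relation(enum.Enum):
    """Semantic relation of a correspondence; equivalence only."""

    EQUIVALENCE = "="


@dataclass(frozen=True)
class Correspondence:
    """A scored claim ``<source, target, relation, score>``."""

    source: str
    target: str
    relation: Relation = Relation.EQUIVALENCE
    score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"correspondence score {self.score!r} outside [0, 1]")

    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class Alignment:
    """A set of correspondences between two ontologies."""

    correspondences: set[Correspondence] = field(default_factory=set)
    source_ontology: str = ""
    target_ontology: str = ""

    def __len__(self) -> int:
        return len(self.correspondences)

    def __iter__(self) -> Iterable[Correspondence]:
        return iter(self.correspondences)

    def pairs(self) -> set[tuple[str, str]]:
        """Correspondence identities as (source IRI, target IRI) pairs."""
        return {c.pair() for c in self.correspondences}

    def is_one_to_one(self) -> bool:
        sources = [c.source for c in self.correspondences]
        targets = [c.target for c in self.correspondences]
        return len(set(sources)) == len(sources) and len(set(targets)) == len(targets)
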