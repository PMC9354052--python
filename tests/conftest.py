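"""Shared fixtures: tiny hand-built ontologies and RDF files."""

from __future__ import annotations

import logging

import pytest

from biohan.model import (
    RDFS_SUBCLASSOF,
    Ontology,
    Triple,
)

logging.getLogger("biohan").setLevel(logging.ERROR)

FMA = "http://bioontology.org/ontologies/fma/"

# Synthetic stand-in for the published collection example: the "physical
# state" property whose rdfs:range is an rdf:List with the four members Gas,
# Liquid, Semi-solid and Solid, expressed as valid RDF/XML (parseType
# Collection produces the rdf:first/rdf:rest blank-node spine).
PHYSICAL_STATE_RDFXML = f"""<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#">
  <rdf:Description rdf:about="{FMA}physical_state">
    <rdfs:range rdf:parseType="Collection">
      <rdf:Description rdf:about="{FMA}Gas"/>
      <rdf:Description rdf:about="{FMA}Liquid"/>
      <rdf:Description rdf:about="{FMA}Semi-solid"/>
      <rdf:Description rdf:about="{FMA}Solid"/>
    </rdfs:range>
  </rdf:Description>
</rdf:RDF>
"""

TWO_CONCEPT_TURTLE = """@prefix ex: <http://example.org/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
ex:Capillary rdfs:subClassOf ex:BloodVessel .
"""


@pytest.fixture
def physical_state_file(tmp_path):
    path = tmp_path / "physical_state.rdf"
    path.write_text(PHYSICAL_STATE_RDFXML, encoding="utf-8")
    return path


@pytest.fixture
def two_concept_file(tmp_path):
    path = tmp_path / "two.ttl"
    path.write_text(TWO_CONCEPT_TURTLE, encoding="utf-8")
    return path


def make_ontology(edges=(), labels=None, triples=()) -> Ontology:
    """Build an ontology from (child, parent) subClassOf pairs and extras."""
    onto = Ontology()
    for child, parent in edges:
        onto.concepts |= {child, parent}
        onto.triples.add(Triple(child, RDFS_SUBCLASSOF, parent))
    for t in triples:
        onto.triples.add(t)
        onto.concepts.add(t.subject)
        if isinstance(t.object, str) and not t.object.startswith("http://www.w3.org"):
            onto.concepts.add(t.object)
    for iri, labs in (labels or {}).items():
        onto.concepts.add(iri)
        for lab in labs if isinstance(labs, (list, tuple)) else [labs]:
            onto.add_label(iri, lab)
    return onto
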