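"""Materialize subsumptions hidden inside OWL constructs.

Builds a small ontology in which a subclass axiom is wrapped in an
owl:intersectionOf and a property range sits inside an rdf:List, then runs
the rewriting rules and prints what they added.
"""

from biohan.enrichment import enrich
from biohan.model import (
    OWL_INTERSECTION_OF,
    RDF,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    Ontology,
    Triple,
)

EX = "http://example.org/demo#"
onto = Ontology()

# "Capillary ⊑ (BloodVessel ⊓ MicroStructure)" via an intersection class
triples = {
    Triple(EX + "Capillary", RDFS_SUBCLASSOF, EX + "anon1"),
    Triple(EX + "anon1", OWL_INTERSECTION_OF, EX + "list1"),
    Triple(EX + "list1", RDF + "first", EX + "BloodVessel"),
    Triple(EX + "list1", RDF + "rest", EX + "list2"),
    Triple(EX + "list2", RDF + "first", EX + "MicroStructure"),
    Triple(EX + "list2", RDF + "rest", RDF + "nil"),
    # "physical_state ranges over {Gas, Liquid}" via an rdf:List
    Triple(EX + "physical_state", RDFS_RANGE, EX + "plist1"),
    Triple(EX + "plist1", RDF + "first", EX + "Gas"),
    Triple(EX + "plist1", RDF + "rest", EX + "plist2"),
    Triple(EX + "plist2", RDF + "first", EX + "Liquid"),
    Triple(EX + "plist2", RDF + "rest", RDF + "nil"),
}
onto.triples |= triples
onto.concepts |= {t.subject for t in triples} | {
    o for t in triples if isinstance(o := t.object, str) and not o.startswith(RDF)
}

enriched, report = enrich(onto)

print("rule counts:", report.rule_counts)
print("added triples:")
for t in sorted(report.added, key=lambda t: (t.predicate, t.subject)):
    print(f"  {t.subject.split('#')[-1]} --{t.predicate.split('#')[-1]}--> "
          f"{str(t.object).split('#')[-1]}")

# The two intersection conjuncts become explicit subClassOf statements and
# the list members become explicit range statements — the hierarchy a graph
# encoder sees afterwards no longer hides behind anonymous nodes.
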