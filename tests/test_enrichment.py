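"""Axiom rewriting rules against brute-force oracles."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from conftest import make_ontology

from biohan.enrichment import (
    AnchorMap,
    anchor_concepts,
    augment,
    enrich,
    enrich_domain_range,
    flatten_collections,
    normalize_label,
    propagate_domain_to_subclasses,
    propagate_sameas,
    rewrite_concept_axioms,
    rewrite_property_axioms,
)
from biohan.errors import MalformedCollectionError
from biohan.model import (
    OWL,
    OWL_INTERSECTION_OF,
    OWL_SAMEAS,
    OWL_UNION_OF,
    RDF,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    Triple,
)
from biohan.ontology_io import load_ontology

EX = "http://example.org/"
FMA = "http://bioontology.org/ontologies/fma/"
RDF_FIRST, RDF_REST, RDF_NIL = RDF + "first", RDF + "rest", RDF + "nil"


def list_triples(head: str, members: list[str]) -> set[Triple]:
    out = set()
    node = head
    for i, m in enumerate(members):
        nxt = RDF_NIL if i == len(members) - 1 else f"{head}-n{i + 1}"
        out.add(Triple(node, RDF_FIRST, m))
        out.add(Triple(node, RDF_REST, nxt))
        node = nxt
    return out


class TestFlatten:
    def test_physical_state_collection(self, physical_state_file):
        """The collection example flattens to four explicit range statements."""
        onto = load_ontology(physical_state_file)
        flat, report = flatten_collections(onto)
        ranges = {
            str(t.object) for t in flat.triples if t.predicate == RDFS_RANGE
        }
        assert ranges == {FMA + n for n in ("Gas", "Liquid", "Semi-solid", "Solid")}
        assert report.rule_counts["flatten"] == 4
        assert not any(t.predicate == RDF_FIRST for t in flat.triples)

    def test_no_collections_noop(self):
        onto = make_ontology(edges=[(f"{EX}a", f"{EX}b")])
        flat, report = flatten_collections(onto)
        assert flat == onto
        assert report.added == set() and report.removed == set()

    def test_nested_lists_flatten_to_leaves(self):
        inner = list_triples(f"{EX}inner", [f"{EX}m{i}" for i in range(3)])
        outer = list_triples(f"{EX}outer", [f"{EX}k0", f"{EX}k1"])
        # splice: outer's second member is the inner list head
        outer = {t for t in outer if not (t.subject == f"{EX}outer-n1" and t.predicate == RDF_FIRST)}
        outer.add(Triple(f"{EX}outer-n1", RDF_FIRST, f"{EX}inner"))
        onto = make_ontology(
            triples=inner | outer | {Triple(f"{EX}p", RDFS_RANGE, f"{EX}outer")}
        )
        flat, _ = flatten_collections(onto)
        ranges = {str(t.object) for t in flat.triples if t.predicate == RDFS_RANGE}
        assert ranges == {f"{EX}k0", f"{EX}m0", f"{EX}m1", f"{EX}m2"}

    def test_cyclic_list_raises(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}h", RDF_FIRST, f"{EX}x"),
                Triple(f"{EX}h", RDF_REST, f"{EX}h2"),
                Triple(f"{EX}h2", RDF_FIRST, f"{EX}y"),
                Triple(f"{EX}h2", RDF_REST, f"{EX}h"),
                Triple(f"{EX}p", RDFS_RANGE, f"{EX}h"),
            }
        )
        with pytest.raises(MalformedCollectionError):
            flatten_collections(onto)

    def test_container_membership(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}bag", RDF_TYPE, RDF + "Bag"),
                Triple(f"{EX}bag", RDF + "_1", f"{EX}one"),
                Triple(f"{EX}bag", RDF + "_2", f"{EX}two"),
                Triple(f"{EX}p", RDFS_RANGE, f"{EX}bag"),
            }
        )
        flat, _ = flatten_collections(onto)
        ranges = {str(t.object) for t in flat.triples if t.predicate == RDFS_RANGE}
        assert ranges == {f"{EX}one", f"{EX}two"}


class TestDomainRange:
    def test_direct_inheritance(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}pb", RDFS_SUBPROPERTYOF, f"{EX}pa"),
                Triple(f"{EX}pa", RDFS_DOMAIN, f"{EX}A"),
            }
        )
        out, _ = enrich_domain_range(onto)
        assert Triple(f"{EX}pb", RDFS_DOMAIN, f"{EX}A") in out.triples

    def test_chain_inheritance(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}pc", RDFS_SUBPROPERTYOF, f"{EX}pb"),
                Triple(f"{EX}pb", RDFS_SUBPROPERTYOF, f"{EX}pa"),
                Triple(f"{EX}pa", RDFS_RANGE, f"{EX}X"),
            }
        )
        out, _ = enrich_domain_range(onto)
        assert Triple(f"{EX}pb", RDFS_RANGE, f"{EX}X") in out.triples
        assert Triple(f"{EX}pc", RDFS_RANGE, f"{EX}X") in out.triples

    def test_no_subproperties_noop(self):
        onto = make_ontology(edges=[(f"{EX}a", f"{EX}b")])
        out, report = enrich_domain_range(onto)
        assert out == onto and not report.added


class TestConceptAxioms:
    def intersection(self, cls: str, members: list[str]) -> set[Triple]:
        head = cls + "-list"
        return {Triple(cls, OWL_INTERSECTION_OF, head)} | list_triples(head, members)

    def test_subclass_of_intersection(self):
        onto = make_ontology(
            triples=self.intersection(f"{EX}AB", [f"{EX}A", f"{EX}B"])
            | {Triple(f"{EX}C", RDFS_SUBCLASSOF, f"{EX}AB")}
        )
        out, _ = rewrite_concept_axioms(onto)
        assert Triple(f"{EX}C", RDFS_SUBCLASSOF, f"{EX}A") in out.triples
        assert Triple(f"{EX}C", RDFS_SUBCLASSOF, f"{EX}B") in out.triples

    def test_union_below_class(self):
        head = f"{EX}AB-list"
        onto = make_ontology(
            triples={Triple(f"{EX}AB", OWL_UNION_OF, head)}
            | list_triples(head, [f"{EX}A", f"{EX}B"])
            | {Triple(f"{EX}AB", RDFS_SUBCLASSOF, f"{EX}C")}
        )
        out, _ = rewrite_concept_axioms(onto)
        assert Triple(f"{EX}A", RDFS_SUBCLASSOF, f"{EX}C") in out.triples
        assert Triple(f"{EX}B", RDFS_SUBCLASSOF, f"{EX}C") in out.triples

    def test_ternary_intersection_memberwise(self):
        onto = make_ontology(
            triples=self.intersection(f"{EX}T", [f"{EX}A", f"{EX}B", f"{EX}C"])
            | {Triple(f"{EX}D", RDFS_SUBCLASSOF, f"{EX}T")}
        )
        out, report = rewrite_concept_axioms(onto)
        added_sub = {t for t in report.added if t.predicate == RDFS_SUBCLASSOF}
        assert added_sub == {
            Triple(f"{EX}D", RDFS_SUBCLASSOF, f"{EX}{m}") for m in "ABC"
        }

    def test_equivalent_class_mutual_subclass(self):
        onto = make_ontology(
            triples={Triple(f"{EX}A", OWL + "equivalentClass", f"{EX}B")}
        )
        out, _ = rewrite_concept_axioms(onto)
        assert Triple(f"{EX}A", RDFS_SUBCLASSOF, f"{EX}B") in out.triples
        assert Triple(f"{EX}B", RDFS_SUBCLASSOF, f"{EX}A") in out.triples

    def test_oneof_typing(self):
        head = f"{EX}enum-list"
        onto = make_ontology(
            triples={Triple(f"{EX}Enum", OWL + "oneOf", head)}
            | list_triples(head, [f"{EX}i1", f"{EX}i2"])
        )
        out, _ = rewrite_concept_axioms(onto)
        assert Triple(f"{EX}i1", RDF_TYPE, f"{EX}Enum") in out.triples
        assert Triple(f"{EX}i2", RDF_TYPE, f"{EX}Enum") in out.triples


class TestPropertyAxioms:
    def test_symmetric(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}p", RDF_TYPE, OWL + "SymmetricProperty"),
                Triple(f"{EX}A", f"{EX}p", f"{EX}B"),
            }
        )
        out, _ = rewrite_property_axioms(onto)
        assert Triple(f"{EX}B", f"{EX}p", f"{EX}A") in out.triples

    def test_transitive_chain(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}p", RDF_TYPE, OWL + "TransitiveProperty"),
                Triple(f"{EX}A", f"{EX}p", f"{EX}B"),
                Triple(f"{EX}B", f"{EX}p", f"{EX}C"),
                Triple(f"{EX}C", f"{EX}p", f"{EX}D"),
            }
        )
        out, report = rewrite_property_axioms(onto)
        added = {(t.subject, t.object) for t in report.added}
        assert added == {
            (f"{EX}A", f"{EX}C"),
            (f"{EX}A", f"{EX}D"),
            (f"{EX}B", f"{EX}D"),
        }

    @pytest.mark.parametrize("trial", range(5))
    def test_transitive_closure_matches_reachability_oracle(self, trial):
        """Closure on random digraphs (≤50 nodes) equals BFS reachability."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 51))
        g = nx.gnp_random_graph(n, 2.0 / n, directed=True, seed=int(rng.integers(1 << 30)))
        p = f"{EX}p"
        onto = make_ontology(
            triples={Triple(p, RDF_TYPE, OWL + "TransitiveProperty")}
            | {Triple(f"{EX}n{a}", p, f"{EX}n{b}") for a, b in g.edges}
        )
        out, _ = rewrite_property_axioms(onto)
        got = {(t.subject, t.object) for t in out.triples if t.predicate == p}
        # oracle: one-or-more-step reachability via boolean matrix powers
        A = np.zeros((n, n), dtype=bool)
        for a, b in g.edges:
            A[a, b] = True
        reach = A.copy()
        for _ in range(n):
            reach = reach | (reach @ A)
        expected = {
            (f"{EX}n{a}", f"{EX}n{b}") for a in range(n) for b in range(n) if reach[a, b]
        }
        assert got == expected


class TestSameAs:
    def test_pair_shares_statement(self):
        onto = make_ontology(
            triples={
                Triple(f"{EX}A", OWL_SAMEAS, f"{EX}B"),
                Triple(f"{EX}A", f"{EX}p", f"{EX}X"),
            }
        )
        out, _ = propagate_sameas(onto)
        assert Triple(f"{EX}B", f"{EX}p", f"{EX}X") in out.triples

    def test_chain_components_match_union_find_oracle(self):
        """A sameAs chain A~B~C shares all statements across the component."""
        rng = np.random.default_rng(3)
        names = [f"{EX}e{i}" for i in range(12)]
        links = {(names[int(rng.integers(12))], names[int(rng.integers(12))]) for _ in range(8)}
        facts = {Triple(n, f"{EX}p", f"{EX}v{i}") for i, n in enumerate(names[:6])}
        onto = make_ontology(
            triples={Triple(a, OWL_SAMEAS, b) for a, b in links if a != b} | facts
        )
        out, _ = propagate_sameas(onto)
        g = nx.Graph([(a, b) for a, b in links if a != b])
        for comp in nx.connected_components(g):
            values = {
                str(t.object)
                for t in facts
                if t.subject in comp
            }
            for member in comp:
                got = {
                    str(t.object)
                    for t in out.triples
                    if t.subject == member and t.predicate == f"{EX}p"
                }
                assert values <= got

    def test_no_sameas_noop(self):
        onto = make_ontology(edges=[(f"{EX}a", f"{EX}b")])
        out, report = propagate_sameas(onto)
        assert out == onto and not report.added


class TestHierarchyDomain:
    def test_domain_to_subclass(self):
        onto = make_ontology(
            edges=[(f"{EX}B", f"{EX}A")],
            triples={Triple(f"{EX}p", RDFS_DOMAIN, f"{EX}A")},
        )
        out, _ = propagate_domain_to_subclasses(onto)
        assert Triple(f"{EX}p", RDFS_DOMAIN, f"{EX}B") in out.triples

    def test_two_level_descendants(self):
        onto = make_ontology(
            edges=[(f"{EX}B", f"{EX}A"), (f"{EX}C", f"{EX}B")],
            triples={Triple(f"{EX}p", RDFS_DOMAIN, f"{EX}A")},
        )
        out, report = propagate_domain_to_subclasses(onto)
        assert {t.object for t in report.added} == {f"{EX}B", f"{EX}C"}

    def test_leaf_noop(self):
        onto = make_ontology(
            triples={Triple(f"{EX}p", RDFS_DOMAIN, f"{EX}A")}
        )
        out, report = propagate_domain_to_subclasses(onto)
        assert not report.added


class TestEnrichPipeline:
    def test_empty_rule_set_is_identity(self):
        onto = make_ontology(edges=[(f"{EX}a", f"{EX}b")])
        out, report = enrich(onto, rules=set())
        assert out == onto and not report.added

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            enrich(make_ontology(), rules={"telepathy"})

    def test_idempotent(self, physical_state_file):
        onto = load_ontology(physical_state_file)
        onto.triples |= {
            Triple(f"{EX}q", RDF_TYPE, OWL + "TransitiveProperty"),
            Triple(f"{EX}A", f"{EX}q", f"{EX}B"),
            Triple(f"{EX}B", f"{EX}q", f"{EX}C"),
        }
        once, _ = enrich(onto)
        twice, report = enrich(once)
        assert twice.triples == once.triples
        assert not report.added

    def test_combined_counts_match_single_rules(self, physical_state_file):
        onto = load_ontology(physical_state_file)
        onto.triples |= {
            Triple(f"{EX}q", RDF_TYPE, OWL + "TransitiveProperty"),
            Triple(f"{EX}A", f"{EX}q", f"{EX}B"),
            Triple(f"{EX}B", f"{EX}q", f"{EX}C"),
        }
        _, report = enrich(onto)
        assert report.rule_counts["flatten"] == 4
        assert report.rule_counts["property_axioms"] == 1
        assert len(report.added) == sum(report.rule_counts.values())

    def test_monotone_except_scaffolding(self):
        onto = make_ontology(
            edges=[(f"{EX}B", f"{EX}A")],
            triples={Triple(f"{EX}p", RDFS_DOMAIN, f"{EX}A")},
        )
        out, _ = enrich(onto)
        assert onto.triples <= out.triples


class TestAnchoringAndAugment:
    def test_normalization_forced_match(self):
        onto = make_ontology(labels={f"{EX}a": "Blood Vessel"})
        ext = make_ontology(labels={f"{EX}x": "blood  vessel"})
        anchors = anchor_concepts(onto, ext)
        assert anchors.anchors == {f"{EX}a": f"{EX}x"}

    def test_disjoint_vocabularies_empty(self):
        onto = make_ontology(labels={f"{EX}a": "aorta"})
        ext = make_ontology(labels={f"{EX}x": "femur"})
        assert len(anchor_concepts(onto, ext)) == 0

    def test_ambiguity_resolved_by_shared_label_count(self):
        onto = make_ontology(labels={f"{EX}a": ["vessel", "tube"]})
        ext = make_ontology(
            labels={f"{EX}x1": ["vessel"], f"{EX}x2": ["vessel", "tube"]}
        )
        anchors = anchor_concepts(onto, ext)
        assert anchors.anchors[f"{EX}a"] == f"{EX}x2"

    def test_augment_empty_anchor_noop(self):
        onto = make_ontology(labels={f"{EX}a": "aorta"})
        out, report = augment(onto, make_ontology(), AnchorMap())
        assert out == onto and not report.added

    def test_neighborhood_augmentation_transfers_relation(self):
        onto = make_ontology(labels={f"{EX}a": "aorta", f"{EX}b": "artery"})
        ext = make_ontology(
            labels={f"{EX}x": "aorta", f"{EX}y": "artery"},
            edges=[(f"{EX}x", f"{EX}y")],
        )
        anchors = anchor_concepts(onto, ext)
        out, _ = augment(onto, ext, anchors)
        assert Triple(f"{EX}a", RDFS_SUBCLASSOF, f"{EX}b") in out.triples

    def test_concept_augmentation_copies_labels(self):
        onto = make_ontology(labels={f"{EX}a": "aorta"})
        ext = make_ontology(
            labels={f"{EX}x": ["aorta", "great artery", "arteria maxima"]}
        )
        out, _ = augment(onto, ext, anchor_concepts(onto, ext))
        assert set(out.labels_of(f"{EX}a")) == {"aorta", "great artery", "arteria maxima"}

    def test_labels_never_removed_by_enrichment(self):
        onto = make_ontology(
            edges=[(f"{EX}B", f"{EX}A")],
            labels={f"{EX}A": "alpha", f"{EX}B": "beta"},
            triples={Triple(f"{EX}p", RDFS_DOMAIN, f"{EX}A")},
        )
        out, _ = enrich(onto)
        for iri, labs in onto.labels.items():
            assert set(labs) <= set(out.labels.get(iri, []))


def test_normalize_label():
    assert normalize_label("  Semi-Solid (state)! ") == "semi solid state"
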