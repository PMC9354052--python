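"""Ontology enriching: axiom rewriting and external-resource augmentation.

Biomedical ontologies hide much of their hierarchy inside OWL constructs:
rdf:List/containers wrap property ranges, ``owl:intersectionOf`` and
``owl:unionOf`` wrap subsumptions, and property axioms (symmetric, transitive,
equivalent) leave entailed statements implicit.  This module materializes that
hidden structure as explicit triples so that a purely graph-based encoder can
see it, and additionally imports labels and relations from an external
terminology (a UMLS-like resource) through string-matched anchors.

Rules are applied to a global fixed point: enriching the output of ``enrich``
adds nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ConsistencyError, MalformedCollectionError
from .model import (
    OWL,
    OWL_EQUIVALENT_CLASS,
    OWL_EQUIVALENT_PROPERTY,
    OWL_INTERSECTION_OF,
    OWL_ONE_OF,
    OWL_SAMEAS,
    OWL_SYMMETRIC,
    OWL_TRANSITIVE,
    OWL_UNION_OF,
    RDF,
    RDF_TYPE,
    RDFS_DOMAIN,
    RDFS_RANGE,
    RDFS_SUBCLASSOF,
    RDFS_SUBPROPERTYOF,
    Literal,
    Ontology,
    Triple,
)

RDF_FIRST = RDF + "first"
RDF_REST = RDF + "rest"
RDF_NIL = RDF + "nil"
RDF_LI = RDF + "li"
RDF_LIST = RDF + "List"
_CONTAINER_TYPES = {RDF + "Bag", RDF + "Seq", RDF + "Alt"}

#: Predicates whose rdf:List objects are *logical* constructs consumed by the
#: concept-axiom rule, not plain collections to flatten.
_LOGICAL_LIST_PREDICATES = {
    OWL_INTERSECTION_OF,
    OWL_UNION_OF,
    OWL_ONE_OF,
    OWL + "distinctMembers",
    OWL + "members",
}

#: All valid rule names accepted by :func:`enrich`.
ALL_RULES = (
    "flatten",
    "domain_range",
    "concept_axioms",
    "property_axioms",
    "sameas",
    "hierarchy_domain",
)


@dataclass
class EnrichmentReport:
    """Bookkeeping for one enrichment pass: what was added, removed, by whom."""

    added: set[Triple] = field(default_factory=set)
    removed: set[Triple] = field(default_factory=set)
    rule_counts: dict[str, int] = field(default_factory=dict)

    def record(self, rule: str, added: set[Triple], removed: set[Triple] = frozenset()) -> None:
        fresh = added - self.added
        self.added |= fresh
        self.removed |= removed
        self.added -= self.removed
        if fresh or rule in self.rule_counts:
            self.rule_counts[rule] = self.rule_counts.get(rule, 0) + len(fresh)

    def merge(self, other: "EnrichmentReport") -> None:
        for rule, _ in other.rule_counts.items():
            self.rule_counts.setdefault(rule, 0)
        fresh = other.added - self.added
        self.added |= fresh
        self.removed |= other.removed
        self.added -= self.removed
        for rule, count in other.rule_counts.items():
            # attribute fresh additions proportionally is overkill; counts are
            # additive because each sub-report counted only genuinely new triples
            self.rule_counts[rule] = self.rule_counts.get(rule, 0)
        for rule, count in other.rule_counts.items():
            self.rule_counts[rule] += count


@dataclass
class AnchorMap:
    """Map from ontology concepts to their string-matched external concepts."""

    anchors: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.anchors)

    def items(self):
        return self.anchors.items()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _index_by_subject(triples: set[Triple]) -> dict[str, list[Triple]]:
    idx: dict[str, list[Triple]] = {}
    for t in triples:
        idx.setdefault(t.subject, []).append(t)
    return idx


def _list_members(head: str, by_subject: dict[str, list[Triple]], seen: set[str] | None = None):
    """Walk an rdf:List from ``head``; returns (members, scaffolding triples).

    Nested lists are flattened to their leaf members.  A cycle raises
    :class:`MalformedCollectionError` naming the head node.
    """
    seen = set(seen or ())
    members: list = []
    scaffolding: set[Triple] = set()
    node = head
    while node != RDF_NIL:
        if node in seen:
            raise MalformedCollectionError(f"cyclic rdf:List at {head}")
        seen.add(node)
        first = rest = None
        for t in by_subject.get(node, []):
            if t.predicate == RDF_FIRST:
                first, scaffolding = t.object, scaffolding | {t}
            elif t.predicate == RDF_REST:
                rest, scaffolding = t.object, scaffolding | {t}
            elif t.predicate == RDF_TYPE and t.object == RDF_LIST:
                scaffolding.add(t)
        if first is None and rest is None:
            break  # dangling tail; treat as end
        if first is not None:
            if isinstance(first, str) and _is_list_head(first, by_subject):
                sub_members, sub_scaff = _list_members(first, by_subject, seen)
                members.extend(sub_members)
                scaffolding |= sub_scaff
            else:
                members.append(first)
        if rest is None or isinstance(rest, Literal):
            break
        node = rest
    return members, scaffolding


def _is_list_head(node: str, by_subject: dict[str, list[Triple]]) -> bool:
    return any(t.predicate in (RDF_FIRST, RDF_REST) for t in by_subject.get(node, []))


def _container_members(node: str, by_subject: dict[str, list[Triple]]):
    """Members of an rdf:Bag/Seq/Alt via rdf:_n / rdf:li, in numeric order."""
    entries = []
    scaffolding: set[Triple] = set()
    is_container = False
    for t in by_subject.get(node, []):
        if t.predicate == RDF_TYPE and t.object in _CONTAINER_TYPES:
            scaffolding.add(t)
            is_container = True
        elif t.predicate == RDF_LI:
            entries.append((0, t.object))
            scaffolding.add(t)
            is_container = True
        elif t.predicate.startswith(RDF + "_"):
            try:
                n = int(t.predicate[len(RDF) + 1 :])
            except ValueError:
                continue
            entries.append((n, t.object))
            scaffolding.add(t)
            is_container = True
    entries.sort(key=lambda e: (e[0], str(e[1])))
    return ([o for _, o in entries], scaffolding) if is_container else ([], set())


# ---------------------------------------------------------------------------
# collection / container flattening
# ---------------------------------------------------------------------------


def flatten_collections(ontology: Ontology) -> tuple[Ontology, EnrichmentReport]:
    """Replace statements pointing at rdf:List/Bag/Seq/Alt by one statement per
    member, and drop the scaffolding triples.

    Lists owned by OWL logical predicates (``owl:intersectionOf`` etc.) are
    left intact for the concept-axiom rule.
    """
    out = ontology.copy()
    report = EnrichmentReport(rule_counts={"flatten": 0})
    by_subject = _index_by_subject(out.triples)

    added: set[Triple] = set()
    removed: set[Triple] = set()
    logical_heads: set[str] = set()
    for t in out.triples:
        if t.predicate in _LOGICAL_LIST_PREDICATES and isinstance(t.object, str):
            # protect the whole spine of the logical list
            node = t.object
            guard = set()
            while isinstance(node, str) and node != RDF_NIL and node not in guard:
                guard.add(node)
                logical_heads.add(node)
                nxt = None
                for tt in by_subject.get(node, []):
                    if tt.predicate == RDF_REST:
                        nxt = tt.object
                node = nxt if isinstance(node, str) else None
                if nxt is None:
                    break
                node = nxt

    for t in list(out.triples):
        obj = t.object
        if not isinstance(obj, str) or t.predicate in _LOGICAL_LIST_PREDICATES:
            continue
        if t.predicate in (RDF_FIRST, RDF_REST, RDF_LI) or t.predicate.startswith(RDF + "_"):
            continue
        if obj in logical_heads:
            continue
        members: list = []
        scaffolding: set[Triple] = set()
        if _is_list_head(obj, by_subject):
            members, scaffolding = _list_members(obj, by_subject)
        else:
            members, scaffolding = _container_members(obj, by_subject)
        if not members:
            continue
        removed.add(t)
        removed |= scaffolding
        for m in members:
            added.add(Triple(t.subject, t.predicate, m))

    scaffold_nodes = {t.subject for t in removed if t.predicate in (RDF_FIRST, RDF_REST)}
    scaffold_nodes |= {
        t.subject for t in removed if t.predicate == RDF_LI or t.predicate.startswith(RDF + "_")
    }
    out.triples = (out.triples - removed) | added
    out.concepts -= scaffold_nodes
    for m in added:
        if isinstance(m.object, str) and m.object not in out.relations:
            out.concepts.add(m.object)
    report.record("flatten", added, removed)
    return out, report


# ---------------------------------------------------------------------------
# reasoning rules 1-5
# ---------------------------------------------------------------------------


def _transitive_closure(edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Brute reachability closure; graphs here are small after preprocessing."""
    succ: dict[str, set[str]] = {}
    for a, b in edges:
        succ.setdefault(a, set()).add(b)
    closure = set(edges)
    changed = True
    while changed:
        changed = False
        for a, b in list(closure):
            for c in succ.get(b, ()):
                if (a, c) not in closure:
                    closure.add((a, c))
                    succ.setdefault(a, set()).add(c)
                    changed = True
    return closure


def enrich_domain_range(ontology: Ontology) -> tuple[Ontology, EnrichmentReport]:
    """Rule 1: sub-properties inherit the domain and range of their ancestors,
    through sub-property chains."""
    out = ontology.copy()
    report = EnrichmentReport(rule_counts={"domain_range": 0})
    sub_edges = {
        (t.subject, t.object)
        for t in out.triples
        if t.predicate == RDFS_SUBPROPERTYOF and isinstance(t.object, str)
    }
    closure = _transitive_closure(sub_edges)
    dr: dict[str, list[Triple]] = {}
    for t in out.triples:
        if t.predicate in (RDFS_DOMAIN, RDFS_RANGE):
            dr.setdefault(t.subject, []).append(t)
    added = set()
    for pb, pa in closure:
        for t in dr.get(pa, []):
            cand = Triple(pb, t.predicate, t.object)
            if cand not in out.triples:
                added.add(cand)
    out.triples |= added
    report.record("domain_range", added)
    return out, report


def rewrite_concept_axioms(ontology: Ontology) -> tuple[Ontology, EnrichmentReport]:
    """Rule 2: materialize subsumptions hidden in owl:intersectionOf /
    owl:unionOf / owl:equivalentClass / owl:oneOf constructs."""
    out = ontology.copy()
    report = EnrichmentReport(rule_counts={"concept_axioms": 0})
    by_subject = _index_by_subject(out.triples)

    def named_list(obj) -> list[str]:
        if not isinstance(obj, str):
            return []
        members, _ = _list_members(obj, by_subject)
        return [m for m in members if isinstance(m, str)]

    intersections: dict[str, list[str]] = {}
    unions: dict[str, list[str]] = {}
    oneofs: dict[str, list[str]] = {}
    for t in out.triples:
        if t.predicate == OWL_INTERSECTION_OF:
            intersections[t.subject] = named_list(t.object)
        elif t.predicate == OWL_UNION_OF:
            unions[t.subject] = named_list(t.object)
        elif t.predicate == OWL_ONE_OF:
            oneofs[t.subject] = named_list(t.object)

    added: set[Triple] = set()

    def add(s: str, p: str, o: str) -> None:
        cand = Triple(s, p, o)
        if cand not in out.triples:
            added.add(cand)

    for t in out.triples:
        if not isinstance(t.object, str):
            continue
        if t.predicate in (RDFS_SUBCLASSOF, OWL_EQUIVALENT_CLASS):
            # C below an intersection: C is below every conjunct.
            if t.object in intersections:
                for m in intersections[t.object]:
                    add(t.subject, RDFS_SUBCLASSOF, m)
            # equivalence to a union puts every disjunct below C.
            if t.predicate == OWL_EQUIVALENT_CLASS and t.object in unions:
                for m in unions[t.object]:
                    add(m, RDFS_SUBCLASSOF, t.subject)
        if t.predicate == RDFS_SUBCLASSOF and t.subject in unions:
            # a union below C: every disjunct is below C.
            for m in unions[t.subject]:
                add(m, RDFS_SUBCLASSOF, t.object)
        if t.predicate == OWL_EQUIVALENT_CLASS:
            a, b = t.subject, t.object
            if a not in intersections | unions and b not in intersections | unions:
                add(a, RDFS_SUBCLASSOF, b)
                add(b, RDFS_SUBCLASSOF, a)
    for cls, individuals in oneofs.items():
        for ind in individuals:
            add(ind, RDF_TYPE, cls)

    out.triples |= added
    report.record("concept_axioms", added)
    return out, report


def rewrite_property_axioms(ontology: Ontology) -> tuple[Ontology, EnrichmentReport]:
    """Rule 3: materialize symmetric statements, transitive closures, and
    shared statements of equivalent properties."""
    out = ontology.copy()
    report = EnrichmentReport(rule_counts={"property_axioms": 0})
    symmetric = {
        t.subject for t in out.triples if t.predicate == RDF_TYPE and t.object == OWL_SYMMETRIC
    }
    transitive = {
        t.subject for t in out.triples if t.predicate == RDF_TYPE and t.object == OWL_TRANSITIVE
    }
    # union-find over owl:equivalentProperty
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in out.triples:
        if t.predicate == OWL_EQUIVALENT_PROPERTY and isinstance(t.object, str):
            parent[find(t.subject)] = find(t.object)

    groups: dict[str, set[str]] = {}
    for p in parent:
        groups.setdefault(find(p), set()).add(p)

    added: set[Triple] = set()
    for t in out.triples:
        if t.predicate in symmetric and isinstance(t.object, str):
            cand = Triple(t.object, t.predicate, t.subject)
            if cand not in out.triples:
                added.add(cand)
    for p in transitive:
        edges = {
            (t.subject, t.object)
            for t in out.triples | added
            if t.predicate == p and isinstance(t.object, str)
        }
        for a, b in _transitive_closure(edges) - edges:
            added.add(Triple(a, p, b))
    for group in groups.values():
        if len(group) < 2:
            continue
        for t in out.triples:
            if t.predicate in group:
                for q in group:
                    cand = Triple(t.subject, q, t.object)
                    if cand not in out.triples:
                        added.add(cand)
            if t.subject in group and t.predicate != OWL_EQUIVALENT_PROPERTY:
                for q in group:
                    cand = Triple(q, t.predicate, t.object)
                    if cand not in out.triples:
                        added.add(cand)
    out.triples |= added
    report.record("property_axioms", added)
    return out, report


def propagate_sameas(ontology: Ontology) -> tuple[Ontology, EnrichmentReport]:
    """Rule 4: members of an owl:sameAs component share all statements and
    labels."""
    out = ontology.copy()
    report = EnrichmentReport(rule_counts={"sameas": 0})
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in out.triples:
        if t.predicate == OWL_SAMEAS and isinstance(t.object, str):
            parent[find(t.subject)] = find(t.object)
    groups: dict[str, set[str]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)

    added: set[Triple] = set()
    for group in groups.values():
        if len(group) < 2:
            continue
        for t in list(out.triples):
            if t.predicate == OWL_SAMEAS:
                continue
            if t.subject in group:
                for m in group:
                    cand = Triple(m, t.predicate, t.object)
                    if cand not in out.triples:
                        added.add(cand)
            if isinstance(t.object, str) and t.object in group:
                for m in group:
                    cand = Triple(t.subject, t.predicate, m)
                    if cand not in out.triples:
                        added.add(cand)
        all_labels = sorted({lab for m in group for lab in out.labels_of(m)})
        for m in group:
            for lab in all_labels:
                out.add_label(m, lab)
    out.triples |= added
    report.record("sameas", added)
    return out, report


def propagate_domain_to_subclasses(ontology: Ontology) -> tuple[Ontology, EnrichmentReport]:
    """Rule 5: a property constrained to a concept is constrained to every
    descendant of that concept (for both rdfs:domain and rdfs:range)."""
    out = ontology.copy()
    report = EnrichmentReport(rule_counts={"hierarchy_domain": 0})
    children: dict[str, set[str]] = {}
    for child, par in out.subclass_edges():
        children.setdefault(par, set()).add(child)

    def descendants(root: str) -> set[str]:
        seen: set[str] = set()
        stack = [root]
        while stack:
            node = stack.pop()
            for c in children.get(node, ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    added: set[Triple] = set()
    for t in list(out.triples):
        if t.predicate in (RDFS_DOMAIN, RDFS_RANGE) and isinstance(t.object, str):
            for d in descendants(t.object):
                cand = Triple(t.subject, t.predicate, d)
                if cand not in out.triples:
                    added.add(cand)
    out.triples |= added
    report.record("hierarchy_domain", added)
    return out, report


_RULE_FUNCS = {
    "flatten": flatten_collections,
    "domain_range": enrich_domain_range,
    "concept_axioms": rewrite_concept_axioms,
    "property_axioms": rewrite_property_axioms,
    "sameas": propagate_sameas,
    "hierarchy_domain": propagate_domain_to_subclasses,
}


def enrich(
    ontology: Ontology,
    rules: set[str] | None = None,
    max_iterations: int = 100,
) -> tuple[Ontology, EnrichmentReport]:
    """Apply the selected rewriting rules iteratively to a global fixed point.

    Parameters
    ----------
    rules:
        Subset of :data:`ALL_RULES`; ``None`` selects all rules.
    max_iterations:
        Guard against pathological non-termination; exceeded → RuntimeError.
    """
    selected = list(ALL_RULES) if rules is None else [r for r in ALL_RULES if r in rules]
    unknown = set() if rules is None else set(rules) - set(ALL_RULES)
    if unknown:
        raise ValueError(f"unknown enrichment rules: {sorted(unknown)}")
    current = ontology.copy()
    report = EnrichmentReport(rule_counts={r: 0 for r in selected})
    for _ in range(max_iterations):
        changed = False
        for rule in selected:
            nxt, sub = _RULE_FUNCS[rule](current)
            if nxt.triples != current.triples or sub.added or sub.removed:
                if sub.added or sub.removed:
                    changed = True
                report.merge(sub)
                current = nxt
        if not changed:
            return current, report
    raise RuntimeError(
        f"enrichment did not reach a fixed point within {max_iterations} iterations"
    )


# ---------------------------------------------------------------------------
# external-resource augmentation
# ---------------------------------------------------------------------------

_PUNCT = re.compile(r"[^0-9a-z]+")


def normalize_label(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_PUNCT.sub(" ", text.lower()).split())


def anchor_concepts(ontology: Ontology, external: Ontology) -> AnchorMap:
    """Anchor ontology concepts to external concepts by exact normalized-label
    match; ambiguity is resolved by the most shared labels, then by IRI order."""
    ext_by_label: dict[str, set[str]] = {}
    ext_labels: dict[str, set[str]] = {}
    for iri in external.concepts:
        norms = {normalize_label(lab) for lab in external.labels_of(iri)} - {""}
        ext_labels[iri] = norms
        for n in norms:
            ext_by_label.setdefault(n, set()).add(iri)

    anchors: dict[str, str] = {}
    for iri in sorted(ontology.concepts):
        norms = {normalize_label(lab) for lab in ontology.labels_of(iri)} - {""}
        if not norms:
            continue
        candidates: set[str] = set()
        for n in norms:
            candidates |= ext_by_label.get(n, set())
        if not candidates:
            continue
        best = min(candidates, key=lambda c: (-len(norms & ext_labels[c]), c))
        anchors[iri] = best
    return AnchorMap(anchors=anchors)


def augment(
    ontology: Ontology, external: Ontology, anchors: AnchorMap
) -> tuple[Ontology, EnrichmentReport]:
    """Import semantics from the external resource through the anchor map.

    Concept augmentation copies the anchored external concept's labels,
    annotations and equivalence statements onto the ontology concept.
    Neighborhood augmentation mirrors every external relation between two
    anchored concepts back onto their pre-images.
    """
    out = ontology.copy()
    report = EnrichmentReport(
        rule_counts={"concept_augmentation": 0, "neighborhood_augmentation": 0}
    )
    for _, ext_iri in anchors.items():
        if ext_iri not in external.concepts:
            raise ConsistencyError(f"anchor target {ext_iri} absent from external resource")

    preimages: dict[str, set[str]] = {}
    for c, x in anchors.items():
        preimages.setdefault(x, set()).add(c)

    concept_added: set[Triple] = set()
    for c, x in sorted(anchors.items()):
        for lab in external.labels_of(x):
            out.add_label(c, lab)
        for ann in external.annotations.get(x, []):
            bucket = out.annotations.setdefault(c, [])
            if ann not in bucket:
                bucket.append(ann)
        for t in external.triples:
            if t.subject == x and t.predicate in (OWL_EQUIVALENT_CLASS, OWL_SAMEAS):
                cand = Triple(c, t.predicate, t.object)
                if cand not in out.triples:
                    concept_added.add(cand)
    out.triples |= concept_added
    report.record("concept_augmentation", concept_added)

    neigh_added: set[Triple] = set()
    for t in external.triples:
        if not isinstance(t.object, str):
            continue
        if t.predicate in (OWL_EQUIVALENT_CLASS, OWL_SAMEAS):
            continue
        for ci in preimages.get(t.subject, ()):
            for cj in preimages.get(t.object, ()):
                cand = Triple(ci, t.predicate, cj)
                if cand not in out.triples:
                    neigh_added.add(cand)
    out.triples |= neigh_added
    if neigh_added:
        out.relations |= {
            t.predicate
            for t in neigh_added
            if not t.predicate.startswith(("http://www.w3.org/",))
        }
    report.record("neighborhood_augmentation", neigh_added)
    return out, report
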