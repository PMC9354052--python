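"""Synthetic paired ontologies with known ground truth.

Real biomedical matching tasks pit two independently built terminologies
against each other: the same concepts appear under different labels
(synonyms), unrelated concepts share a label (homonyms), hierarchies are
organized at different granularities (levels collapsed or inserted), and part
of the subsumption structure hides inside OWL constructs.  This module
generates a rooted subClassOf tree, derives a heterogeneous copy by applying
exactly those four distortions with known bookkeeping, and can emit a
pseudo-terminology of "hub" concepts that carries both sides' labels — the
role an external resource such as UMLS plays for anchoring and augmentation.

Labels are deterministic pseudoword phrases from a seeded syllable pool, so
fixtures require no downloads and matching difficulty is controlled purely
structurally.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ValidationError
from .model import (
    OWL_INTERSECTION_OF,
    RDF,
    RDFS_SUBCLASSOF,
    Alignment,
    Correspondence,
    Ontology,
    Relation,
    Triple,
)

SRC_NS = "http://example.org/source#"
TGT_NS = "http://example.org/target#"
EXT_NS = "http://example.org/external#"

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu "
    "ka ke ki ko ku la le li lo lu ma me mi mo mu na ne ni no nu "
    "pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu "
    "va ve vi vo vu za ze zi zo zu"
).split()


@dataclass
class FixtureSpec:
    """Generation parameters for one paired-ontology fixture.

    The defaults are the package's standard study conditions: a 50-concept
    tree with branching 3, 30% synonym replacement, 10% level collapse or
    insertion, two injected homonym collisions and 20% of subsumptions hidden
    behind intersection axioms.
    """

    n_concepts: int = 50
    branching: int = 3
    max_depth: int = 6
    synonym_rate: float = 0.3
    level_collapse_rate: float = 0.1
    homonym_count: int = 2
    axiom_hiding_rate: float = 0.2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_concepts < 2:
            raise ValidationError("n_concepts must be at least 2")
        for name in ("synonym_rate", "level_collapse_rate", "axiom_hiding_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.homonym_count < 0 or self.branching < 1 or self.max_depth < 1:
            raise ValidationError("homonym_count/branching/max_depth must be valid")


def _word_pool(rng: np.random.Generator, count: int) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < count:
        n_syll = int(rng.integers(2, 4))
        w = "".join(_SYLLABLES[rng.integers(len(_SYLLABLES))] for _ in range(n_syll))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _term_bank(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Per-concept (primary label, synonym label) pairs, unique across bank.

    A synonym keeps the primary's head word but reorders and swaps the
    modifier ("kedo zodu" → "zodu rafi"), mirroring how terminology synonyms
    usually share a stem while differing in form — the partial lexical
    relatedness a domain language model would also surface for true synonym
    pairs.
    """
    rng = np.random.default_rng(spec.seed)
    words = _word_pool(rng, 3 * spec.n_concepts + 8)
    bank = []
    for i in range(spec.n_concepts):
        a, b, c = words[3 * i], words[3 * i + 1], words[3 * i + 2]
        primary = f"{a} {b}"
        synonym = f"{b} {c}"
        bank.append((primary, synonym))
    return bank


def _tree_parents(spec: FixtureSpec) -> list[int]:
    """Parent index for each node >0, respecting branching and max_depth."""
    rng = np.random.default_rng(spec.seed + 17)
    parents = [-1]
    depth = [0]
    child_count = [0]
    for i in range(1, spec.n_concepts):
        eligible = [
            j
            for j in range(i)
            if child_count[j] < spec.branching and depth[j] < spec.max_depth - 1
        ]
        if not eligible:
            eligible = [j for j in range(i) if depth[j] < spec.max_depth - 1] or [0]
        p = int(eligible[rng.integers(len(eligible))])
        parents.append(p)
        depth.append(depth[p] + 1)
        child_count.append(0)
        child_count[p] += 1
    return parents


def generate_source(spec: FixtureSpec) -> Ontology:
    """A rooted subClassOf tree of ``n_concepts`` with unique labels."""
    bank = _term_bank(spec)
    parents = _tree_parents(spec)
    onto = Ontology()
    iris = [f"{SRC_NS}C{i:04d}" for i in range(spec.n_concepts)]
    for i, iri in enumerate(iris):
        onto.concepts.add(iri)
        onto.add_label(iri, bank[i][0])
        if i > 0:
            onto.triples.add(Triple(iri, RDFS_SUBCLASSOF, iris[parents[i]]))
    return onto


def derive_target(source: Ontology, spec: FixtureSpec) -> tuple[Ontology, Alignment]:
    """Heterogeneous copy of ``source`` plus the ground-truth alignment.

    Applies, in order: level collapse/insertion, synonym replacement,
    homonym injection, and axiom hiding (subClassOf re-expressed through
    owl:intersectionOf with rdf:List scaffolding).  The alignment covers
    exactly the source concepts that survive the level operations.
    """
    bank = _term_bank(spec)
    rng = np.random.default_rng(spec.seed + 101)
    n = spec.n_concepts
    src_iris = [f"{SRC_NS}C{i:04d}" for i in range(n)]
    tgt_iris = [f"{TGT_NS}D{i:04d}" for i in range(n)]
    if set(src_iris) - source.concepts:
        raise ConfigurationError("source was not produced by generate_source")

    parent: dict[int, int] = {}
    for t in source.triples:
        if t.predicate == RDFS_SUBCLASSOF:
            parent[src_iris.index(t.subject)] = src_iris.index(t.object)
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    # --- level collapse / insertion -------------------------------------
    removed: set[int] = set()
    internal = sorted(i for i in range(1, n) if children.get(i))
    for i in internal:
        u = rng.random()
        if u < spec.level_collapse_rate / 2 and i in parent:
            removed.add(i)  # children re-wired to grandparent below
        # insertion handled separately (new nodes, no alignment entry)
    inserted: list[tuple[int, str]] = []  # (child index, new node IRI)
    for i in sorted(i for i in range(1, n) if i not in removed):
        if rng.random() < spec.level_collapse_rate / 2 and i in parent:
            inserted.append((i, f"{TGT_NS}X{len(inserted):03d}"))

    def surviving_parent(i: int) -> int | None:
        p = parent.get(i)
        while p is not None and p in removed:
            p = parent.get(p)
        return p

    survivors = [i for i in range(n) if i not in removed]
    target = Ontology()
    extra_words = _word_pool(np.random.default_rng(spec.seed + 202), 2 * len(inserted) + 2)
    insert_map = {i: iri for i, iri in inserted}
    edges: list[tuple[str, str]] = []
    for idx, (i, new_iri) in enumerate(inserted):
        target.concepts.add(new_iri)
        target.add_label(new_iri, f"{extra_words[2 * idx]} {extra_words[2 * idx + 1]}")
    for i in survivors:
        target.concepts.add(tgt_iris[i])
        p = surviving_parent(i)
        if p is None and i != 0:
            p = 0
        if i == 0:
            continue
        if i in insert_map:
            edges.append((tgt_iris[i], insert_map[i]))
            edges.append((insert_map[i], tgt_iris[p]))
        else:
            edges.append((tgt_iris[i], tgt_iris[p]))

    # --- labels: synonyms then homonyms ---------------------------------
    for i in survivors:
        use_synonym = rng.random() < spec.synonym_rate
        target.add_label(tgt_iris[i], bank[i][1] if use_synonym else bank[i][0])
    adjacent = {frozenset(e) for e in edges}
    survivor_iris = [tgt_iris[i] for i in survivors]
    placed = 0
    for _ in range(20 * spec.homonym_count):
        if placed >= spec.homonym_count or len(survivor_iris) < 3:
            break
        a = survivor_iris[rng.integers(len(survivor_iris))]
        b = survivor_iris[rng.integers(len(survivor_iris))]
        if a == b or frozenset((a, b)) in adjacent:
            continue
        target.labels[b] = list(target.labels[a])
        placed += 1

    # --- axiom hiding ----------------------------------------------------
    # a dedicated generic concept plays the second conjunct, mimicking the
    # broad "defined concept = parent AND some-category" axioms of clinical
    # terminologies; it has no ground-truth counterpart
    filler = f"{TGT_NS}G0000"
    rdf_first, rdf_rest, rdf_nil = RDF + "first", RDF + "rest", RDF + "nil"
    bn_count = 0
    for child, par in edges:
        if rng.random() < spec.axiom_hiding_rate:
            cls = f"{TGT_NS}bn/and{bn_count:03d}"
            l1 = f"{TGT_NS}bn/list{bn_count:03d}a"
            l2 = f"{TGT_NS}bn/list{bn_count:03d}b"
            bn_count += 1
            target.triples |= {
                Triple(child, RDFS_SUBCLASSOF, cls),
                Triple(cls, OWL_INTERSECTION_OF, l1),
                Triple(l1, rdf_first, par),
                Triple(l1, rdf_rest, l2),
                Triple(l2, rdf_first, filler),
                Triple(l2, rdf_rest, rdf_nil),
            }
            target.concepts |= {cls, l1, l2}
            if filler not in target.concepts:
                target.concepts.add(filler)
                target.add_label(filler, "generic entity")
        else:
            target.triples.add(Triple(child, RDFS_SUBCLASSOF, par))

    reference = Alignment(source_ontology=SRC_NS, target_ontology=TGT_NS)
    for i in survivors:
        reference.correspondences.add(
            Correspondence(src_iris[i], tgt_iris[i], Relation.EQUIVALENCE, 1.0)
        )
    if not target.concepts:
        raise ValidationError("distortion rates produced an empty target ontology")
    return target, reference


def hidden_edge_bookkeeping(spec: FixtureSpec) -> dict[str, int]:
    """Counts the generator can certify: total target edges and hidden ones."""
    source = generate_source(spec)
    target, _ = derive_target(source, spec)
    plain = len(target.subclass_edges()) - sum(
        1 for t in target.triples if t.predicate == RDFS_SUBCLASSOF and "bn/" in str(t.object)
    )
    hidden = sum(
        1 for t in target.triples if t.predicate == OWL_INTERSECTION_OF
    )
    return {"plain_subclass": plain, "hidden_subclass": hidden}


def generate_external(
    source: Ontology,
    target: Ontology,
    coverage: float = 1.0,
    seed: int = 0,
) -> Ontology:
    """Pseudo-terminology of hub concepts carrying both sides' labels.

    For a ``coverage`` fraction of ground-truth pairs (identified through the
    generator's index-based IRI convention) a hub concept is created whose
    labels are the union of the pair's labels; hub-hub subClassOf edges mirror
    the source hierarchy between covered pairs, so anchoring and augmentation
    have deterministic expected effects.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValidationError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def index_of(iri: str) -> int | None:
        local = iri.rsplit("#", 1)[-1]
        if len(local) > 1 and local[0] in "CD" and local[1:].isdigit():
            return int(local[1:])
        return None

    src_by_idx = {index_of(c): c for c in source.concepts if index_of(c) is not None}
    tgt_by_idx = {index_of(c): c for c in target.concepts if index_of(c) is not None}
    common = sorted(set(src_by_idx) & set(tgt_by_idx))
    n_cover = int(round(coverage * len(common)))
    covered = sorted(rng.choice(common, size=n_cover, replace=False).tolist()) if n_cover else []

    external = Ontology()
    hub_of: dict[int, str] = {}
    for i in covered:
        hub = f"{EXT_NS}H{i:04d}"
        hub_of[i] = hub
        external.concepts.add(hub)
        for lab in source.labels_of(src_by_idx[i]) + target.labels_of(tgt_by_idx[i]):
            external.add_label(hub, lab)
    covered_set = set(covered)
    for t in source.triples:
        if t.predicate != RDFS_SUBCLASSOF or not isinstance(t.object, str):
            continue
        ci, pi = index_of(t.subject), index_of(t.object)
        if ci in covered_set and pi in covered_set:
            external.triples.add(Triple(hub_of[ci], RDFS_SUBCLASSOF, hub_of[pi]))
    return external


def split_seeds(reference: Alignment, fraction: float, seed: int) -> Alignment:
    """Deterministically sample a fraction of the reference as training seeds."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ordered = sorted(reference.correspondences, key=lambda c: (c.source, c.target))
    k = int(round(fraction * len(ordered)))
    chosen = rng.choice(len(ordered), size=k, replace=False) if k else []
    return Alignment(
        correspondences={ordered[int(i)] for i in chosen},
        source_ontology=reference.source_ontology,
        target_ontology=reference.target_ontology,
    )


def standard_pair(seed: int = 42):
    """The standard synthetic matching task: spec defaults at ``seed``.

    Returns (source, target, reference, seeds) with 30% of the reference as
    training seeds.
    """
    spec = FixtureSpec(seed=seed)
    source = generate_source(spec)
    target, reference = derive_target(source, spec)
    seeds = split_seeds(reference, 0.3, seed=seed + 7)
    return source, target, reference, seeds


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path, seed_fraction: float = 0.3,
                      coverage: float = 1.0) -> dict:
    """Emit source.ttl, target.ttl, external.ttl, reference.rdf, seeds.rdf and
    ledger.json into ``out_dir``; returns the ledger dictionary."""
    from .ontology_io import write_alignment, write_ontology

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    source = generate_source(spec)
    target, reference = derive_target(source, spec)
    external = generate_external(source, target, coverage=coverage, seed=spec.seed)
    seeds = split_seeds(reference, seed_fraction, seed=spec.seed + 7)
    write_ontology(source, out / "source.ttl")
    write_ontology(target, out / "target.ttl")
    write_ontology(external, out / "external.ttl")
    write_alignment(reference, out / "reference.rdf")
    write_alignment(seeds, out / "seeds.rdf")
    ledger = {
        "spec": asdict(spec),
        "n_reference": len(reference),
        "n_seeds": len(seeds),
        "n_source_concepts": len(source.concepts),
        "n_target_concepts": len(target.concepts),
        **hidden_edge_bookkeeping(spec),
    }
    (out / "ledger.json").write_text(json.dumps(ledger, indent=2), encoding="utf-8")
    return ledger
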