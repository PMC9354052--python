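"""The paired-ontology generator: tree shape, distortions, bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest

from biohan.enrichment import anchor_concepts, augment, enrich
from biohan.errors import ValidationError
from biohan.model import RDFS_SUBCLASSOF
from biohan.synthetic_fixtures import (
    FixtureSpec,
    derive_target,
    generate_external,
    generate_source,
    split_seeds,
    write_fixture_dir,
)

ZERO_RATES = dict(synonym_rate=0.0, level_collapse_rate=0.0, homonym_count=0,
                  axiom_hiding_rate=0.0)


class TestGenerateSource:
    def test_minimum_size_rejected(self):
        with pytest.raises(ValidationError):
            FixtureSpec(n_concepts=1)

    def test_two_concepts(self):
        onto = generate_source(FixtureSpec(n_concepts=2, seed=0))
        assert len(onto.concepts) == 2
        assert len(onto.subclass_edges()) == 1

    def test_tree_property(self):
        onto = generate_source(FixtureSpec(n_concepts=50, branching=3, seed=1))
        assert len(onto.subclass_edges()) == 49  # |E| = |V| − 1

    def test_branching_respected(self):
        onto = generate_source(FixtureSpec(n_concepts=40, branching=3, max_depth=12, seed=2))
        children = {}
        for child, parent in onto.subclass_edges():
            children.setdefault(parent, []).append(child)
        assert max(len(v) for v in children.values()) <= 3

    def test_deterministic(self):
        s1 = generate_source(FixtureSpec(n_concepts=30, seed=7))
        s2 = generate_source(FixtureSpec(n_concepts=30, seed=7))
        assert s1 == s2

    def test_unique_labels(self):
        onto = generate_source(FixtureSpec(n_concepts=50, seed=3))
        labels = [lab for labs in onto.labels.values() for lab in labs]
        assert len(labels) == len(set(labels))


class TestDeriveTarget:
    def test_zero_rates_isomorphic_copy(self):
        spec = FixtureSpec(n_concepts=20, seed=4, **ZERO_RATES)
        source = generate_source(spec)
        target, reference = derive_target(source, spec)
        assert len(reference) == 20
        assert len(target.subclass_edges()) == len(source.subclass_edges())
        src_labels = sorted(l for labs in source.labels.values() for l in labs)
        tgt_labels = sorted(l for labs in target.labels.values() for l in labs)
        assert src_labels == tgt_labels

    def test_full_axiom_hiding_recoverable(self):
        """With every subsumption hidden, no plain isA edge points at a named
        parent, and enrichment recovers at least the original edge set."""
        spec = FixtureSpec(n_concepts=10, seed=5, synonym_rate=0.0,
                           level_collapse_rate=0.0, homonym_count=0,
                           axiom_hiding_rate=1.0)
        source = generate_source(spec)
        target, _ = derive_target(source, spec)
        plain = {
            (t.subject, t.object)
            for t in target.triples
            if t.predicate == RDFS_SUBCLASSOF and "bn/" not in str(t.object)
        }
        assert plain == set()
        enriched, _ = enrich(target)
        recovered = {
            (s.rsplit("#", 1)[-1][1:], o.rsplit("#", 1)[-1][1:])
            for s, o in enriched.subclass_edges()
            if "bn/" not in o and "G0000" not in o
        }
        original = {
            (s.rsplit("#", 1)[-1][1:], o.rsplit("#", 1)[-1][1:])
            for s, o in source.subclass_edges()
        }
        assert original <= recovered

    @pytest.mark.parametrize("hiding", [0.2, 0.5])
    def test_recovery_rate_at_partial_hiding(self, hiding):
        """Enrichment recovers ≥95% of hidden subsumptions (it recovers all:
        the rewrite rule is exact on the generator's constructs)."""
        spec = FixtureSpec(n_concepts=40, seed=8, synonym_rate=0.0,
                           level_collapse_rate=0.0, homonym_count=0,
                           axiom_hiding_rate=hiding)
        source = generate_source(spec)
        target, _ = derive_target(source, spec)
        before = {(s, o) for s, o in target.subclass_edges() if "bn/" not in o}
        enriched, _ = enrich(target)
        after = {(s, o) for s, o in enriched.subclass_edges() if "bn/" not in o and "G0000" not in o}
        total_expected = len(source.subclass_edges())
        hidden = total_expected - len(before)
        assert hidden > 0
        recovered_hidden = len(after) - len(before)
        assert recovered_hidden / hidden >= 0.95

    def test_level_collapse_bookkeeping(self):
        spec = FixtureSpec(n_concepts=50, seed=42, synonym_rate=0.0,
                           level_collapse_rate=0.2, homonym_count=0,
                           axiom_hiding_rate=0.0)
        source = generate_source(spec)
        target, reference = derive_target(source, spec)
        surviving = {c for c in target.concepts if "#D" in c}
        assert len(reference) == len(surviving)
        assert reference.is_one_to_one()

    def test_deterministic(self):
        spec = FixtureSpec(n_concepts=25, seed=10)
        source = generate_source(spec)
        t1, r1 = derive_target(source, spec)
        t2, r2 = derive_target(source, spec)
        assert t1 == t2 and r1.pairs() == r2.pairs()


class TestGenerateExternal:
    def test_zero_coverage_no_anchors(self):
        spec = FixtureSpec(n_concepts=15, seed=11, **ZERO_RATES)
        source = generate_source(spec)
        target, _ = derive_target(source, spec)
        external = generate_external(source, target, coverage=0.0, seed=0)
        assert len(anchor_concepts(source, external)) == 0

    def test_full_coverage_anchors_everything(self):
        spec = FixtureSpec(n_concepts=15, seed=12, **ZERO_RATES)
        source = generate_source(spec)
        target, _ = derive_target(source, spec)
        external = generate_external(source, target, coverage=1.0, seed=0)
        assert len(anchor_concepts(source, external)) == 15
        assert len(anchor_concepts(target, external)) == 15

    def test_hub_edges_transfer_through_augmentation(self):
        """One hub subClassOf edge yields one augmented edge per side."""
        spec = FixtureSpec(n_concepts=12, seed=13, synonym_rate=1.0,
                           level_collapse_rate=0.0, homonym_count=0,
                           axiom_hiding_rate=0.0)
        source = generate_source(spec)
        target, _ = derive_target(source, spec)
        external = generate_external(source, target, coverage=1.0, seed=0)
        n_hub_edges = len(external.subclass_edges())
        assert n_hub_edges > 0
        for onto in (source, target):
            anchors = anchor_concepts(onto, external)
            augmented, report = augment(onto, external, anchors)
            mirrored = {
                (a, b)
                for a, b in augmented.subclass_edges()
                if (a, b) not in onto.subclass_edges()
            }
            # every hub edge maps back onto an (already present or new) edge
            assert len(mirrored) <= n_hub_edges
            assert augmented.subclass_edges() >= onto.subclass_edges()

    def test_synonym_bridge_via_external(self):
        """With full synonym replacement, anchoring still joins both sides
        through hubs that carry the union of labels."""
        spec = FixtureSpec(n_concepts=10, seed=14, synonym_rate=1.0,
                           level_collapse_rate=0.0, homonym_count=0,
                           axiom_hiding_rate=0.0)
        source = generate_source(spec)
        target, _ = derive_target(source, spec)
        external = generate_external(source, target, coverage=1.0, seed=0)
        a_src = anchor_concepts(source, external)
        a_tgt = anchor_concepts(target, external)
        # hubs anchored from both sides identify the ground-truth pairs
        joined = {
            (c_s, c_t)
            for c_s, x_s in a_src.items()
            for c_t, x_t in a_tgt.items()
            if x_s == x_t
        }
        assert len(joined) == 10


@pytest.mark.parametrize("seed", range(5))
def test_end_to_end_smoke_zero_heterogeneity(seed):
    """With no distortions and no external resource the full pipeline
    (enrich → embed → train → match) recovers the identity alignment."""
    from biohan.training_eval import TrainingConfig, evaluate, train

    spec = FixtureSpec(n_concepts=16, seed=seed, **ZERO_RATES)
    source = generate_source(spec)
    target, reference = derive_target(source, spec)
    seeds_alignment = split_seeds(reference, 0.3, seed=seed + 1)
    src_e, _ = enrich(source)
    tgt_e, _ = enrich(target)
    cfg = TrainingConfig(epochs=200, input_dim=128, dim=32, seed=seed)
    result = train(src_e, tgt_e, seeds_alignment, cfg)
    assert evaluate(result.alignment, reference) == (1.0, 1.0, 1.0)


class TestSplitSeedsAndFixtureDir:
    def test_split_fraction(self):
        spec = FixtureSpec(n_concepts=30, seed=15, **ZERO_RATES)
        source = generate_source(spec)
        _, reference = derive_target(source, spec)
        seeds = split_seeds(reference, 0.3, seed=1)
        assert len(seeds) == round(0.3 * len(reference))
        assert seeds.pairs() <= reference.pairs()

    def test_write_fixture_dir_round_trips(self, tmp_path):
        from biohan.ontology_io import load_ontology, read_alignment

        spec = FixtureSpec(n_concepts=12, seed=16)
        ledger = write_fixture_dir(spec, tmp_path)
        source = load_ontology(tmp_path / "source.ttl")
        reference = read_alignment(tmp_path / "reference.rdf")
        seeds = read_alignment(tmp_path / "seeds.rdf")
        assert len(source.concepts) >= 12
        assert len(reference) == ledger["n_reference"]
        assert seeds.pairs() <= reference.pairs()
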