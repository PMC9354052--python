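# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting

Given two ontologies O_s = (C_s, R_s, T_s) and O_t = (C_t, R_t, T_t) with
labels and annotations, a set of seed equivalences M⁺ ⊂ C_s × C_t, and a
reference alignment for evaluation, the task is to produce a one-to-one
equivalence alignment. Only `subClassOf`-dominated structure is assumed;
non-hierarchical relations participate in the graph if present but the
method is designed for tree-like terminologies.

## Enrichment rules

All rules are applied jointly to a global fixed point (iteration cap 100;
reaching the cap raises an error naming the run). Except for collection
flattening — which removes exactly the rdf:List/container scaffolding it
consumed — every rule only adds triples; labels are never removed.

- Flattening skips rdf:Lists owned by OWL logical predicates
  (`owl:intersectionOf`, `owl:unionOf`, `owl:oneOf`): those lists are the
  input of the concept-axiom rule, and flattening them first would destroy
  the construct before it is interpreted.
- `owl:equivalentClass` between named classes is materialized as mutual
  `subClassOf` rather than merging nodes, keeping concept identities stable
  for alignment scoring. Equivalence to an intersection (C ≡ A ⊓ B)
  contributes C ⊑ A, C ⊑ B; equivalence to a union contributes A ⊑ C, B ⊑ C.
- Transitive, symmetric and hierarchy rules are closed to a fixed point,
  not applied single-step: closure makes enrichment idempotent and the
  resulting graph independent of rule order.
- Anchoring to an external terminology uses exact normalized-label equality
  (lowercase, punctuation stripped, whitespace collapsed); ambiguity is
  resolved by the number of shared labels, then lexicographic IRI. No fuzzy
  matching: anchors must be high-precision because augmentation copies
  semantics wholesale.

The scaffolding-predicate list is explicit in the code so dialect quirks of
particular ontology distributions can be accommodated without code changes.

## Geometry

All hyperbolic computation uses the Poincaré ball of curvature −1/K with
Möbius addition/matrix products and exponential/logarithmic maps at the
origin. The hyperbolic-GNN literature mixes ball and hyperboloid
vocabulary; one model was standardized on because mixing coordinate charts
mid-layer has no benefit and complicates the algebra. Aggregation takes place in the
tangent space at the origin (the per-node formulation writes log at the
center point; the origin chart keeps attention, aggregation and the decoder
in a single common frame and is the choice made here).

Numerical safety: points are re-projected to norm ≤ (1−10⁻⁵)·√K after every
operation; artanh arguments are clamped to 1−10⁻⁷; norms are smoothed with
ε = 10⁻¹⁵ inside the square root so gradients exist at the origin. With
these clamps the exp/log round trip is exact to 10⁻⁵ for tangent norms ≤ 3,
and at K = 10⁶ the layer operations agree with their Euclidean counterparts
to 10⁻³ relative error (both are tested).

## Encoder

- Input features: character-trigram feature hashing (signed, L2-normalized,
  dimension 512, keyed by a seed through BLAKE2) over the concatenation of
  a concept's labels and annotations. This encoder is deterministic and
  dependency-free; a callable hook accepts any external language model that
  returns fixed-size vectors, which is what a production deployment over
  real biomedical text would use.
- Two layers, 512 → 128 → 128, LeakyReLU slope 0.2 in attention logits,
  ReLU as the tangent-space activation, per-layer trainable curvature
  initialized at K = 1 (parametrized as K = e^κ to stay positive).
- Proximity matrix: B_k rows hold 1/d_i^{(k)} at nodes whose shortest-path
  distance is exactly k (d_i^{(k)} = their count), P = (B₁+B₂)/2; with
  hops = 1 the multi-hop term is absent. Attention logits are
  LeakyReLU(P_ij · aᵀ[Wh_i ‖ Wh_j]) softmaxed over N_i = {j : P_ij > 0};
  the softmax is computed with constant per-row shifts, which is exact.
- The message-passing graph is the symmetrized union of `subClassOf`,
  materialized equivalences, and domain relations between *named, labelled*
  concepts. Anonymous construct nodes (intersection classes, list nodes)
  are excluded: their semantics are already materialized as explicit edges
  by enrichment, and leaving them in systematically distorts the
  neighborhoods of one ontology relative to the other. They are likewise
  never alignment candidates.
- Self-loops are excluded from N_i; the center contributes through the
  W_AGG term of the aggregation.

## Training

L = L_H + α·L_M, α = 1, full-batch Adam, all randomness from one seed.
E⁻ corrupts one side of each edge per epoch (1 per positive); M⁻ corrupts
each seed with 5 replacements per epoch. Resampling negatives each epoch is
a choice; fixing them increases variance on small fixtures.

Two decisions deserve emphasis because the loss p(c_i, c_j) in the
reconstruction term is not pinned down by its usual presentation:

- **p as Fermi-Dirac probability (default).** With p = squared distance the
  positive term is unbounded and its gradient keeps pulling adjacent
  concepts toward coincidence; on 50-node fixtures this collapses siblings
  onto each other and the alignment quality *decreases* with training (held
  out F1 0.46 after 200 epochs vs 0.79 untrained). With
  p = 1 − sim(c_i,c_j) ∈ (0,1) the pull saturates and training improves
  over the untrained encoder. The squared-distance variant remains
  available (`reconstruction_variant="sqdist"`).
- **Learning rate 10⁻⁴** (from the sanctioned set {10⁻², 10⁻³, 10⁻⁴}): the
  larger rates let the structure losses overwrite the lexical signal
  carried by the input features before the seed-contrastive term can anchor
  the two spaces to each other.

Margin μ = 1 and hinge weight ω = 1 (no stated values exist for them);
with the probability-based p, μ = 1 makes the hinge a plain push of
negative pairs toward similarity 0.

The Euclidean ablation ("hyperbolic off") runs the identical architecture
with identity maps instead of exp/log and decodes through squared Euclidean
distance; attention-off replaces α with uniform weights over N_i;
multi-hop-off sets P = B₁.

## Synthetic benchmark

`synthetic_fixtures` generates a rooted subClassOf tree (default 50
concepts, branching ≤ 3, depth ≤ 6, unique two-word pseudoword labels) and
derives a heterogeneous copy:

- **Synonyms** (rate 0.3): the label is replaced by a synonym that keeps the
  head word but reorders and swaps the modifier. Real terminology synonyms
  usually share a stem, and a domain language model recovers relatedness
  even when they do not; since the offline hash encoder has no semantic
  prior, lexical overlap is the generator's stand-in for that
  LM-recoverable relatedness. Fully disjoint renaming is representable too
  (it is what the homonym operator produces) but is not the default
  synonym model.
- **Level collapse/insertion** (rate 0.1, split evenly): an internal node is
  deleted (children re-wired to the grandparent) or a new intermediate node
  is inserted — the granularity mismatch seen between independently built
  hierarchies.
- **Homonyms** (2 collisions): an unrelated concept takes over another's
  label, so lexical matching alone is ambiguous.
- **Axiom hiding** (rate 0.2): a subsumption C ⊑ P is re-expressed as
  C ⊑ (P ⊓ G) through `owl:intersectionOf` with rdf:List scaffolding, where
  G is a dedicated generic concept — the "defined concept" idiom of
  clinical terminologies. Enrichment must recover these edges before the
  encoder can see them (the recovery is exact and is asserted ≥ 95%).

30% of the ground truth serves as training seeds; evaluation excludes the
seeds from both prediction and reference ("held-out"). With all rates zero
the pipeline must recover the identity alignment exactly (asserted F1 = 1.0
for five generator seeds), which pins the deterministic plumbing.

What passing these tests does **not** show: performance on real ontologies
with hundreds of thousands of concepts, DAG (multi-parent) hierarchies,
real lexical variation, or UMLS-derived seed quality. The generator's trees
are clean and its label noise is structural, so absolute F1 values here do
not transfer to benchmark campaigns.

### Scale of the shipped experiments

Tests and the acceptance script train for 200 epochs on 50-concept pairs
(the reference configuration trains 1000 epochs on full ontologies); the
component-ablation comparison uses the full 1000 epochs over five seeds.
These sizes were chosen so the whole suite runs in minutes on one CPU while
keeping every qualitative behavior measurable.

### A negative result, on record

On this fixture family the multi-hop ablation (P = B₁) matches or slightly
*exceeds* the full model (median held-out F1 0.783 vs 0.725 over five seeds
at 1000 epochs), while attention-off ties the full model. In a clean tree
the two-hop neighborhood consists of the grandparent and the siblings, and
siblings are exactly the concepts a matcher must keep apart — blending them
into the aggregation erodes their separability. The benefits reported for
multi-hop aggregation in the matching literature arise on large, lexically
rich, multi-parent ontologies where distant context disambiguates rather
than blurs. The
corresponding acceptance check is left failing deliberately rather than
tuned away; see the test for the exact numbers.

## Known limitations

- No OWL 2 DL reasoning: enrichment is a fixed rule set, not a reasoner;
  negative axioms (disjointness) are ignored.
- One-to-one equivalences only; no subsumption mappings, no m:n.
- Full-batch training bounds practical graph size to a few thousand
  concepts; mini-batching is out of scope.
- The bundled autodiff engine implements exactly the operator set the model
  needs; it is not a general-purpose framework.
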