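"""Joint training of the hyperbolic encoder and alignment evaluation.

The encoder (shared between the two ontologies) is optimized with Adam on
L = L_H + α·L_M, where

* L_H is a margin-based graph reconstruction loss: squared hyperbolic
  distance p(c_i, c_j) summed over adjacent concept pairs E⁺ plus a hinge
  ω·[μ − p]₊ over corrupted pairs E⁻, and
* L_M is a contrastive matching loss over seed correspondences M⁺ and
  corrupted correspondences M⁻ through the Fermi-Dirac similarity:
  −Σ log sim(M⁺) − Σ log(1 − sim(M⁻)).

Negative sets are resampled every epoch; all randomness derives from the
config seed.  Evaluation follows the usual alignment criteria: precision,
recall and their harmonic mean F1, with correspondences identified by their
(source IRI, target IRI) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import manifold
from .errors import ConfigurationError, DivergenceError
from .hyperbolic_encoder import (
    LayerParams,
    PoincareVector,
    adjacency_from_ontology,
    forward_layers,
    init_layer_params,
    proximity_matrix,
)
from .initial_embedding import embed_ontology
from .matching import ScoreTable, SimilarityConfig, score_matrix, stable_marriage
from .model import Alignment, Ontology

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyper-parameters of the joint training run.

    Defaults follow the reference configuration: 1000 epochs, two attention
    layers mapping 512 → 128 → 128, trade-off α = 1, five negatives per seed
    correspondence, Fermi-Dirac r = 2, t = 1.  The learning rate defaults to
    1e-4, the smallest of the sanctioned choices {1e-2, 1e-3, 1e-4}: on
    fixture-scale graphs the larger rates let the structure losses overwrite
    the lexical signal carried by the input features.
    """

    epochs: int = 1000
    learning_rate: float = 0.0001
    dim: int = 128
    input_dim: int = 512
    num_layers: int = 2
    margin_mu: float = 1.0
    tradeoff_omega: float = 1.0
    alpha: float = 1.0
    negatives_per_seed: int = 5
    negatives_per_edge: int = 1
    seed: int = 0
    # ablation switches
    geometry: str = "hyperbolic"  # "euclidean" disables the ball geometry
    attention: bool = True  # False → uniform neighbor weights
    hops: int = 2  # 1 → no multi-hop aggregation
    curvature_trainable: bool = True
    reconstruction_variant: str = "fermi_dirac"  # or "sqdist"
    sim: SimilarityConfig = field(default_factory=SimilarityConfig)
    log_every: int = 0  # 0 disables per-epoch logging

    def __post_init__(self) -> None:
        for name in ("epochs", "learning_rate", "dim", "input_dim", "num_layers",
                     "margin_mu", "tradeoff_omega"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be nonnegative")
        if self.negatives_per_seed < 1:
            raise ConfigurationError("negatives_per_seed must be >= 1")
        if self.hops not in (1, 2):
            raise ConfigurationError("hops must be 1 or 2")
        if self.geometry not in ("hyperbolic", "euclidean"):
            raise ConfigurationError(f"unknown geometry {self.geometry!r}")


@dataclass
class SampleSets:
    """Positive/negative pair sets for one loss evaluation."""

    edge_positives: set[tuple[str, str]] = field(default_factory=set)
    edge_negatives: set[tuple[str, str]] = field(default_factory=set)
    seed_positives: set[tuple[str, str]] = field(default_factory=set)
    seed_negatives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.edge_positives & self.edge_negatives:
            raise ConfigurationError("edge positives and negatives overlap")
        if self.seed_positives & self.seed_negatives:
            raise ConfigurationError("seed positives and negatives overlap")


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------


def sample_negatives(
    positives: set[tuple[str, str]],
    candidate_pool: set[str],
    k: int,
    rng_seed: int,
    pool_left: set[str] | None = None,
    pool_right: set[str] | None = None,
) -> set[tuple[str, str]]:
    """For each positive pair, k corrupted pairs replacing one side at random.

    The corrupted side is chosen by fair coin; replacements are drawn
    uniformly from the pool for that side, rejecting collisions with any
    positive.  Fully determined by ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    return _sample_negatives_rng(positives, candidate_pool, k, rng, pool_left, pool_right)


def _sample_negatives_rng(
    positives, candidate_pool, k, rng, pool_left=None, pool_right=None
) -> set[tuple[str, str]]:
    left = sorted(pool_left if pool_left is not None else candidate_pool)
    right = sorted(pool_right if pool_right is not None else candidate_pool)
    if min(len(left), len(right)) <= k:
        raise ConfigurationError(
            f"candidate pool of size {min(len(left), len(right))} too small for k={k}"
        )
    positive_set = set(positives)
    negatives: set[tuple[str, str]] = set()
    for a, b in sorted(positives):
        for _ in range(k):
            for _attempt in range(100):
                if rng.random() < 0.5:
                    cand = (left[rng.integers(len(left))], b)
                else:
                    cand = (a, right[rng.integers(len(right))])
                if cand not in positive_set and cand not in negatives and cand != (a, b):
                    negatives.add(cand)
                    break
            else:
                raise ConfigurationError(
                    "candidate pool too small to avoid collisions with positives"
                )
    return negatives


# ---------------------------------------------------------------------------
# losses (array core + PoincareVector surface)
# ---------------------------------------------------------------------------


def _pair_sqdist(x, y, curvature_k, geometry: str):
    if geometry == "euclidean":
        diff = x - y
        return ad.sum(diff * diff, axis=-1, keepdims=False)
    return manifold.squared_distance(x, y, curvature_k)


def _reconstruction_core(pos_x, pos_y, neg_x, neg_y, curvature_k, mu, omega,
                         geometry="hyperbolic", variant="sqdist", sim=None):
    def p(x, y):
        sq = _pair_sqdist(x, y, curvature_k, geometry)
        if variant == "fermi_dirac":
            sim_cfg = sim or SimilarityConfig()
            return 1.0 - 1.0 / (ad.exp((sq - sim_cfg.r) / sim_cfg.t) + 1.0)
        return sq

    total = 0.0
    if pos_x is not None:
        total = total + ad.sum(p(pos_x, pos_y))
    if neg_x is not None:
        total = total + omega * ad.sum(ad.relu(mu - p(neg_x, neg_y)))
    return total


def reconstruction_loss(
    vectors: dict[str, PoincareVector],
    samples: SampleSets,
    config: TrainingConfig,
) -> float:
    """L_H over the sampled adjacency pairs: Σ p(E⁺) + ω·Σ [μ − p(E⁻)]₊."""
    def gather(pairs):
        if not pairs:
            return None, None
        try:
            xs = np.stack([vectors[a].coords for a, _ in sorted(pairs)])
            ys = np.stack([vectors[b].coords for _, b in sorted(pairs)])
        except KeyError as exc:
            raise ConfigurationError(f"missing vector for concept {exc}") from exc
        return xs, ys

    k = next(iter(vectors.values())).curvature_k if vectors else 1.0
    pos_x, pos_y = gather(samples.edge_positives)
    neg_x, neg_y = gather(samples.edge_negatives)
    value = _reconstruction_core(
        pos_x, pos_y, neg_x, neg_y, k, config.margin_mu, config.tradeoff_omega,
        geometry=config.geometry, variant=config.reconstruction_variant, sim=config.sim,
    )
    return float(ad.data_of(value)) if not isinstance(value, float) else value


def _matching_core(pos_sq, neg_sq, sim_config: SimilarityConfig):
    total = 0.0
    if pos_sq is not None:
        sim = 1.0 / (ad.exp((pos_sq - sim_config.r) / sim_config.t) + 1.0)
        total = total + (-1.0) * ad.sum(ad.log(sim))
    if neg_sq is not None:
        sim = 1.0 / (ad.exp((neg_sq - sim_config.r) / sim_config.t) + 1.0)
        total = total + (-1.0) * ad.sum(ad.log(1.0 - sim))
    return total


def matching_loss(
    source_vectors: dict[str, PoincareVector],
    target_vectors: dict[str, PoincareVector],
    seeds: SampleSets,
    sim_config: SimilarityConfig | None = None,
    geometry: str = "hyperbolic",
) -> float:
    """L_M = −Σ_{M⁺} log sim − Σ_{M⁻} log(1 − sim); finite since sim ∈ (0,1)."""
    sim_config = sim_config or SimilarityConfig()
    all_vecs = {**source_vectors, **target_vectors}
    k = next(iter(all_vecs.values())).curvature_k if all_vecs else 1.0

    def sq(pairs):
        if not pairs:
            return None
        try:
            xs = np.stack([source_vectors[a].coords for a, _ in sorted(pairs)])
            ys = np.stack([target_vectors[b].coords for _, b in sorted(pairs)])
        except KeyError as exc:
            raise ConfigurationError(f"missing vector for concept {exc}") from exc
        return _pair_sqdist(xs, ys, k, geometry)

    value = _matching_core(sq(seeds.seed_positives), sq(seeds.seed_negatives), sim_config)
    return float(ad.data_of(value)) if not isinstance(value, float) else value


def total_loss(lh: float, lm: float, alpha: float) -> float:
    """L = L_H + α·L_M."""
    return lh + alpha * lm


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def evaluate(predicted: Alignment, reference: Alignment) -> tuple[float, float, float]:
    """OAEI-style precision, recall and F1 on (source, target) identities."""
    map_pairs = predicted.pairs()
    ref_pairs = reference.pairs()
    hits = len(map_pairs & ref_pairs)
    p = hits / len(map_pairs) if map_pairs else 0.0
    r = hits / len(ref_pairs) if ref_pairs else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def evaluate_heldout(
    predicted: Alignment, reference: Alignment, seeds: Alignment
) -> tuple[float, float, float]:
    """P/R/F1 after removing the training seeds from both sides."""
    seed_pairs = seeds.pairs()
    pred = Alignment(
        correspondences={c for c in predicted.correspondences if c.pair() not in seed_pairs}
    )
    ref = Alignment(
        correspondences={c for c in reference.correspondences if c.pair() not in seed_pairs}
    )
    return evaluate(pred, ref)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    """Outputs of one training run."""

    source_vectors: dict[str, PoincareVector]
    target_vectors: dict[str, PoincareVector]
    alignment: Alignment
    losses: list[tuple[float, float, float]]  # (total, L_H, L_M) per epoch
    layers: list[LayerParams]
    scores: ScoreTable


class _TrainableLayer:
    """Tensor-valued view of one layer's parameters."""

    def __init__(self, params: LayerParams, trainable_curvature: bool) -> None:
        self.weight = ad.parameter(params.weight)
        self.bias = ad.parameter(params.bias)
        self.attention_vec = ad.parameter(params.attention_vec)
        self.aggregation_weight = ad.parameter(params.aggregation_weight)
        self.log_k_in = ad.parameter(np.log(params.curvature_in))
        self.log_k_out = ad.parameter(np.log(params.curvature_out))
        self.trainable_curvature = trainable_curvature

    def tensors(self) -> list[ad.Tensor]:
        base = [self.weight, self.bias, self.attention_vec, self.aggregation_weight]
        if self.trainable_curvature:
            base += [self.log_k_in, self.log_k_out]
        return base

    def k_in(self):
        return ad.exp(self.log_k_in) if self.trainable_curvature else float(np.exp(self.log_k_in.data))

    def k_out(self):
        return ad.exp(self.log_k_out) if self.trainable_curvature else float(np.exp(self.log_k_out.data))

    def frozen(self) -> LayerParams:
        return LayerParams(
            weight=self.weight.data.copy(),
            bias=self.bias.data.copy(),
            attention_vec=self.attention_vec.data.copy(),
            aggregation_weight=self.aggregation_weight.data.copy(),
            curvature_in=float(np.exp(self.log_k_in.data)),
            curvature_out=float(np.exp(self.log_k_out.data)),
            trainable_curvature=self.trainable_curvature,
        )


def _edge_index_pairs(ontology: Ontology, nodes: list[str]) -> list[tuple[int, int]]:
    index = {n: i for i, n in enumerate(nodes)}
    pairs = set()
    for child, parent in ontology.subclass_edges():
        i, j = index.get(child), index.get(parent)
        if i is not None and j is not None and i != j:
            pairs.add((i, j))
    return sorted(pairs)


def train(
    source: Ontology,
    target: Ontology,
    seeds: Alignment,
    config: TrainingConfig | None = None,
) -> TrainResult:
    """Full-batch joint training, followed by stable-marriage matching.

    The encoder weights are shared between the two ontologies so that seed
    supervision in one region of the space shapes both sides.  Raises
    :class:`DivergenceError` on a non-finite loss.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)

    # The training graph covers named, labelled concepts; anonymous axiom
    # scaffolding (intersection classes, list nodes) is excluded from message
    # passing — its semantics were materialized as explicit edges during
    # enrichment.
    src_nodes = sorted(c for c in source.concepts if source.labels.get(c)) or sorted(source.concepts)
    tgt_nodes = sorted(c for c in target.concepts if target.labels.get(c)) or sorted(target.concepts)
    for corr in seeds.correspondences:
        if corr.source not in source.concepts or corr.target not in target.concepts:
            raise ConfigurationError(
                f"seed references unknown concepts: {corr.source} / {corr.target}"
            )

    src_prox = proximity_matrix(
        adjacency_from_ontology(source, src_nodes), hops=config.hops, nodes=src_nodes
    )
    tgt_prox = proximity_matrix(
        adjacency_from_ontology(target, tgt_nodes), hops=config.hops, nodes=tgt_nodes
    )
    src_X = embed_ontology(source, dimension=config.input_dim, seed=config.seed).matrix(src_nodes)
    tgt_X = embed_ontology(target, dimension=config.input_dim, seed=config.seed).matrix(tgt_nodes)

    dims = [config.input_dim] + [config.dim] * config.num_layers
    layers = [
        _TrainableLayer(
            init_layer_params(dims[i], dims[i + 1], rng),
            config.curvature_trainable and config.geometry == "hyperbolic",
        )
        for i in range(config.num_layers)
    ]
    params: list[ad.Tensor] = [t for layer in layers for t in layer.tensors()]
    optimizer = ad.Adam(params, lr=config.learning_rate)

    src_edges = _edge_index_pairs(source, src_nodes)
    tgt_edges = _edge_index_pairs(target, tgt_nodes)
    src_index = {n: i for i, n in enumerate(src_nodes)}
    tgt_index = {n: i for i, n in enumerate(tgt_nodes)}
    seed_pairs = sorted((src_index[c.source], tgt_index[c.target]) for c in seeds.correspondences)

    def forward(X, prox):
        return forward_layers(
            X,
            layers,
            prox.weights,
            curvatures_in=[l.k_in() for l in layers],
            curvatures_out=[l.k_out() for l in layers],
            geometry=config.geometry,
            attention=config.attention,
        )

    def pair_loss_sq(out_a, out_b, pairs, k):
        ia = np.array([p[0] for p in pairs], dtype=int)
        ib = np.array([p[1] for p in pairs], dtype=int)
        return _pair_sqdist(out_a[ia], out_b[ib], k, config.geometry)

    losses: list[tuple[float, float, float]] = []
    n_src, n_tgt = len(src_nodes), len(tgt_nodes)
    for epoch in range(config.epochs):
        optimizer.zero_grad()
        out_s = forward(src_X, src_prox)
        out_t = forward(tgt_X, tgt_prox)
        k_final = layers[-1].k_out() if config.geometry == "hyperbolic" else 1.0

        lh = 0.0
        for out, edges, n in ((out_s, src_edges, n_src), (out_t, tgt_edges, n_tgt)):
            if not edges:
                continue
            neg = _corrupt_index_pairs(edges, n, n, config.negatives_per_edge, rng)
            pos_sq = pair_loss_sq(out, out, edges, k_final)
            neg_sq = pair_loss_sq(out, out, neg, k_final)
            if config.reconstruction_variant == "fermi_dirac":
                pos_sq = 1.0 - 1.0 / (ad.exp((pos_sq - config.sim.r) / config.sim.t) + 1.0)
                neg_sq = 1.0 - 1.0 / (ad.exp((neg_sq - config.sim.r) / config.sim.t) + 1.0)
            lh = lh + ad.sum(pos_sq) + config.tradeoff_omega * ad.sum(
                ad.relu(config.margin_mu - neg_sq)
            )

        lm = 0.0
        if seed_pairs and config.alpha > 0:
            neg_pairs = _corrupt_index_pairs(
                seed_pairs, n_src, n_tgt, config.negatives_per_seed, rng
            )
            pos_sq = pair_loss_sq(out_s, out_t, seed_pairs, k_final)
            neg_sq = pair_loss_sq(out_s, out_t, neg_pairs, k_final)
            lm = _matching_core(pos_sq, neg_sq, config.sim)

        total = lh + config.alpha * lm
        lh_value = float(ad.data_of(lh)) if not isinstance(lh, float) else lh
        lm_value = float(ad.data_of(lm)) if not isinstance(lm, float) else lm
        total_value = float(ad.data_of(total)) if not isinstance(total, float) else total
        if not np.isfinite(total_value):
            raise DivergenceError(f"non-finite loss {total_value} at epoch {epoch}")
        losses.append((total_value, lh_value, lm_value))
        if isinstance(total, ad.Tensor):
            total.backward()
            optimizer.step()
        if config.log_every and epoch % config.log_every == 0:
            logger.info("epoch %d: loss=%.4f (L_H=%.4f, L_M=%.4f)", epoch, total_value, lh_value, lm_value)

    frozen = [layer.frozen() for layer in layers]
    out_s = ad.data_of(forward(src_X, src_prox))
    out_t = ad.data_of(forward(tgt_X, tgt_prox))
    if config.geometry == "euclidean":
        # Euclidean ablation: outputs are plain vectors, decoded through the
        # same Fermi-Dirac similarity on squared Euclidean distance.
        from .matching import similarity_from_sqdist

        src_vectors = {n: out_s[i] for i, n in enumerate(src_nodes)}
        tgt_vectors = {n: out_t[i] for i, n in enumerate(tgt_nodes)}
        sq = ((out_s[:, None, :] - out_t[None, :, :]) ** 2).sum(axis=-1)
        scores = ScoreTable(src_nodes, tgt_nodes, similarity_from_sqdist(sq, config.sim))
    else:
        k_final = frozen[-1].curvature_out
        src_vectors = {n: PoincareVector(out_s[i], k_final) for i, n in enumerate(src_nodes)}
        tgt_vectors = {n: PoincareVector(out_t[i], k_final) for i, n in enumerate(tgt_nodes)}
        scores = score_matrix(src_vectors, tgt_vectors, config.sim)
    alignment = stable_marriage(scores, config.sim.min_similarity)
    return TrainResult(
        source_vectors=src_vectors,
        target_vectors=tgt_vectors,
        alignment=alignment,
        losses=losses,
        layers=frozen,
        scores=scores,
    )


def _corrupt_index_pairs(pairs, n_left, n_right, k, rng) -> list[tuple[int, int]]:
    """k corrupted index pairs per positive, avoiding the positive set."""
    positive = set(pairs)
    out: list[tuple[int, int]] = []
    for a, b in pairs:
        for _ in range(k):
            for _attempt in range(50):
                if rng.random() < 0.5:
                    cand = (int(rng.integers(n_left)), b)
                else:
                    cand = (a, int(rng.integers(n_right)))
                if cand not in positive:
                    out.append(cand)
                    break
    return out
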