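"""Hyperbolic graph attention encoding of ontology concepts.

Each layer (i) transforms points by a Möbius linear map W ⊗ x ⊕ b, (ii)
computes attention coefficients over one- and two-hop neighbors, weighted by
a hop-blended proximity matrix P = (B₁ + B₂)/2, (iii) aggregates neighbor
tangent vectors together with a self term W_AGG·log₀(x), and (iv) applies a
Euclidean nonlinearity in the tangent space while switching to the next
layer's curvature.  Stacking two such layers embeds the (tree-like) concept
graph in a Poincaré ball where geodesic distance reflects hierarchy.

All aggregation happens in the tangent space at the origin.  Attention logits
follow the GAT recipe on the linearly transformed tangent states:
α_ij = softmax_j LeakyReLU(P_ij · aᵀ[W h_i ‖ W h_j]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import manifold
from .errors import ConfigurationError, NumericError
from .initial_embedding import EmbeddingTable
from .model import (
    OWL_EQUIVALENT_CLASS,
    RDFS_SUBCLASSOF,
    Ontology,
)

LEAKY_RELU_SLOPE = 0.2  # standard GAT value


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoincareVector:
    """A point inside the ball of curvature −1/K."""

    coords: np.ndarray
    curvature_k: float = 1.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if not np.all(np.isfinite(coords)):
            raise NumericError("PoincareVector with non-finite coordinates")
        if np.linalg.norm(coords) / math.sqrt(self.curvature_k) >= 1.0:
            raise NumericError("point on or outside the ball boundary")


@dataclass
class LayerParams:
    """Parameters of one hyperbolic graph attention layer."""

    weight: np.ndarray  # (d_out, d_in)
    bias: np.ndarray  # (d_out,)
    attention_vec: np.ndarray  # (2*d_out,)
    aggregation_weight: np.ndarray  # (d_out, d_out)
    curvature_in: float = 1.0
    curvature_out: float = 1.0
    trainable_curvature: bool = True

    def __post_init__(self) -> None:
        d_out = self.weight.shape[0]
        if self.curvature_in <= 0 or self.curvature_out <= 0:
            raise ConfigurationError("curvatures must be positive")
        if self.attention_vec.shape != (2 * d_out,):
            raise ConfigurationError(
                f"attention vector length {self.attention_vec.shape} != 2*{d_out}"
            )
        if self.bias.shape != (d_out,):
            raise ConfigurationError("bias dimension mismatch")
        if self.aggregation_weight.shape != (d_out, d_out):
            raise ConfigurationError("aggregation weight must be (d_out, d_out)")


def init_layer_params(
    d_in: int,
    d_out: int,
    rng: np.random.Generator,
    curvature_in: float = 1.0,
    curvature_out: float = 1.0,
) -> LayerParams:
    """Glorot-style initialization of one layer."""
    scale = math.sqrt(2.0 / (d_in + d_out))
    return LayerParams(
        weight=rng.normal(0.0, scale, size=(d_out, d_in)),
        bias=np.zeros(d_out),
        attention_vec=rng.normal(0.0, scale, size=2 * d_out),
        aggregation_weight=np.eye(d_out) + rng.normal(0.0, 0.01, size=(d_out, d_out)),
        curvature_in=curvature_in,
        curvature_out=curvature_out,
    )


@dataclass
class ProximityMatrix:
    """Hop-blended topological weights P = (Σ_k B_k)/hops over ordered nodes.

    Each B_k row holds 1/d_i^{(k)} at the columns of nodes whose shortest-path
    distance from i is exactly k, where d_i^{(k)} counts those nodes.
    """

    weights: np.ndarray
    nodes: list[str] = field(default_factory=list)
    hops: int = 2
    per_hop: list[np.ndarray] = field(default_factory=list)

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def entry(self, i, j) -> float:
        idx = self.index()
        return float(self.weights[idx[i], idx[j]])


def proximity_matrix(
    adjacency: np.ndarray, hops: int = 2, nodes: list[str] | None = None
) -> ProximityMatrix:
    """Build P from a symmetric 0/1 adjacency matrix without self-loops."""
    A = np.asarray(adjacency, dtype=bool)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ConfigurationError("adjacency must be square")
    if np.any(np.diag(A)):
        raise ConfigurationError("adjacency must not contain self-loops")
    A = A | A.T
    eye = np.eye(n, dtype=bool)
    reach = A.copy()  # nodes within distance <= k
    exact = A.copy()  # distance exactly k
    per_hop: list[np.ndarray] = []
    for _ in range(hops):
        deg = exact.sum(axis=1).astype(float)
        B = np.zeros((n, n))
        rows = deg > 0
        B[rows] = exact[rows] / deg[rows, None]
        per_hop.append(B)
        nxt = (exact.astype(int) @ A.astype(int)) > 0
        exact = nxt & ~reach & ~eye
        reach = reach | exact
    P = np.sum(per_hop, axis=0) / hops
    return ProximityMatrix(
        weights=P, nodes=list(nodes) if nodes else [str(i) for i in range(n)],
        hops=hops, per_hop=per_hop,
    )


def adjacency_from_ontology(ontology: Ontology, nodes: list[str]) -> np.ndarray:
    """Symmetrized concept graph: subClassOf plus domain relations and
    materialized equivalences between concepts."""
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    edge_preds = {RDFS_SUBCLASSOF, OWL_EQUIVALENT_CLASS} | ontology.relations
    for t in ontology.triples:
        if t.predicate not in edge_preds or not isinstance(t.object, str):
            continue
        i, j = index.get(t.subject), index.get(t.object)
        if i is None or j is None or i == j:
            continue
        A[i, j] = A[j, i] = True
    return A


# ---------------------------------------------------------------------------
# per-node operations (NumPy surface)
# ---------------------------------------------------------------------------


def exp_map_origin(v: np.ndarray, curvature_k: float = 1.0) -> PoincareVector:
    """Lift a tangent vector at the origin onto the ball."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise NumericError("non-finite tangent vector")
    return PoincareVector(manifold.expmap0(v, curvature_k), curvature_k)


def log_map_origin(x: PoincareVector) -> np.ndarray:
    """Project a ball point back to the tangent space at the origin."""
    return manifold.logmap0(x.coords, x.curvature_k)


def hyperbolic_linear(x: PoincareVector, params: LayerParams) -> PoincareVector:
    """Möbius linear map (W ⊗ x) ⊕ exp₀(b) at the layer's input curvature."""
    if params.weight.shape[1] != x.coords.shape[-1]:
        raise ConfigurationError(
            f"weight expects dim {params.weight.shape[1]}, point has {x.coords.shape[-1]}"
        )
    k = params.curvature_in
    wx = manifold.mobius_matvec(params.weight, x.coords, k)
    out = manifold.mobius_add(wx, manifold.expmap0(params.bias, k), k)
    return PoincareVector(out, k)


def attention_weights(
    tangent_states: dict[str, np.ndarray],
    params: LayerParams,
    proximity: ProximityMatrix,
    neighborhood: dict[str, set[str]],
) -> dict[tuple[str, str], float]:
    """GAT-style attention over each node's (multi-hop) neighborhood.

    Logits are LeakyReLU(P_ij · aᵀ[W h_i ‖ W h_j]) on the supplied tangent
    states; the softmax normalizes over j ∈ N_i, so each non-empty row sums
    to one.  Nodes with empty neighborhoods contribute no entries.
    """
    d_out = params.weight.shape[0]
    a1, a2 = params.attention_vec[:d_out], params.attention_vec[d_out:]
    transformed = {n: params.weight @ v for n, v in tangent_states.items()}
    index = proximity.index()
    alphas: dict[tuple[str, str], float] = {}
    for i, nbrs in neighborhood.items():
        if not nbrs:
            continue
        js = sorted(nbrs)
        logits = []
        for j in js:
            raw = float(a1 @ transformed[i] + a2 @ transformed[j])
            pij = float(proximity.weights[index[i], index[j]])
            z = pij * raw
            logits.append(z if z > 0 else LEAKY_RELU_SLOPE * z)
        logits = np.asarray(logits)
        e = np.exp(logits - logits.max())
        soft = e / e.sum()
        for j, a in zip(js, soft):
            alphas[(i, j)] = float(a)
    return alphas


def aggregate(
    center: PoincareVector,
    neighbor_states: dict[str, PoincareVector],
    alphas: dict[str, float],
    params: LayerParams,
) -> PoincareVector:
    """Attention-based aggregation in the origin tangent space.

    exp₀( W_AGG·log₀(center) + Σ_j α_j·log₀(neighbor_j) ); with no neighbors
    this reduces to the self term alone.
    """
    k = center.curvature_k
    tangent = params.aggregation_weight @ manifold.logmap0(center.coords, k)
    for node, alpha in alphas.items():
        tangent = tangent + alpha * manifold.logmap0(neighbor_states[node].coords, k)
    return PoincareVector(manifold.expmap0(tangent, k), k)


def hyperbolic_activation(
    x: PoincareVector,
    curvature_in: float,
    curvature_out: float,
    activation: str = "relu",
) -> PoincareVector:
    """σ in the tangent space, mapping curvature −1/K_in to −1/K_out."""
    t = manifold.logmap0(x.coords, curvature_in)
    if activation == "relu":
        t = np.maximum(t, 0.0)
    elif activation == "leaky_relu":
        t = np.where(t > 0, t, LEAKY_RELU_SLOPE * t)
    else:
        raise ConfigurationError(f"unknown activation {activation!r}")
    return PoincareVector(manifold.expmap0(t, curvature_out), curvature_out)


def hyperbolic_distance(x: PoincareVector, y: PoincareVector) -> float:
    """Geodesic distance; requires equal curvature."""
    if x.curvature_k != y.curvature_k:
        raise ConfigurationError("curvature mismatch between points")
    return float(manifold.distance(x.coords, y.coords, x.curvature_k))


# ---------------------------------------------------------------------------
# vectorized forward pass (shared by encode_ontology and training)
# ---------------------------------------------------------------------------


def masked_softmax_rows(logits, mask: np.ndarray):
    """Row softmax restricted to ``mask``; all-zero rows for empty masks.

    Row maxima are subtracted as constants for stability (softmax is
    invariant to per-row shifts, so this is exact, also for gradients).
    """
    data = ad.data_of(logits)
    shifted_max = np.where(mask, data, -np.inf).max(axis=1, keepdims=True)
    shifted_max = np.where(np.isfinite(shifted_max), shifted_max, 0.0)
    e = ad.exp(logits - shifted_max) * mask.astype(float)
    has_nb = mask.any(axis=1, keepdims=True)
    denom = ad.sum(e, axis=1, keepdims=True) + (~has_nb).astype(float)
    return e / denom


def layer_forward(
    h,
    layer,
    proximity_weights: np.ndarray,
    *,
    k_in,
    k_out,
    geometry: str = "hyperbolic",
    attention: bool = True,
    activation: str = "relu",
):
    """One layer on an (n, d_in) batch of points; returns (n, d_out) points.

    ``layer`` exposes ``weight``/``bias``/``attention_vec``/
    ``aggregation_weight`` as arrays or autodiff Tensors.
    """
    hyper = geometry == "hyperbolic"
    P = np.asarray(proximity_weights)
    mask = P > 0

    t_prev = manifold.logmap0(h, k_in) if hyper else h
    m = ad.matmul(t_prev, _t(layer.weight))
    if hyper:
        proj = manifold.mobius_add(
            manifold.expmap0(m, k_in), manifold.expmap0(layer.bias, k_in), k_in
        )
        u = manifold.logmap0(proj, k_in)
    else:
        u = m + layer.bias

    if attention:
        d_out = ad.data_of(layer.weight).shape[0]
        a1 = layer.attention_vec[:d_out]
        a2 = layer.attention_vec[d_out:]
        s = ad.matmul(m, _col(a1))  # (n, 1)
        r = ad.matmul(m, _col(a2)).T  # (1, n)
        logits = ad.leaky_relu(P * (s + r), LEAKY_RELU_SLOPE)
        alpha = masked_softmax_rows(logits, mask)
    else:  # uniform weights over the neighborhood (attention ablation)
        counts = mask.sum(axis=1, keepdims=True)
        alpha = mask / np.maximum(counts, 1)

    agg = ad.matmul(u, _t(layer.aggregation_weight)) + ad.matmul(alpha, u)
    if hyper:
        point = manifold.expmap0(agg, k_in)
        tangent = manifold.logmap0(point, k_in)
    else:
        tangent = agg
    act = ad.relu(tangent) if activation == "relu" else ad.leaky_relu(tangent, LEAKY_RELU_SLOPE)
    return manifold.expmap0(act, k_out) if hyper else act


def _t(w):
    return w.T if isinstance(w, ad.Tensor) else ad.data_of(w).T


def _col(x):
    return x.reshape(-1, 1) if isinstance(x, ad.Tensor) else np.asarray(x).reshape(-1, 1)


def _row(x):
    return x.reshape(1, -1) if isinstance(x, ad.Tensor) else np.asarray(x).reshape(1, -1)


def forward_layers(
    X,
    layers,
    proximity_weights: np.ndarray,
    *,
    curvatures_in=None,
    curvatures_out=None,
    geometry: str = "hyperbolic",
    attention: bool = True,
    activation: str = "relu",
):
    """Lift (n, d₀) Euclidean inputs and run all layers; returns (n, d_L)."""
    k_ins = curvatures_in or [layer.curvature_in for layer in layers]
    k_outs = curvatures_out or [layer.curvature_out for layer in layers]
    h = manifold.expmap0(X, k_ins[0]) if geometry == "hyperbolic" else X
    for layer, k_in, k_out in zip(layers, k_ins, k_outs):
        h = layer_forward(
            h,
            layer,
            proximity_weights,
            k_in=k_in,
            k_out=k_out,
            geometry=geometry,
            attention=attention,
            activation=activation,
        )
    return h


def encode_ontology(
    embeddings: EmbeddingTable,
    ontology: Ontology,
    layers: list[LayerParams],
    proximity: ProximityMatrix,
    *,
    geometry: str = "hyperbolic",
    attention: bool = True,
) -> dict[str, PoincareVector]:
    """Encode every concept of an ontology into the final hyperbolic space."""
    if not layers:
        raise ConfigurationError("at least one layer is required")
    d = embeddings.dimension
    for layer in layers:
        if layer.weight.shape[1] != d:
            raise ConfigurationError(
                f"layer expects input dim {layer.weight.shape[1]}, got {d}"
            )
        d = layer.weight.shape[0]
    nodes = proximity.nodes
    X = embeddings.matrix(nodes)
    out = forward_layers(
        X, layers, proximity.weights, geometry=geometry, attention=attention
    )
    k_final = layers[-1].curvature_out
    return {
        node: PoincareVector(np.asarray(ad.data_of(out))[i], k_final)
        for i, node in enumerate(nodes)
    }
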