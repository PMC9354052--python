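"""Similarity decoding and one-to-one alignment extraction.

Concept pairs are scored with a Fermi-Dirac decoder on squared hyperbolic
distance, sim = 1 / (exp((d² − r)/t) + 1), which maps distance 0 near 1 and
is exactly 0.5 where d² = r.  A one-to-one equivalence alignment is then
extracted with the Gale–Shapley stable-marriage algorithm over the pairwise
similarities, source concepts proposing; ties are broken by IRI order so the
result is reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import manifold
from .errors import ConfigurationError
from .hyperbolic_encoder import PoincareVector
from .model import Alignment, Correspondence, Relation

logger = logging.getLogger(__name__)


@dataclass
class SimilarityConfig:
    """Fermi-Dirac decoder hyper-parameters (defaults r=2.0, t=1.0)."""

    r: float = 2.0
    t: float = 1.0
    min_similarity: float = 0.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ConfigurationError("temperature t must be positive")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ConfigurationError("min_similarity must be in [0, 1]")


def similarity_from_sqdist(sq_dist, config: SimilarityConfig):
    """sim = 1 / (exp((d² − r)/t) + 1); works elementwise on arrays."""
    return 1.0 / (np.exp((sq_dist - config.r) / config.t) + 1.0)


def similarity(x: PoincareVector, y: PoincareVector, config: SimilarityConfig | None = None) -> float:
    """Fermi-Dirac similarity of two points; strictly decreasing in distance."""
    config = config or SimilarityConfig()
    if x.curvature_k != y.curvature_k:
        raise ConfigurationError("curvature mismatch between points")
    d = float(manifold.distance(x.coords, y.coords, x.curvature_k))
    return float(similarity_from_sqdist(d * d, config))


@dataclass
class ScoreTable:
    """All |C_s|×|C_t| similarities with deterministic sorted-IRI order."""

    sources: list[str]
    targets: list[str]
    scores: np.ndarray  # (|sources|, |targets|)

    def entry(self, source: str, target: str) -> float:
        return float(self.scores[self.sources.index(source), self.targets.index(target)])


def score_matrix(
    source_vectors: dict[str, PoincareVector],
    target_vectors: dict[str, PoincareVector],
    config: SimilarityConfig | None = None,
) -> ScoreTable:
    """Pairwise Fermi-Dirac similarities between two embedded concept sets."""
    config = config or SimilarityConfig()
    sources = sorted(source_vectors)
    targets = sorted(target_vectors)
    if not sources or not targets:
        logger.warning("score_matrix over an empty concept set")
        return ScoreTable(sources, targets, np.zeros((len(sources), len(targets))))
    k = next(iter(source_vectors.values())).curvature_k
    for v in list(source_vectors.values()) + list(target_vectors.values()):
        if v.curvature_k != k:
            raise ConfigurationError("all vectors must share one curvature")
    Y = np.stack([target_vectors[t].coords for t in targets])
    scores = np.zeros((len(sources), len(targets)))
    for i, s in enumerate(sources):
        d = manifold.distance(source_vectors[s].coords, Y, k)
        scores[i] = similarity_from_sqdist(np.asarray(d) ** 2, config)
    return ScoreTable(sources, targets, scores)


def stable_marriage(
    scores: ScoreTable,
    min_similarity: float = 0.0,
    source_ontology: str = "",
    target_ontology: str = "",
) -> Alignment:
    """Gale–Shapley with source concepts proposing.

    Preference order is descending similarity with ties broken by the other
    side's IRI; the result is one-to-one and stable.  Pairs scoring below
    ``min_similarity`` are removed after matching.
    """
    if not np.all(np.isfinite(scores.scores)):
        raise ConfigurationError("similarity scores must be finite")
    n_s, n_t = len(scores.sources), len(scores.targets)
    alignment = Alignment(
        source_ontology=source_ontology, target_ontology=target_ontology
    )
    if n_s == 0 or n_t == 0:
        return alignment

    # preference lists: column indices sorted by (-similarity, target IRI)
    pref: list[list[int]] = []
    for i in range(n_s):
        order = sorted(range(n_t), key=lambda j: (-scores.scores[i, j], scores.targets[j]))
        pref.append(order)

    def target_prefers(j: int, new_i: int, cur_i: int) -> bool:
        a, b = scores.scores[new_i, j], scores.scores[cur_i, j]
        if a != b:
            return a > b
        return scores.sources[new_i] < scores.sources[cur_i]

    next_choice = [0] * n_s
    engaged_t: dict[int, int] = {}  # target index -> source index
    free = list(range(n_s - 1, -1, -1))
    while free:
        i = free.pop()
        if next_choice[i] >= n_t:
            continue  # exhausted all targets; stays unmatched
        j = pref[i][next_choice[i]]
        next_choice[i] += 1
        if j not in engaged_t:
            engaged_t[j] = i
        elif target_prefers(j, i, engaged_t[j]):
            free.append(engaged_t[j])
            engaged_t[j] = i
        else:
            free.append(i)

    for j, i in engaged_t.items():
        s = float(scores.scores[i, j])
        if s < min_similarity:
            continue
        alignment.correspondences.add(
            Correspondence(
                source=scores.sources[i],
                target=scores.targets[j],
                relation=Relation.EQUIVALENCE,
                score=min(max(s, 0.0), 1.0),
            )
        )
    return alignment


def blocking_pairs(scores: ScoreTable, alignment: Alignment) -> list[tuple[str, str]]:
    """Exhaustive scan for pairs that would both rather be matched together.

    Serves as an independent stability check on stable_marriage output.
    """
    matched_s = {c.source: c.target for c in alignment.correspondences}
    matched_t = {c.target: c.source for c in alignment.correspondences}
    idx_s = {s: i for i, s in enumerate(scores.sources)}
    idx_t = {t: j for j, t in enumerate(scores.targets)}

    def s_prefers(s: str, t_new: str) -> bool:
        cur = matched_s.get(s)
        if cur is None:
            return True
        a, b = scores.scores[idx_s[s], idx_t[t_new]], scores.scores[idx_s[s], idx_t[cur]]
        return a > b or (a == b and t_new < cur)

    def t_prefers(t: str, s_new: str) -> bool:
        cur = matched_t.get(t)
        if cur is None:
            return True
        a, b = scores.scores[idx_s[s_new], idx_t[t]], scores.scores[idx_s[cur], idx_t[t]]
        return a > b or (a == b and s_new < cur)

    out = []
    for s in scores.sources:
        for t in scores.targets:
            if matched_s.get(s) == t:
                continue
            if s_prefers(s, t) and t_prefers(t, s):
                out.append((s, t))
    return out
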