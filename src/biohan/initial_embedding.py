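"""Initial Euclidean concept embeddings from terminological descriptions.

Every concept's textual description (labels plus annotations) is turned into
a fixed-size vector ``h^{0,E}`` that seeds the hyperbolic encoder.  The
default encoder is deterministic character-trigram feature hashing, so the
whole pipeline runs offline and reproducibly; a hook is provided for plugging
in a domain language model (e.g. BioBERT) when one is available, which is the
encoder a production deployment would use.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError
from .model import Ontology

logger = logging.getLogger(__name__)

DEFAULT_DIMENSION = 512


@dataclass
class EmbeddingTable:
    """Concept IRI → input vector, all of one dimension."""

    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    dimension: int = DEFAULT_DIMENSION

    def __post_init__(self) -> None:
        for iri, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ConfigurationError(
                    f"vector for {iri} has shape {v.shape}, expected ({self.dimension},)"
                )
            if not np.all(np.isfinite(v)):
                raise ConfigurationError(f"non-finite entries in vector for {iri}")

    def matrix(self, order: Sequence[str]) -> np.ndarray:
        """Stack vectors for the given IRIs into an (n, d) array."""
        missing = [iri for iri in order if iri not in self.vectors]
        if missing:
            raise ConfigurationError(f"no embedding for concepts: {missing[:5]}")
        return np.stack([self.vectors[iri] for iri in order])


def local_name(iri: str) -> str:
    """Human-ish fallback text from an IRI: local name, separators to spaces."""
    tail = iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1].rsplit(":", 1)[-1]
    return " ".join(tail.replace("_", " ").replace("-", " ").split())


def build_concept_text(concept: str, ontology: Ontology) -> str:
    """Assemble the description text of a concept.

    Order is deterministic: primary label first, then alternate labels in
    stored (predicate-priority) order, then annotation strings sorted by
    (property, text).  A label-less concept falls back to its IRI local name.
    """
    if concept not in ontology.concepts:
        raise KeyError(f"{concept} is not a concept of this ontology")
    segments = list(ontology.labels_of(concept))
    segments += [text for _, text in sorted(ontology.annotations.get(concept, []))]
    if not segments:
        logger.warning("concept %s has no labels; falling back to IRI local name", concept)
        return local_name(concept)
    return " ".join(segments)


def _trigrams(text: str) -> list[str]:
    padded = f"  {text.lower()} "
    return [padded[i : i + 3] for i in range(len(padded) - 2)]


def _hash_bucket(token: str, dimension: int, seed: int) -> tuple[int, float]:
    digest = hashlib.blake2b(
        token.encode("utf-8"), digest_size=8, key=str(seed).encode("utf-8")
    ).digest()
    value = int.from_bytes(digest, "big")
    return value % dimension, 1.0 if (value >> 63) & 1 else -1.0


def hash_ngram_vector(text: str, dimension: int, seed: int) -> np.ndarray:
    """Character-trigram feature hashing with signs, L2-normalized.

    Fully determined by (text, dimension, seed); an empty text maps to the
    zero vector.
    """
    v = np.zeros(dimension)
    if not text.strip():
        return v
    for tri in _trigrams(text.strip()):
        bucket, sign = _hash_bucket(tri, dimension, seed)
        v[bucket] += sign
    norm = np.linalg.norm(v)
    if norm > 0:
        v /= norm
    return v


def encode(
    texts: Sequence[str],
    encoder: str = "hash_ngram",
    dimension: int = DEFAULT_DIMENSION,
    seed: int = 0,
    external_fn: Callable[[Sequence[str]], np.ndarray] | None = None,
    keys: Sequence[str] | None = None,
) -> EmbeddingTable:
    """Encode texts into an :class:`EmbeddingTable`.

    ``keys`` names the table entries (defaults to stringified indices).  The
    ``external_lm`` encoder delegates to ``external_fn`` (a callable returning
    an (n, dimension) array), validating the dimension.
    """
    if dimension < 8:
        raise ConfigurationError("embedding dimension must be at least 8")
    keys = list(keys) if keys is not None else [str(i) for i in range(len(texts))]
    if len(keys) != len(texts):
        raise ConfigurationError("keys and texts must have equal length")

    if encoder == "hash_ngram":
        rows = []
        for text in texts:
            if not text.strip():
                logger.warning("empty description text; emitting zero vector")
            rows.append(hash_ngram_vector(text, dimension, seed))
        vectors = rows
    elif encoder == "external_lm":
        if external_fn is None:
            raise ConfigurationError(
                "external_lm encoder requires an embedding callable; "
                "use encoder='hash_ngram' for the built-in offline encoder"
            )
        arr = np.asarray(external_fn(list(texts)), dtype=float)
        if arr.shape != (len(texts), dimension):
            raise ConfigurationError(
                f"external encoder returned shape {arr.shape}, expected ({len(texts)}, {dimension})"
            )
        vectors = [arr[i] for i in range(len(texts))]
    else:
        raise ConfigurationError(f"unknown encoder {encoder!r}")

    return EmbeddingTable(vectors=dict(zip(keys, vectors)), dimension=dimension)


def embed_ontology(
    ontology: Ontology,
    dimension: int = DEFAULT_DIMENSION,
    seed: int = 0,
    encoder: str = "hash_ngram",
    external_fn: Callable[[Sequence[str]], np.ndarray] | None = None,
) -> EmbeddingTable:
    """Build the input table for every concept of an ontology."""
    concepts = sorted(ontology.concepts)
    texts = [build_concept_text(c, ontology) for c in concepts]
    return encode(
        texts,
        encoder=encoder,
        dimension=dimension,
        seed=seed,
        external_fn=external_fn,
        keys=concepts,
    )


def export_tsv(table: EmbeddingTable, path) -> None:
    """Write ``IRI<TAB>v1,...,vd`` lines, sorted by IRI."""
    with open(path, "w", encoding="utf-8") as fh:
        for iri in sorted(table.vectors):
            fh.write(iri + "\t" + ",".join(f"{x:.8g}" for x in table.vectors[iri]) + "\n")
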