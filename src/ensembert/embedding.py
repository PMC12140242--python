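"""Embedding backends: one contract, several encoders.

Every backend turns a list of texts into a fixed-dimension real matrix, one
row per text, and is frozen: the same text always maps to the same vector.
The default backend used throughout the test suite is
:class:`HashedBagBackend`, a deterministic bag-of-hashed-tokens encoder that
needs no model downloads yet preserves the geometric property the pipeline
relies on — texts sharing tokens have larger dot products than texts with
disjoint tokens.  Pretrained sentence encoders (e.g. all-MiniLM-L6-v2 with
384 dimensions or all-mpnet-base-v2 with 768) plug in behind the same
contract via :class:`SentenceEncoderBackend` when the optional
``sentence-transformers`` dependency is installed.

Because encoders are frozen, corpus embeddings are computed once and can be
cached on disk keyed by (backend_id, text content hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


class EmbeddingError(ValueError):
    pass


class BackendUnavailableError(RuntimeError):
    """Raised when a backend's underlying library or model is not installed."""


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Row-per-text embedding matrix with provenance."""

    vectors: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2:
            raise EmbeddingError(f"expected a 2-D matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise EmbeddingError("embedding matrix contains non-finite entries")
        object.__setattr__(self, "vectors", v)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


class EmbeddingBackend(ABC):
    """Frozen text-to-vector encoder."""

    backend_id: str
    dim: int
    deterministic: bool = True

    @abstractmethod
    def encode(self, texts: Sequence[str]) -> np.ndarray:
        """Return a len(texts) x dim float matrix, rows in input order."""


def _token_bucket(token: str, dim: int, seed: int) -> tuple[int, float]:
    """Deterministic (bucket, sign) for a token — stable across sessions."""
    digest = hashlib.blake2b(f"{seed}|{token}".encode(), digest_size=8).digest()
    value = int.from_bytes(digest, "big")
    return value % dim, 1.0 if (value >> 32) & 1 else -1.0


class HashedBagBackend(EmbeddingBackend):
    """Deterministic bag-of-hashed-tokens sentence encoder.

    Lower-cased whitespace tokens are hashed into ``dim`` signed buckets;
    counts are accumulated and the vector is L2-normalized.  Token overlap
    between two texts therefore translates into dot-product similarity,
    which is all the retrieval and attention stages require.
    """

    def __init__(self, dim: int = 64, seed: int = 0) -> None:
        if dim < 2:
            raise EmbeddingError(f"dim must be >= 2, got {dim}")
        self.dim = int(dim)
        self.seed = int(seed)
        self.backend_id = f"hashed-bag-d{dim}-s{seed}"
        self._token_cache: dict[str, tuple[int, float]] = {}

    def _bucket(self, token: str) -> tuple[int, float]:
        hit = self._token_cache.get(token)
        if hit is None:
            hit = _token_bucket(token, self.dim, self.seed)
            self._token_cache[token] = hit
        return hit

    def token_vector(self, token: str) -> np.ndarray:
        """Unit vector of a single token (its signed hash bucket)."""
        vec = np.zeros(self.dim)
        bucket, sign = self._bucket(token.lower())
        vec[bucket] = sign
        return vec

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim))
        for row, text in enumerate(texts):
            tokens = text.lower().split()
            if not tokens:
                raise EmbeddingError(f"text at position {row} is empty")
            for tok in tokens:
                bucket, sign = self._bucket(tok)
                out[row, bucket] += sign
            norm = np.linalg.norm(out[row])
            if norm == 0.0:  # sign cancellation across buckets; anchor on first token
                bucket, _ = self._bucket(tokens[0])
                out[row, bucket] = 1.0
                norm = 1.0
            out[row] /= norm
        return out


def mock_embed(text: str, dim: int = 64, seed: int = 0) -> np.ndarray:
    """One-off deterministic embedding of a single text (test double)."""
    return HashedBagBackend(dim=dim, seed=seed).encode([text])[0]


class SentenceEncoderBackend(EmbeddingBackend):
    """Pretrained frozen sentence encoder (optional plugin).

    Wraps a sentence-transformers model such as ``all-MiniLM-L6-v2`` (384-d)
    or ``all-mpnet-base-v2`` (768-d).  Requires the optional
    ``sentence-transformers`` dependency and a downloaded checkpoint.
    """

    def __init__(self, model_name: str = "all-MiniLM-L6-v2") -> None:
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise BackendUnavailableError(
                f"backend {model_name!r} needs the optional 'sentence-transformers' "
                "dependency (pip install ensembert[encoders])"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.backend_id = f"sbert-{model_name}"
        self.dim = int(self._model.get_sentence_embedding_dimension())

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        return np.asarray(self._model.encode(list(texts), convert_to_numpy=True), dtype=float)


def embed_texts(backend: EmbeddingBackend, texts: Sequence[str]) -> EmbeddingMatrix:
    """Embed texts through a backend, validating the shape contract."""
    texts = list(texts)
    if not texts:
        raise EmbeddingError("texts must be non-empty")
    for i, t in enumerate(texts):
        if not str(t).strip():
            raise EmbeddingError(f"text at position {i} is empty")
    vectors = backend.encode(texts)
    if vectors.shape != (len(texts), backend.dim):
        raise EmbeddingError(
            f"backend {backend.backend_id} returned shape {vectors.shape}, "
            f"expected {(len(texts), backend.dim)}"
        )
    return EmbeddingMatrix(vectors=vectors, backend_id=backend.backend_id)


def embed_word_mean(backend, text: str) -> np.ndarray:
    """Sentence vector as the mean of per-token vectors.

    This is how word-level models (static word vectors, token-level
    encoders) are reduced to one sentence representation.  The backend must
    expose ``token_vector(token) -> vector or None`` (None = out of
    vocabulary).  If every token is out of vocabulary, a zero vector is
    returned with a warning.
    """
    tokens = text.lower().split()
    if not tokens:
        raise EmbeddingError("text must contain at least one token")
    vecs = [v for v in (backend.token_vector(t) for t in tokens) if v is not None]
    if not vecs:
        logger.warning("all tokens out of vocabulary for text %r; returning zero vector", text)
        return np.zeros(backend.dim)
    return np.mean(np.stack(vecs), axis=0)


def get_backend(name: str = "mock", dim: int = 64, seed: int = 0) -> EmbeddingBackend:
    """Backend factory used by the CLI and pipeline config.

    ``"mock"`` (or ``"hashed-bag"``) returns the deterministic hashed-token
    encoder; any other name is treated as a sentence-transformers model id.
    """
    if name in ("mock", "hashed-bag"):
        return HashedBagBackend(dim=dim, seed=seed)
    return SentenceEncoderBackend(name)


class EmbeddingCache:
    """Disk cache of embeddings keyed by (backend_id, text content hash).

    One ``.npz`` file per store() call plus a JSON manifest; safe to reuse
    across sessions for deterministic backends.
    """

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def _key(backend_id: str, texts: Sequence[str]) -> str:
        h = hashlib.sha256()
        h.update(backend_id.encode())
        for t in texts:
            h.update(b"\x00")
            h.update(t.encode())
        return h.hexdigest()[:32]

    def get_or_compute(self, backend: EmbeddingBackend, texts: Sequence[str]) -> EmbeddingMatrix:
        key = self._key(backend.backend_id, texts)
        npz_path = self.directory / f"{key}.npz"
        if npz_path.exists():
            with np.load(npz_path) as data:
                return EmbeddingMatrix(vectors=data["vectors"], backend_id=backend.backend_id)
        matrix = embed_texts(backend, texts)
        np.savez_compressed(npz_path, vectors=matrix.vectors)
        manifest = {
            "backend_id": backend.backend_id,
            "dim": backend.dim,
            "n_texts": len(texts),
            "text_sha256": [hashlib.sha256(t.encode()).hexdigest() for t in texts],
        }
        (self.directory / f"{key}.json").write_text(json.dumps(manifest, indent=1))
        return matrix
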