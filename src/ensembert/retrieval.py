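"""Zero-shot dense retrieval: top-k posts per (user, item) by dot product.

For each questionnaire item, the item *description* embedding is the query;
every post of a user is scored by the raw dot product between its embedding
and the query, and the k highest-scoring posts (default k=20) are kept as
the model input.  No approximate index is used — user histories are small
enough for exact scoring — and ties are broken by ascending post index so
results are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import UserCorpus
from .embedding import EmbeddingMatrix
from .questionnaire import QuestionnaireItem

DEFAULT_K = 20


class RetrievalError(ValueError):
    pass


@dataclass(frozen=True)
class RetrievedSet:
    """Top-k posts for one (user, item) pair."""

    user_id: str
    item_id: int
    post_indices: np.ndarray  # row indices into the user's post matrix
    similarities: np.ndarray  # matching dot products, non-increasing
    embeddings: np.ndarray    # |post_indices| x d
    k_requested: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.post_indices, dtype=int)
        sims = np.asarray(self.similarities, dtype=float)
        if idx.shape != sims.shape or idx.ndim != 1:
            raise RetrievalError("post_indices and similarities must be aligned 1-D arrays")
        if len(set(idx.tolist())) != idx.size:
            raise RetrievalError("post_indices must be unique")
        if np.any(np.diff(sims) > 1e-12):
            raise RetrievalError("similarities must be sorted non-increasing")
        object.__setattr__(self, "post_indices", idx)
        object.__setattr__(self, "similarities", sims)
        object.__setattr__(self, "embeddings", np.asarray(self.embeddings, dtype=float))

    @property
    def k_returned(self) -> int:
        return int(self.post_indices.size)


def score_posts(post_embeddings: np.ndarray, item_embedding: np.ndarray) -> np.ndarray:
    """Dot product of every post row with the item-description embedding."""
    E = np.asarray(post_embeddings, dtype=float)
    q = np.asarray(item_embedding, dtype=float)
    if E.ndim != 2 or q.ndim != 1 or E.shape[1] != q.shape[0]:
        raise RetrievalError(
            f"dimension mismatch: posts {E.shape} vs item embedding {q.shape}"
        )
    return E @ q


def top_k_indices(similarities: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest similarities, ties broken by ascending index."""
    sims = np.asarray(similarities, dtype=float)
    if k < 1:
        raise RetrievalError(f"k must be >= 1, got {k}")
    n = sims.size
    # lexsort: primary key -sims (descending similarity), secondary ascending index
    order = np.lexsort((np.arange(n), -sims))
    return order[: min(k, n)]


def retrieve_top_k(
    corpus: UserCorpus,
    post_embeddings: EmbeddingMatrix | np.ndarray,
    item: QuestionnaireItem,
    item_embedding: np.ndarray,
    k: int = DEFAULT_K,
) -> RetrievedSet:
    """Return the k posts most similar to the item description.

    When the user has fewer than k posts, all of them are returned and the
    shortfall is reported through the ``k_returned`` property.  A user with
    zero posts is an error for this (user, item) pair.
    """
    E = post_embeddings.vectors if isinstance(post_embeddings, EmbeddingMatrix) else np.asarray(post_embeddings)
    if E.shape[0] != corpus.n_posts:
        raise RetrievalError(
            f"user {corpus.user_id}: {corpus.n_posts} posts but {E.shape[0]} embedding rows"
        )
    if corpus.n_posts == 0:
        raise RetrievalError(
            f"user {corpus.user_id}, item {item.item_id}: no posts to retrieve from"
        )
    sims = score_posts(E, item_embedding)
    idx = top_k_indices(sims, k)
    return RetrievedSet(
        user_id=corpus.user_id,
        item_id=item.item_id,
        post_indices=idx,
        similarities=sims[idx],
        embeddings=E[idx],
        k_requested=k,
    )
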