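"""The ensemble prediction head over frozen sentence embeddings.

For one (user, item) pair the head receives the item-description embedding
``D``, the four choice embeddings ``C`` (4 x d), and the embeddings of the
k' retrieved posts ``RP`` (k' x d).  It composes:

1. cross-attention of the description over the posts:
   ``alpha = softmax(D @ RP.T)``, ``CA = alpha @ RP``;
2. sub-model A: cosine similarities ``CS_l = cos(CA, C_l)`` for the four
   choices, softmaxed (with a trainable temperature) into a probability
   vector over the scores 0-3;
3. sub-model B: the choice embeddings weighted by sub-model A's
   probabilities, added to the attention-weighted mean of the posts, then
   passed through a linear + softmax output layer;
4. an ensemble layer: a single affine map + softmax over the concatenated
   sub-model probability vectors, producing the final score distribution.

The sentence encoder is frozen throughout, so the attention weights and
choice cosines are fixed features of each instance; only the head's small
parameter set (output layer, ensemble layer, temperature) is trained, by
mini-batch gradient descent on a weighted sum of the categorical
cross-entropies of sub-model A and the final output.  Attention weights are
exported per prediction so that the posts driving each item score can be
inspected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import UserCorpus
from .embedding import EmbeddingBackend, embed_texts
from .questionnaire import Questionnaire, Severity, categorize_overall, overall_from_items
from .retrieval import DEFAULT_K, retrieve_top_k

logger = logging.getLogger(__name__)

N_SCORES = 4

COMBINE_MODES = ("softmax", "cosine")
POST_DENOMINATORS = ("retrieved", "fixed_k")


class ModelError(ValueError):
    pass


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    x = np.asarray(x, dtype=float)
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass(frozen=True)
class ItemInstance:
    """Everything the head needs for one (user, item) pair."""

    description_embedding: np.ndarray  # (d,)
    choice_embeddings: np.ndarray      # (4, d)
    post_embeddings: np.ndarray        # (k', d), k' >= 1
    gold_score: int | None = None
    user_id: str | None = None
    item_id: int | None = None

    def __post_init__(self) -> None:
        D = np.asarray(self.description_embedding, dtype=float)
        C = np.asarray(self.choice_embeddings, dtype=float)
        RP = np.asarray(self.post_embeddings, dtype=float)
        d = D.shape[0]
        if C.shape != (N_SCORES, d) or RP.ndim != 2 or RP.shape[1] != d or RP.shape[0] < 1:
            raise ModelError(
                f"inconsistent instance shapes: D {D.shape}, C {C.shape}, RP {RP.shape}"
            )
        object.__setattr__(self, "description_embedding", D)
        object.__setattr__(self, "choice_embeddings", C)
        object.__setattr__(self, "post_embeddings", RP)

    @property
    def dim(self) -> int:
        return self.description_embedding.shape[0]


@dataclass(frozen=True)
class AttentionOutput:
    """Attention-weighted post representation and its weights."""

    context: np.ndarray  # (d,)
    weights: np.ndarray  # (k',), non-negative, sums to 1


@dataclass(frozen=True)
class Prediction:
    """Per-item output: three probability vectors plus interpretability data."""

    probs_a: np.ndarray
    probs_b: np.ndarray
    probs_final: np.ndarray
    predicted_score: int
    alpha: np.ndarray
    similarities: np.ndarray  # the four choice cosines
    user_id: str | None = None
    item_id: int | None = None


@dataclass
class HeadParameters:
    """Trainable parameters of the head, serializable to JSON.

    ``W_out``/``b_out`` form sub-model B's output layer (d -> 4 logits);
    ``W_ens``/``b_ens`` form the ensemble layer (8 -> 4 logits); ``tau`` is
    sub-model A's softmax temperature.
    """

    W_out: np.ndarray
    b_out: np.ndarray
    W_ens: np.ndarray
    b_ens: np.ndarray
    tau: float = 1.0
    dim: int = 0
    k: int = DEFAULT_K
    backend_id: str = ""
    combine_mode: str = "softmax"
    post_denominator: str = "retrieved"
    format_version: int = 1

    def __post_init__(self) -> None:
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        self.W_ens = np.asarray(self.W_ens, dtype=float)
        self.b_ens = np.asarray(self.b_ens, dtype=float)
        if self.combine_mode not in COMBINE_MODES:
            raise ModelError(f"combine_mode must be one of {COMBINE_MODES}")
        if self.post_denominator not in POST_DENOMINATORS:
            raise ModelError(f"post_denominator must be one of {POST_DENOMINATORS}")
        d = self.W_out.shape[1]
        if self.W_out.shape != (N_SCORES, d) or self.b_out.shape != (N_SCORES,):
            raise ModelError(f"bad output-layer shapes {self.W_out.shape}, {self.b_out.shape}")
        if self.W_ens.shape != (N_SCORES, 2 * N_SCORES) or self.b_ens.shape != (N_SCORES,):
            raise ModelError(f"bad ensemble-layer shapes {self.W_ens.shape}, {self.b_ens.shape}")
        for arr in (self.W_out, self.b_out, self.W_ens, self.b_ens):
            if not np.all(np.isfinite(arr)):
                raise ModelError("parameters contain non-finite values")
        self.dim = int(self.dim or d)

    def save(self, path: str | Path) -> None:
        doc = {
            "format_version": self.format_version,
            "dim": self.dim,
            "k": self.k,
            "backend_id": self.backend_id,
            "combine_mode": self.combine_mode,
            "post_denominator": self.post_denominator,
            "tau": self.tau,
            "W_out": self.W_out.tolist(),
            "b_out": self.b_out.tolist(),
            "W_ens": self.W_ens.tolist(),
            "b_ens": self.b_ens.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "HeadParameters":
        doc = json.loads(Path(path).read_text())
        return cls(
            W_out=np.array(doc["W_out"]),
            b_out=np.array(doc["b_out"]),
            W_ens=np.array(doc["W_ens"]),
            b_ens=np.array(doc["b_ens"]),
            tau=float(doc["tau"]),
            dim=int(doc["dim"]),
            k=int(doc["k"]),
            backend_id=doc.get("backend_id", ""),
            combine_mode=doc.get("combine_mode", "softmax"),
            post_denominator=doc.get("post_denominator", "retrieved"),
            format_version=int(doc.get("format_version", 1)),
        )


def init_parameters(
    dim: int,
    seed: int = 0,
    k: int = DEFAULT_K,
    backend_id: str = "",
    combine_mode: str = "softmax",
    post_denominator: str = "retrieved",
    scale: float = 0.01,
) -> HeadParameters:
    """Small random initialization, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    return HeadParameters(
        W_out=scale * rng.standard_normal((N_SCORES, dim)),
        b_out=np.zeros(N_SCORES),
        W_ens=scale * rng.standard_normal((N_SCORES, 2 * N_SCORES)),
        b_ens=np.zeros(N_SCORES),
        tau=1.0,
        dim=dim,
        k=k,
        backend_id=backend_id,
        combine_mode=combine_mode,
        post_denominator=post_denominator,
    )


@dataclass
class TrainConfig:
    """Training hyperparameters; the seed fixes every stochastic choice."""

    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 0.05
    seed: int = 0
    lambda_a: float = 1.0
    lambda_final: float = 1.0
    optimizer: str = "adam"
    patience: int = 25
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ModelError("epochs, batch_size and learning_rate must be positive")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ModelError("val_fraction must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ModelError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


# ----------------------------------------------------------------------
# forward pass, stage by stage

def cross_attention(D: np.ndarray, RP: np.ndarray) -> AttentionOutput:
    """Attend the item description over the retrieved posts.

    ``logits = D @ RP.T``; ``alpha = softmax(logits)``; the context is the
    alpha-weighted sum of the post rows.  No logit scaling is applied (the
    temperature lives in sub-model A).
    """
    D = np.asarray(D, dtype=float)
    RP = np.asarray(RP, dtype=float)
    if D.ndim != 1 or RP.ndim != 2 or RP.shape[1] != D.shape[0]:
        raise ModelError(f"dimension mismatch: D {D.shape} vs RP {RP.shape}")
    if not (np.all(np.isfinite(D)) and np.all(np.isfinite(RP))):
        raise ModelError("non-finite input to cross_attention")
    alpha = softmax(D @ RP.T)
    return AttentionOutput(context=alpha @ RP, weights=alpha)


def choice_similarities(CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Cosine similarity of the attended context with each choice embedding."""
    CA = np.asarray(CA, dtype=float)
    C = np.asarray(C, dtype=float)
    ca_norm = np.linalg.norm(CA)
    c_norms = np.linalg.norm(C, axis=1)
    if ca_norm == 0.0 or np.any(c_norms == 0.0):
        raise ModelError("cosine similarity undefined for zero-norm vectors")
    return (C @ CA) / (c_norms * ca_norm)


def submodel_a(cs: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Softmax over the four choice cosines (optionally temperature-scaled)."""
    return softmax(tau * np.asarray(cs, dtype=float))


def combine(
    probs_a: np.ndarray,
    C: np.ndarray,
    alpha: np.ndarray,
    RP: np.ndarray,
    cs: np.ndarray | None = None,
    mode: str = "softmax",
    post_denominator: str = "retrieved",
    k: int = DEFAULT_K,
) -> np.ndarray:
    """Similarity-weighted choice embeddings plus the attention-weighted posts.

    ``combined = sum_l w_l C_l + (1/m) sum_i alpha_i RP_i`` where the choice
    weights ``w`` are sub-model A's probabilities (``mode="softmax"``, the
    default) or the raw cosines (``mode="cosine"``), and ``m`` is the number
    of retrieved posts (``post_denominator="retrieved"``) or the nominal k
    (``"fixed_k"``).
    """
    C = np.asarray(C, dtype=float)
    RP = np.asarray(RP, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if mode == "softmax":
        w = np.asarray(probs_a, dtype=float)
    elif mode == "cosine":
        if cs is None:
            raise ModelError("mode='cosine' requires the raw cosine scores")
        w = np.asarray(cs, dtype=float)
    else:
        raise ModelError(f"unknown combine mode {mode!r}")
    m = RP.shape[0] if post_denominator == "retrieved" else k
    return w @ C + (alpha @ RP) / m


def submodel_b(combined: np.ndarray, params: HeadParameters) -> np.ndarray:
    """Linear + softmax output layer on the combined representation."""
    return softmax(params.W_out @ np.asarray(combined, dtype=float) + params.b_out)


def ensemble(probs_a: np.ndarray, probs_b: np.ndarray, params: HeadParameters) -> np.ndarray:
    """Affine + softmax over the concatenated sub-model probabilities."""
    x = np.concatenate([np.asarray(probs_a, dtype=float), np.asarray(probs_b, dtype=float)])
    return softmax(params.W_ens @ x + params.b_ens)


def forward(instance: ItemInstance, params: HeadParameters) -> Prediction:
    """Full head forward pass for one (user, item) instance.

    Ties at the final argmax break toward the lowest score (the conservative
    severity reading).
    """
    att = cross_attention(instance.description_embedding, instance.post_embeddings)
    cs = choice_similarities(att.context, instance.choice_embeddings)
    pa = submodel_a(cs, params.tau)
    combined = combine(
        pa,
        instance.choice_embeddings,
        att.weights,
        instance.post_embeddings,
        cs=cs,
        mode=params.combine_mode,
        post_denominator=params.post_denominator,
        k=params.k,
    )
    pb = submodel_b(combined, params)
    pf = ensemble(pa, pb, params)
    return Prediction(
        probs_a=pa,
        probs_b=pb,
        probs_final=pf,
        predicted_score=int(np.argmax(pf)),  # np.argmax returns the first (lowest) maximizer
        alpha=att.weights,
        similarities=cs,
        user_id=instance.user_id,
        item_id=instance.item_id,
    )


# ----------------------------------------------------------------------
# training (frozen encoder => attention and cosines are fixed features)

@dataclass
class _Features:
    """Precomputed fixed features of a set of instances."""

    cs: np.ndarray         # (N, 4) choice cosines
    post_term: np.ndarray  # (N, d) attention-weighted post mean
    C: np.ndarray          # (N, 4, d) choice embeddings
    gold: np.ndarray       # (N,) int
    user_ids: np.ndarray   # (N,) object


def featurize(instances: Sequence[ItemInstance], params_like: HeadParameters | None = None,
              post_denominator: str = "retrieved", k: int = DEFAULT_K) -> _Features:
    """Evaluate the frozen stages (attention, cosines) once per instance."""
    if params_like is not None:
        post_denominator = params_like.post_denominator
        k = params_like.k
    cs_rows, post_rows, c_rows, gold, uids = [], [], [], [], []
    for inst in instances:
        att = cross_attention(inst.description_embedding, inst.post_embeddings)
        cs_rows.append(choice_similarities(att.context, inst.choice_embeddings))
        m = inst.post_embeddings.shape[0] if post_denominator == "retrieved" else k
        post_rows.append((att.weights @ inst.post_embeddings) / m)
        c_rows.append(inst.choice_embeddings)
        gold.append(-1 if inst.gold_score is None else int(inst.gold_score))
        uids.append(inst.user_id)
    return _Features(
        cs=np.stack(cs_rows),
        post_term=np.stack(post_rows),
        C=np.stack(c_rows),
        gold=np.asarray(gold, dtype=int),
        user_ids=np.asarray(uids, dtype=object),
    )


def _batch_forward(f: _Features, idx: np.ndarray, p: dict, combine_mode: str):
    cs = f.cs[idx]
    pa = softmax(p["tau"] * cs, axis=1)
    w = pa if combine_mode == "softmax" else cs
    combined = np.einsum("bl,bld->bd", w, f.C[idx]) + f.post_term[idx]
    pb = softmax(combined @ p["W_out"].T + p["b_out"], axis=1)
    x = np.concatenate([pa, pb], axis=1)
    pf = softmax(x @ p["W_ens"].T + p["b_ens"], axis=1)
    return pa, combined, pb, x, pf


def _batch_loss(f: _Features, idx: np.ndarray, p: dict, combine_mode: str,
                lambda_a: float, lambda_final: float) -> float:
    pa, _, _, _, pf = _batch_forward(f, idx, p, combine_mode)
    rows = np.arange(idx.size)
    g = f.gold[idx]
    eps = 1e-12
    ce_a = -np.log(pa[rows, g] + eps)
    ce_f = -np.log(pf[rows, g] + eps)
    return float(np.mean(lambda_a * ce_a + lambda_final * ce_f))


def _batch_gradients(f: _Features, idx: np.ndarray, p: dict, combine_mode: str,
                     lambda_a: float, lambda_final: float) -> dict:
    B = idx.size
    pa, combined, pb, x, pf = _batch_forward(f, idx, p, combine_mode)
    Y = np.zeros((B, N_SCORES))
    Y[np.arange(B), f.gold[idx]] = 1.0

    dzf = lambda_final * (pf - Y) / B
    dW_ens = dzf.T @ x
    db_ens = dzf.sum(axis=0)
    gx = dzf @ p["W_ens"]
    g_pa_ens, g_pb = gx[:, :N_SCORES], gx[:, N_SCORES:]

    dzb = pb * (g_pb - (g_pb * pb).sum(axis=1, keepdims=True))
    dW_out = dzb.T @ combined
    db_out = dzb.sum(axis=0)
    g_combined = dzb @ p["W_out"]

    if combine_mode == "softmax":
        g_pa_comb = np.einsum("bd,bld->bl", g_combined, f.C[idx])
    else:
        g_pa_comb = np.zeros((B, N_SCORES))
    g_pa = g_pa_ens + g_pa_comb
    dza = pa * (g_pa - (g_pa * pa).sum(axis=1, keepdims=True))
    dza += lambda_a * (pa - Y) / B
    dtau = float(np.sum(dza * f.cs[idx]))

    return {"W_out": dW_out, "b_out": db_out, "W_ens": dW_ens, "b_ens": db_ens, "tau": dtau}


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            g = np.asarray(g, dtype=float)
            self.m[key] = self.beta1 * self.m.get(key, 0.0) + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v.get(key, 0.0) + (1 - self.beta2) * g * g
            m_hat = self.m[key] / (1 - self.beta1**self.t)
            v_hat = self.v[key] / (1 - self.beta2**self.t)
            params[key] = params[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    instances: Sequence[ItemInstance],
    config: TrainConfig,
    init: HeadParameters | None = None,
) -> tuple[HeadParameters, TrainingLog]:
    """Fit the head on gold-labelled instances by mini-batch gradient descent.

    The loss is ``lambda_a * CE(probs_A) + lambda_final * CE(probs_final)``
    averaged over instances.  When ``val_fraction > 0`` a user-level slice of
    the training instances is held out for early stopping, and the returned
    parameters are the ones with the best validation loss.  Fully
    deterministic given ``config.seed``.
    """
    instances = list(instances)
    if not instances:
        raise ModelError("no training instances")
    if any(inst.gold_score is None for inst in instances):
        raise ModelError("every training instance needs a gold_score")
    dim = instances[0].dim

    if init is None:
        init = init_parameters(dim, seed=config.seed)
    feats = featurize(instances, params_like=init)

    rng = np.random.default_rng(config.seed)
    users = np.array(sorted({str(u) for u in feats.user_ids}))
    if config.val_fraction > 0 and len(users) >= 2:
        n_val = max(1, int(round(len(users) * config.val_fraction)))
        n_val = min(n_val, len(users) - 1)
        val_users = set(rng.permutation(users)[:n_val].tolist())
        is_val = np.array([str(u) in val_users for u in feats.user_ids])
    else:
        is_val = np.zeros(len(instances), dtype=bool)
    train_idx = np.flatnonzero(~is_val)
    val_idx = np.flatnonzero(is_val)

    p = {
        "W_out": init.W_out.copy(),
        "b_out": init.b_out.copy(),
        "W_ens": init.W_ens.copy(),
        "b_ens": init.b_ens.copy(),
        "tau": float(init.tau),
    }
    opt = _Adam(config.learning_rate) if config.optimizer == "adam" else None
    log = TrainingLog()
    best_val = np.inf
    best_p = {k: np.copy(v) for k, v in p.items()}
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads = _batch_gradients(
                feats, batch, p, init.combine_mode, config.lambda_a, config.lambda_final
            )
            if opt is not None:
                opt.step(p, grads)
            else:
                for key, g in grads.items():
                    p[key] = p[key] - config.learning_rate * g
        tr_loss = _batch_loss(feats, train_idx, p, init.combine_mode,
                              config.lambda_a, config.lambda_final)
        if not np.isfinite(tr_loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}; "
                f"lr={config.learning_rate}, tau={p['tau']}"
            )
        log.train_loss.append(tr_loss)
        if val_idx.size:
            v_loss = _batch_loss(feats, val_idx, p, init.combine_mode,
                                 config.lambda_a, config.lambda_final)
            log.val_loss.append(v_loss)
            if v_loss < best_val - 1e-9:
                best_val = v_loss
                best_p = {k: np.copy(v) for k, v in p.items()}
                log.best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        else:
            best_p = p
            log.best_epoch = epoch

    return (
        HeadParameters(
            W_out=best_p["W_out"],
            b_out=best_p["b_out"],
            W_ens=best_p["W_ens"],
            b_ens=best_p["b_ens"],
            tau=float(best_p["tau"]),
            dim=dim,
            k=init.k,
            backend_id=init.backend_id,
            combine_mode=init.combine_mode,
            post_denominator=init.post_denominator,
        ),
        log,
    )


# ----------------------------------------------------------------------
# whole-user prediction

@dataclass(frozen=True)
class UserPrediction:
    """One user's predicted item scores, overall score, and category."""

    user_id: str
    item_scores: tuple[int, ...]
    overall: int
    category: Severity
    predictions: tuple[Prediction, ...]

    def attention_report(self, retrieved: Sequence | None = None) -> list[dict]:
        """Per-item attention weights over the retrieved posts (rows sum to 1)."""
        report = []
        for pred in self.predictions:
            report.append(
                {
                    "item_id": pred.item_id,
                    "alpha": pred.alpha.tolist(),
                    "choice_cosines": pred.similarities.tolist(),
                    "predicted_score": pred.predicted_score,
                }
            )
        return report


def embed_questionnaire(
    backend: EmbeddingBackend, questionnaire: Questionnaire
) -> tuple[np.ndarray, np.ndarray]:
    """Embed all item descriptions (21 x d) and choices (21 x 4 x d) once."""
    desc = embed_texts(backend, [it.description for it in questionnaire]).vectors
    choice_texts = [c.text for it in questionnaire for c in it.choices]
    C = embed_texts(backend, choice_texts).vectors.reshape(len(questionnaire), N_SCORES, -1)
    return desc, C


def build_instances(
    corpora: Sequence[UserCorpus],
    questionnaire: Questionnaire,
    backend: EmbeddingBackend,
    k: int = DEFAULT_K,
    require_gold: bool = False,
) -> list[ItemInstance]:
    """Embed, retrieve, and assemble one instance per (user, item) pair.

    Users with zero posts are skipped with a warning (they cannot be
    retrieved from); with ``require_gold`` they must carry gold scores.
    """
    desc_emb, choice_emb = embed_questionnaire(backend, questionnaire)
    out: list[ItemInstance] = []
    for corpus in corpora:
        if corpus.n_posts == 0:
            logger.warning("user %s has no usable posts; skipped", corpus.user_id)
            continue
        if require_gold and corpus.gold_scores is None:
            raise ModelError(f"user {corpus.user_id} lacks gold scores")
        post_matrix = embed_texts(backend, corpus.texts)
        for item in questionnaire:
            rs = retrieve_top_k(corpus, post_matrix, item, desc_emb[item.item_id - 1], k=k)
            gold = None if corpus.gold_scores is None else corpus.gold_scores[item.item_id - 1]
            out.append(
                ItemInstance(
                    description_embedding=desc_emb[item.item_id - 1],
                    choice_embeddings=choice_emb[item.item_id - 1],
                    post_embeddings=rs.embeddings,
                    gold_score=gold,
                    user_id=corpus.user_id,
                    item_id=item.item_id,
                )
            )
    return out


def predict_user(
    corpus: UserCorpus,
    questionnaire: Questionnaire,
    params: HeadParameters,
    backend: EmbeddingBackend,
    k: int | None = None,
) -> UserPrediction:
    """Predict all 21 item scores for one user and aggregate them.

    The overall score is the sum of the per-item argmax predictions and the
    category is its evaluation-scheme banding.
    """
    if corpus.n_posts == 0:
        raise ModelError(f"user {corpus.user_id} has no usable posts")
    k = params.k if k is None else k
    instances = build_instances([corpus], questionnaire, backend, k=k)
    preds = tuple(forward(inst, params) for inst in instances)
    scores = tuple(p.predicted_score for p in preds)
    overall = overall_from_items(scores)
    return UserPrediction(
        user_id=corpus.user_id,
        item_scores=scores,
        overall=overall,
        category=categorize_overall(overall),
        predictions=preds,
    )
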