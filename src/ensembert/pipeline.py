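"""End-to-end orchestration: ingest/simulate -> filter -> embed -> retrieve
-> train -> predict -> evaluate, with a reproducibility manifest.

A run is described by a :class:`RunConfig` (loadable from a JSON document).
Input is either a posts file + gold-score file or a synthetic-cohort
configuration.  The run splits users into train/test, trains the head on the
train side, predicts every test user at item / overall / category
granularity, and writes predictions, the evaluation report, per-item
attention weights, trained parameters, and a manifest with content hashes of
every output so a rerun can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .corpus import UserCorpus, attach_gold_scores, filter_corpora, read_gold_scores, read_posts, split_users
from .embedding import get_backend
from .metrics import EvaluationReport, evaluation_report
from .model import (
    HeadParameters,
    TrainConfig,
    build_instances,
    forward,
    init_parameters,
    train,
)
from .questionnaire import (
    Questionnaire,
    bundled_questionnaire,
    categorize_overall,
    load_questionnaire,
    overall_from_items,
)
from .retrieval import DEFAULT_K
from .synthetic_data import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything one experiment needs; JSON-serializable."""

    workdir: str = "ensembert_run"
    posts_path: str | None = None
    scores_path: str | None = None
    questionnaire_path: str | None = None
    synthetic: CohortConfig | None = None
    backend_name: str = "mock"
    backend_dim: int = 64
    backend_seed: int = 0
    k: int = DEFAULT_K
    min_words: int = 3
    test_fraction: float = 0.2
    split_seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        if "synthetic" in doc and doc["synthetic"] is not None:
            doc["synthetic"] = CohortConfig(**doc["synthetic"])
        if "train" in doc and doc["train"] is not None:
            doc["train"] = TrainConfig(**doc["train"])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


@dataclass
class RunManifest:
    """Reproducibility record of one run."""

    config: dict
    package_version: str
    seeds: dict
    output_hashes: dict = field(default_factory=dict)
    timings_sec: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "package_version": self.package_version,
                "seeds": self.seeds,
                "output_hashes": self.output_hashes,
                "timings_sec": self.timings_sec,
            },
            indent=1,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig) -> tuple[list[UserCorpus], Questionnaire]:
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        questionnaire = cohort.questionnaire
        if config.questionnaire_path:
            questionnaire = load_questionnaire(config.questionnaire_path)
        return list(cohort.corpora), questionnaire
    if not config.posts_path or not config.scores_path:
        raise PipelineError("need either a synthetic config or posts_path + scores_path")
    corpora = read_posts(config.posts_path)
    corpora = attach_gold_scores(corpora, read_gold_scores(config.scores_path))
    questionnaire = (
        load_questionnaire(config.questionnaire_path)
        if config.questionnaire_path
        else bundled_questionnaire()
    )
    return corpora, questionnaire


def predict_split(
    corpora: Sequence[UserCorpus],
    questionnaire: Questionnaire,
    params: HeadParameters,
    backend,
    k: int,
) -> tuple[dict, dict, dict, list[dict]]:
    """Predict every user; returns item/overall/category mappings + attention rows."""
    item_pred: dict = {}
    overall_pred: dict = {}
    cat_pred: dict = {}
    attention_rows: list[dict] = []
    instances = build_instances(corpora, questionnaire, backend, k=k)
    by_user: dict[str, list] = {}
    for inst in instances:
        by_user.setdefault(inst.user_id, []).append(inst)
    for uid, insts in by_user.items():
        preds = [forward(inst, params) for inst in sorted(insts, key=lambda i: i.item_id)]
        scores = [p.predicted_score for p in preds]
        overall = overall_from_items(scores)
        overall_pred[uid] = overall
        cat_pred[uid] = int(categorize_overall(overall))
        for p in preds:
            item_pred[(uid, p.item_id)] = p.predicted_score
            attention_rows.append(
                {
                    "user_id": uid,
                    "item_id": p.item_id,
                    "alpha": p.alpha.tolist(),
                    "choice_cosines": p.similarities.tolist(),
                    "predicted_score": p.predicted_score,
                }
            )
    return item_pred, overall_pred, cat_pred, attention_rows


def run_experiment(config: RunConfig) -> tuple[EvaluationReport, RunManifest]:
    """Execute the full pipeline on a train/test user split."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        seeds={
            "split": config.split_seed,
            "train": config.train.seed,
            "backend": config.backend_seed,
            "synthetic": None if config.synthetic is None else config.synthetic.seed,
        },
    )
    timings = manifest.timings_sec

    t0 = time.perf_counter()
    corpora, questionnaire = _load_inputs(config)
    corpora = filter_corpora(corpora, min_words=config.min_words)
    usable = [c for c in corpora if c.n_posts > 0 and c.gold_scores is not None]
    dropped = len(corpora) - len(usable)
    if dropped:
        logger.warning("%d user(s) dropped (no usable posts or no gold scores)", dropped)
    timings["ingest"] = time.perf_counter() - t0

    train_users, test_users = split_users(usable, config.test_fraction, config.split_seed)
    train_ids = {c.user_id for c in train_users}
    test_ids = {c.user_id for c in test_users}
    if train_ids & test_ids:
        raise PipelineError("train/test user overlap detected")
    logger.info("split: %d train / %d test users", len(train_users), len(test_users))

    backend = get_backend(config.backend_name, dim=config.backend_dim, seed=config.backend_seed)

    t0 = time.perf_counter()
    train_instances = build_instances(
        train_users, questionnaire, backend, k=config.k, require_gold=True
    )
    timings["embed_retrieve_train_side"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    init = init_parameters(
        dim=backend.dim,
        seed=config.train.seed,
        k=config.k,
        backend_id=backend.backend_id,
    )
    params, log = train(train_instances, config.train, init=init)
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    item_pred, overall_pred, cat_pred, attention_rows = predict_split(
        test_users, questionnaire, params, backend, config.k
    )
    timings["predict"] = time.perf_counter() - t0

    item_true = {
        (c.user_id, item_id): c.gold_scores[item_id - 1]
        for c in test_users
        for item_id in range(1, len(questionnaire) + 1)
    }
    overall_true = {c.user_id: c.gold_overall for c in test_users}
    cat_true = {c.user_id: int(categorize_overall(c.gold_overall)) for c in test_users}
    train_cats = [int(categorize_overall(c.gold_overall)) for c in train_users]

    report = evaluation_report(
        item_true, item_pred, overall_true, overall_pred, cat_true, cat_pred,
        train_cats=train_cats,
    )

    # persist outputs
    params_path = workdir / "params.json"
    params.save(params_path)
    item_df = pd.DataFrame(
        [
            {"user_id": u, "item_id": i, "true": item_true[(u, i)], "pred": item_pred[(u, i)]}
            for (u, i) in sorted(item_true, key=lambda k: (str(k[0]), k[1]))
        ]
    )
    item_df.to_csv(workdir / "predictions_item.csv", index=False)
    user_df = pd.DataFrame(
        [
            {
                "user_id": u,
                "true_overall": overall_true[u],
                "pred_overall": overall_pred[u],
                "true_category": cat_true[u],
                "pred_category": cat_pred[u],
            }
            for u in sorted(overall_true, key=str)
        ]
    )
    user_df.to_csv(workdir / "predictions_user.csv", index=False)
    (workdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    with (workdir / "attention.jsonl").open("w") as fh:
        for row in attention_rows:
            fh.write(json.dumps(row) + "\n")
    (workdir / "training_log.json").write_text(
        json.dumps({"train_loss": log.train_loss, "val_loss": log.val_loss,
                    "best_epoch": log.best_epoch})
    )

    for name in ("params.json", "predictions_item.csv", "predictions_user.csv",
                 "report.json", "attention.jsonl", "training_log.json"):
        manifest.output_hashes[name] = _sha256(workdir / name)
    (workdir / "manifest.json").write_text(manifest.to_json())
    return report, manifest
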