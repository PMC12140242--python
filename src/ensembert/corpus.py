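"""Per-user post collections: reading, length filtering, splitting, summaries.

Post histories arrive as line-delimited JSON records ``{"user_id", "text",
"timestamp"?}``; optional gold item scores arrive as a CSV with a ``user_id``
column followed by 21 integer columns.  Posts with fewer than three
whitespace tokens are dropped before retrieval, since one- and two-word
posts carry almost no usable semantics.  Splits are always at user level so
no user contributes posts to both the train and the test side.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .questionnaire import N_ITEMS, Questionnaire, Severity, categorize_overall, overall_from_items

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Raised for malformed post or score files."""


@dataclass(frozen=True)
class Post:
    post_id: int
    text: str
    timestamp: str | None = None


@dataclass(frozen=True)
class UserCorpus:
    """One user's ordered posts, optionally with their 21 gold item scores."""

    user_id: str
    posts: tuple[Post, ...]
    gold_scores: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.gold_scores is not None:
            scores = tuple(int(s) for s in self.gold_scores)
            if len(scores) != N_ITEMS or any(s not in (0, 1, 2, 3) for s in scores):
                raise CorpusError(
                    f"user {self.user_id}: gold_scores must be {N_ITEMS} integers in 0..3"
                )
            object.__setattr__(self, "gold_scores", scores)

    @property
    def n_posts(self) -> int:
        return len(self.posts)

    @property
    def gold_overall(self) -> int:
        if self.gold_scores is None:
            raise CorpusError(f"user {self.user_id} has no gold scores")
        return overall_from_items(self.gold_scores)

    @property
    def texts(self) -> list[str]:
        return [p.text for p in self.posts]


@dataclass(frozen=True)
class CorpusStats:
    """Cohort-level summary: post-count shape, score marginals, categories."""

    n_users: int
    posts_per_user_mean: float
    posts_per_user_median: float
    posts_per_user_std: float
    cv_percent: float | None
    score_marginals: tuple[float, float, float, float] | None = None
    category_counts: tuple[int, int, int, int] | None = None


#: Published summary of the eRisk 2019/2021 depression cohort (100 Reddit
#: users with self-reported BDI-II item scores): posts-per-user shape after
#: the >2-word filter, item-score marginals, and severity-category counts.
#: Used as the emulation target for the synthetic cohort generator.
ERISK_REFERENCE_STATS = CorpusStats(
    n_users=100,
    posts_per_user_mean=274.0,
    posts_per_user_median=165.0,
    posts_per_user_std=265.0,
    cv_percent=None,  # derived: see cv_percent()
    score_marginals=(0.25, 0.35, 0.23, 0.17),
    category_counts=(10, 17, 31, 42),
)


def cv_percent(mean: float, std: float) -> float | None:
    """Coefficient of variation in percent, 100*std/mean; None when mean is 0."""
    if mean == 0:
        return None
    return 100.0 * std / mean


def read_posts(path: str | Path) -> list[UserCorpus]:
    """Read a line-delimited JSON post file into one UserCorpus per user.

    Original line order is preserved as post order within each user; post
    ids are 0-based positions within the user's sequence.
    """
    path = Path(path)
    by_user: dict[str, list[Post]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
            for fld in ("user_id", "text"):
                if fld not in rec:
                    raise CorpusError(f"{path}:{lineno}: record missing required field {fld!r}")
            uid = str(rec["user_id"])
            text = str(rec["text"])
            if not text.strip():
                raise CorpusError(f"{path}:{lineno}: post text is empty")
            if uid not in by_user:
                by_user[uid] = []
                order.append(uid)
            by_user[uid].append(
                Post(post_id=len(by_user[uid]), text=text, timestamp=rec.get("timestamp"))
            )
    return [UserCorpus(user_id=uid, posts=tuple(by_user[uid])) for uid in order]


def read_gold_scores(path: str | Path) -> dict[str, tuple[int, ...]]:
    """Read a gold-score CSV (user_id + 21 integer columns) into a mapping."""
    df = pd.read_csv(path)
    if "user_id" not in df.columns:
        raise CorpusError(f"{path}: gold-score file must have a 'user_id' column")
    score_cols = [c for c in df.columns if c != "user_id"]
    if len(score_cols) != N_ITEMS:
        raise CorpusError(
            f"{path}: expected {N_ITEMS} score columns, found {len(score_cols)}"
        )
    out: dict[str, tuple[int, ...]] = {}
    for _, row in df.iterrows():
        out[str(row["user_id"])] = tuple(int(row[c]) for c in score_cols)
    return out


def attach_gold_scores(
    corpora: Iterable[UserCorpus], scores: Mapping[str, Sequence[int]]
) -> list[UserCorpus]:
    """Return corpora with gold scores attached where available."""
    out = []
    for c in corpora:
        if c.user_id in scores:
            out.append(replace(c, gold_scores=tuple(int(s) for s in scores[c.user_id])))
        else:
            out.append(c)
    return out


def filter_short_posts(corpus: UserCorpus, min_words: int = 3) -> UserCorpus:
    """Drop posts with fewer than ``min_words`` whitespace tokens.

    The default keeps only posts with more than two words.  Post ids are
    preserved, so filtered corpora stay aligned with the original ordering.
    """
    if min_words < 1:
        raise ValueError(f"min_words must be >= 1, got {min_words}")
    kept = tuple(p for p in corpus.posts if len(p.text.split()) >= min_words)
    if not kept:
        logger.warning("user %s: no posts survive the %d-word filter", corpus.user_id, min_words)
    return replace(corpus, posts=kept)


def filter_corpora(corpora: Iterable[UserCorpus], min_words: int = 3) -> list[UserCorpus]:
    return [filter_short_posts(c, min_words) for c in corpora]


def split_users(
    corpora: Sequence[UserCorpus], test_fraction: float, seed: int
) -> tuple[list[UserCorpus], list[UserCorpus]]:
    """User-level holdout split; deterministic given the seed.

    The test side gets ``round(n * test_fraction)`` users (the standard
    80-20 holdout with 100 users yields 80 train / 20 test).
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = len(corpora)
    if n < 2:
        raise ValueError(f"need at least 2 users to split, got {n}")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [corpora[i] for i in range(n) if i not in test_idx]
    test = [corpora[i] for i in range(n) if i in test_idx]
    return train, test


def summarize_corpus(
    corpora: Sequence[UserCorpus],
    questionnaire: Questionnaire | None = None,
    ddof: int = 1,
) -> CorpusStats:
    """Posts-per-user shape, gold-score marginals, and category counts.

    ``ddof=1`` (sample standard deviation) is the default; set ``ddof=0``
    for the population convention.  Category counts use the evaluation
    banding of each user's summed gold scores and are omitted when any user
    lacks gold scores.
    """
    counts = np.array([c.n_posts for c in corpora], dtype=float)
    if counts.size == 0:
        raise ValueError("cannot summarize an empty cohort")
    mean = float(counts.mean())
    std = float(counts.std(ddof=ddof)) if counts.size > 1 else 0.0
    marginals = None
    cat_counts = None
    with_gold = [c for c in corpora if c.gold_scores is not None]
    if with_gold:
        all_scores = np.concatenate([np.asarray(c.gold_scores) for c in with_gold])
        freq = np.bincount(all_scores, minlength=4).astype(float)
        marginals = tuple(freq / freq.sum())
        if len(with_gold) == len(corpora):
            cats = [categorize_overall(c.gold_overall) for c in corpora]
            cat_counts = tuple(
                int(sum(1 for c in cats if c == s)) for s in Severity
            )
    return CorpusStats(
        n_users=len(corpora),
        posts_per_user_mean=mean,
        posts_per_user_median=float(np.median(counts)),
        posts_per_user_std=std,
        cv_percent=cv_percent(mean, std),
        score_marginals=marginals,
        category_counts=cat_counts,
    )


def write_posts(corpora: Iterable[UserCorpus], path: str | Path) -> None:
    """Write corpora back to the line-delimited JSON post format."""
    path = Path(path)
    with path.open("w") as fh:
        for c in corpora:
            for p in c.posts:
                rec = {"user_id": c.user_id, "text": p.text}
                if p.timestamp is not None:
                    rec["timestamp"] = p.timestamp
                fh.write(json.dumps(rec) + "\n")


def write_gold_scores(corpora: Iterable[UserCorpus], path: str | Path) -> None:
    """Write gold scores (users that have them) to the tabular CSV format."""
    rows = []
    for c in corpora:
        if c.gold_scores is not None:
            rows.append({"user_id": c.user_id, **{f"item_{i+1}": s for i, s in enumerate(c.gold_scores)}})
    pd.DataFrame(rows).to_csv(path, index=False)
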