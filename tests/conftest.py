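import numpy as np
import pytest

from ensembert.corpus import Post, UserCorpus
from ensembert.embedding import HashedBagBackend
from ensembert.model import TrainConfig
from ensembert.questionnaire import bundled_questionnaire
from ensembert.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def questionnaire():
    return bundled_questionnaire()


@pytest.fixture(scope="session")
def backend():
    return HashedBagBackend(dim=64, seed=0)


def small_cohort_config(**overrides) -> CohortConfig:
    """Desk-scale cohort: study-condition marginals/signal/correlation with a
    reduced posts-per-user scale (median 30, std 48 — the reference 165/265
    shape scaled by ~5.5x) so tests stay fast."""
    defaults = dict(
        n_users=60,
        post_count_median=30.0,
        post_count_std=48.0,
        signal_strength=0.8,
        inter_item_correlation=0.6,
        seed=0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config())


@pytest.fixture()
def tiny_corpus():
    posts = tuple(
        Post(post_id=i, text=t)
        for i, t in enumerate(
            ["ok", "I feel sad today honestly", "why me", "sleep has been terrible lately for weeks"]
        )
    )
    return UserCorpus(user_id="u1", posts=posts, gold_scores=tuple([1] * 21))


def fast_train_config(seed: int = 0, **overrides) -> TrainConfig:
    defaults = dict(epochs=120, seed=seed, patience=20)
    defaults.update(overrides)
    return TrainConfig(**defaults)
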