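"""Internal-consistency statistics over a users x items score matrix.

Cronbach's alpha ``K/(K-1) * (1 - sum(var_item) / var_total)`` quantifies
how much the 21 items behave as measurements of one underlying construct;
values above 0.9 indicate excellent internal consistency.  The corrected
item-total correlation of an item is the Pearson correlation between its
column and the sum of the *other* columns; near-zero or negative values flag
items that do not track the overall construct.  Sample (n-1) variances are
used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import UserCorpus
from .questionnaire import N_ITEMS, Questionnaire


class PsychometricsError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreMatrix:
    """Complete n_users x n_items integer score matrix."""

    values: np.ndarray
    user_ids: tuple[str, ...] | None = None
    item_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise PsychometricsError(f"score matrix must be 2-D, got shape {v.shape}")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(v == np.round(v)):
                raise PsychometricsError("score matrix entries must be integers")
            v = v.astype(int)
        if np.any((v < 0) | (v > 3)):
            raise PsychometricsError("score matrix entries must be in 0..3")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_corpora(
        cls, corpora: Sequence[UserCorpus], questionnaire: Questionnaire | None = None
    ) -> "ScoreMatrix":
        rows = []
        uids = []
        for c in corpora:
            if c.gold_scores is None:
                raise PsychometricsError(f"user {c.user_id} has no gold scores")
            rows.append(c.gold_scores)
            uids.append(c.user_id)
        names = tuple(it.name for it in questionnaire) if questionnaire else None
        return cls(values=np.asarray(rows, dtype=int), user_ids=tuple(uids), item_names=names)

    @property
    def n_users(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


def _as_values(m: ScoreMatrix | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, ScoreMatrix) else np.asarray(m, dtype=float)


def cronbach_alpha(m: ScoreMatrix | np.ndarray, ddof: int = 1) -> float:
    """Cronbach's alpha via the item/total variance formula."""
    v = _as_values(m).astype(float)
    n, k = v.shape
    if n < 2 or k < 2:
        raise PsychometricsError(f"need >= 2 users and >= 2 items, got {v.shape}")
    total_var = np.var(v.sum(axis=1), ddof=ddof)
    if total_var == 0:
        raise PsychometricsError("total-score variance is zero; alpha undefined")
    item_vars = np.var(v, axis=0, ddof=ddof)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def item_total_correlations(m: ScoreMatrix | np.ndarray) -> np.ndarray:
    """Corrected item-total correlations (item vs sum of the other items).

    Items whose column (or whose rest-total) has zero variance get NaN.
    """
    v = _as_values(m).astype(float)
    n, k = v.shape
    if n < 3:
        raise PsychometricsError(f"need >= 3 users, got {n}")
    total = v.sum(axis=1)
    out = np.full(k, np.nan)
    for j in range(k):
        rest = total - v[:, j]
        if np.std(v[:, j]) == 0 or np.std(rest) == 0:
            continue
        out[j] = float(np.corrcoef(v[:, j], rest)[0, 1])
    return out


def item_descriptives(m: ScoreMatrix | np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-item mean and sample standard deviation."""
    v = _as_values(m).astype(float)
    if v.shape[0] < 2:
        raise PsychometricsError("need >= 2 users for descriptives")
    return v.mean(axis=0), v.std(axis=0, ddof=ddof)


def reliability_report(m: ScoreMatrix | np.ndarray) -> pd.DataFrame:
    """Per-item mean / SD / corrected item-total correlation, alpha in attrs.

    The layout mirrors the standard internal-reliability table for the
    BDI-II: one row per item, Cronbach's alpha as a footer statistic.
    """
    v = _as_values(m)
    means, sds = item_descriptives(v)
    corr = item_total_correlations(v)
    names = None
    if isinstance(m, ScoreMatrix) and m.item_names is not None:
        names = list(m.item_names)
    df = pd.DataFrame(
        {
            "item": names if names is not None else [f"item_{j+1}" for j in range(v.shape[1])],
            "mean": means,
            "sd": sds,
            "item_total_corr": corr,
        }
    )
    df.attrs["cronbach_alpha"] = cronbach_alpha(v)
    return df
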