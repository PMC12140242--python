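"""The BDI-II instrument: items, choices, overall-score and severity arithmetic.

The Beck Depression Inventory-II is a 21-item self-report instrument.  Each
item probes one depressive symptom (sadness, pessimism, loss of energy, ...)
and offers four choices scored 0-3 in increasing intensity.  The overall
score is the plain sum over the 21 items, hence lies in [0, 63], and is
banded into four severity categories (Minimal / Mild / Moderate / Severe).

Two banding conventions are in circulation for the BDI-II total.  This
package evaluates with the ``"evaluation"`` scheme (0-13 / 14-19 / 20-28 /
>=29), which is the one that defines the category-level error metrics
downstream; the older screening bands (0-9 / 10-18 / 19-29 / 30-63) remain
available as ``scheme="screening"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

N_ITEMS = 21
MIN_OVERALL = 0
MAX_OVERALL = 63
SCORE_LEVELS = (0, 1, 2, 3)


class QuestionnaireError(ValueError):
    """Raised when an instrument definition violates its invariants."""


class Severity(IntEnum):
    """Four-level banding of the BDI-II overall score."""

    MINIMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.capitalize()


SEVERITY_LABELS = tuple(s.label for s in Severity)

# Upper (inclusive) bounds of the first three bands; the last band is open.
_BAND_SCHEMES = {
    "evaluation": (13, 19, 28),
    "screening": (9, 18, 29),
}


@dataclass(frozen=True)
class Choice:
    """One response option of an item: free text plus its 0-3 score."""

    text: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in SCORE_LEVELS:
            raise QuestionnaireError(f"choice score must be in {SCORE_LEVELS}, got {self.score!r}")
        if not str(self.text).strip():
            raise QuestionnaireError("choice text must be non-empty")


@dataclass(frozen=True)
class QuestionnaireItem:
    """A single instrument item with its enriched description and 4 choices."""

    item_id: int
    name: str
    description: str
    choices: tuple[Choice, ...]

    def __post_init__(self) -> None:
        if not (1 <= self.item_id <= N_ITEMS):
            raise QuestionnaireError(f"item_id must be in 1..{N_ITEMS}, got {self.item_id}")
        if not self.description.strip():
            raise QuestionnaireError(f"item {self.item_id} ({self.name}): description is empty")
        if len(self.choices) != 4:
            raise QuestionnaireError(
                f"item {self.item_id} ({self.name}): expected 4 choices, got {len(self.choices)}"
            )
        scores = sorted(c.score for c in self.choices)
        if scores != list(SCORE_LEVELS):
            raise QuestionnaireError(
                f"item {self.item_id} ({self.name}): choice scores must be exactly "
                f"{set(SCORE_LEVELS)}, got {scores}"
            )
        object.__setattr__(self, "choices", tuple(sorted(self.choices, key=lambda c: c.score)))

    def choice_for(self, score: int) -> Choice:
        """Return the unique choice carrying ``score``."""
        return self.choices[score]


@dataclass(frozen=True)
class Questionnaire:
    """An ordered, validated collection of 21 items."""

    name: str
    items: tuple[QuestionnaireItem, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(self.items) != N_ITEMS:
            raise QuestionnaireError(f"expected {N_ITEMS} items, got {len(self.items)}")
        if ids != list(range(1, N_ITEMS + 1)):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise QuestionnaireError(f"duplicate item_id(s): {sorted(dupes)}")
            raise QuestionnaireError(f"item_ids must be 1..{N_ITEMS} in order, got {ids}")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: int) -> QuestionnaireItem:
        return self.items[item_id - 1]


def load_questionnaire(path: str | Path) -> Questionnaire:
    """Load and validate an instrument definition from a JSON file.

    The file holds one document: ``{"name": ..., "items": [{"item_id",
    "name", "description", "choices": [{"score", "text"}, ...]}, ...]}``.
    Validation errors name the offending item.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise QuestionnaireError(f"malformed questionnaire file {path}: {exc}") from exc
    return _questionnaire_from_dict(raw)


def _questionnaire_from_dict(raw: dict) -> Questionnaire:
    if not isinstance(raw, dict) or "items" not in raw:
        raise QuestionnaireError("questionnaire document must be a mapping with an 'items' list")
    items = []
    for entry in raw["items"]:
        try:
            choices = tuple(Choice(text=c["text"], score=int(c["score"])) for c in entry["choices"])
            items.append(
                QuestionnaireItem(
                    item_id=int(entry["item_id"]),
                    name=str(entry["name"]),
                    description=str(entry["description"]),
                    choices=choices,
                )
            )
        except KeyError as exc:
            raise QuestionnaireError(
                f"item entry {entry.get('item_id', '?')} is missing field {exc}"
            ) from exc
    return Questionnaire(name=str(raw.get("name", "questionnaire")), items=tuple(items))


def bundled_questionnaire() -> Questionnaire:
    """The BDI-II definition shipped with the package.

    Item names follow the standard instrument.  Two enriched descriptions
    (Pessimism, Punishment feelings) are expert-written; the remaining
    descriptions and all choice texts are reconstructions in the same style
    (the file marks them as such).
    """
    with resources.files("ensembert.data").joinpath("bdi2.json").open() as fh:
        return _questionnaire_from_dict(json.load(fh))


def overall_from_items(item_scores: Sequence[int] | Iterable[int]) -> int:
    """Sum the 21 item scores into the overall score in [0, 63]."""
    scores = list(item_scores)
    if len(scores) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item scores, got {len(scores)}")
    for s in scores:
        if s not in SCORE_LEVELS:
            raise ValueError(f"item scores must be integers in {SCORE_LEVELS}, got {s!r}")
    return int(sum(scores))


def categorize_overall(y: int, scheme: str = "evaluation") -> Severity:
    """Map an overall score to its severity category.

    With the default ``"evaluation"`` scheme: 0-13 Minimal, 14-19 Mild,
    20-28 Moderate, >=29 Severe.
    """
    if not (MIN_OVERALL <= int(y) <= MAX_OVERALL):
        raise ValueError(f"overall score must be in [{MIN_OVERALL}, {MAX_OVERALL}], got {y}")
    try:
        bounds = _BAND_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown banding scheme {scheme!r}; one of {sorted(_BAND_SCHEMES)}")
    for code, upper in enumerate(bounds):
        if y <= upper:
            return Severity(code)
    return Severity.SEVERE
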