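"""Patient-level aggregation of per-snippet predictions.

A patient counts as using a supplement category if at least one of their
keyword observations inside the survey-anchored date window (one year
before to one month after the survey) is classified positive.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .snippets import NoteDocument

DAYS_BEFORE = 365  # "one year prior", inclusive
DAYS_AFTER = 30  # "one month after", inclusive


@dataclass(frozen=True)
class PatientSupplementCall:
    """Per-(patient, category) NLP decision with its evidence counts."""

    patient_id: str
    category: str
    nlp_use: bool
    n_snippets: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_positive > self.n_snippets:
            raise ValueError("n_positive cannot exceed n_snippets")
        if self.nlp_use != (self.n_positive >= 1):
            raise ValueError("nlp_use must equal (n_positive >= 1)")


def filter_notes(
    notes: Iterable[NoteDocument],
    survey_date: _dt.date,
    days_before: int = DAYS_BEFORE,
    days_after: int = DAYS_AFTER,
) -> list[NoteDocument]:
    """Keep notes dated within [survey − days_before, survey + days_after],
    both bounds inclusive."""
    lo = survey_date - _dt.timedelta(days=days_before)
    hi = survey_date + _dt.timedelta(days=days_after)
    return [n for n in notes if lo <= n.note_date <= hi]


def aggregate(
    predictions: Sequence[tuple[str, str]],
    patient_id: str,
    category_universe: Optional[Iterable[str]] = None,
) -> list[PatientSupplementCall]:
    """Any-positive roll-up of (category, "yes"/"no") predictions.

    One call per category with at least one observation; when a category
    universe is supplied, categories without observations are reported with
    ``nlp_use=False`` and zero counts.  Order-independent.
    """
    counts: dict[str, list[int]] = {}
    for category, pred in predictions:
        n_tot, n_pos = counts.setdefault(category, [0, 0])
        counts[category][0] = n_tot + 1
        counts[category][1] = n_pos + (1 if pred == "yes" else 0)
    categories = set(counts)
    if category_universe is not None:
        categories |= set(category_universe)
    out = []
    for category in sorted(categories):
        n_tot, n_pos = counts.get(category, (0, 0))
        out.append(
            PatientSupplementCall(
                patient_id=patient_id,
                category=category,
                nlp_use=n_pos >= 1,
                n_snippets=n_tot,
                n_positive=n_pos,
            )
        )
    return out


def calls_to_rows(calls: Iterable[PatientSupplementCall]) -> list[dict]:
    """Rows for the patient_id,category,nlp_use,n_snippets,n_positive CSV."""
    return [
        {
            "patient_id": c.patient_id,
            "category": c.category,
            "nlp_use": c.nlp_use,
            "n_snippets": c.n_snippets,
            "n_positive": c.n_positive,
        }
        for c in calls
    ]
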