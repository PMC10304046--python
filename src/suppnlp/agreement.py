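"""Agreement between patient-level NLP calls and survey self-report.

The survey answer is treated as the reference standard: precision is the
fraction of NLP-positive patients who also reported use, recall the
fraction of self-reported users the NLP found.  This orientation matters —
self-report is itself imperfect (patients often do not count prescribed
items such as folic acid or melatonin as "supplements"), so a low recall
here can reflect survey under-reporting as much as NLP misses.

Micro averages pool the confusion counts over categories; macro averages
are unweighted means of per-category metrics (macro F1 is the mean of the
per-category F1 values, not the harmonic mean of macro precision and
recall).  Categories reported by no more than a prevalence threshold
(default 10%) of participants are excluded from the summary rows.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .rollup import PatientSupplementCall


@dataclass(frozen=True)
class SurveyRecord:
    patient_id: str
    survey_date: _dt.date
    category: str
    reported_use: bool


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 as the harmonic mean of precision and recall."""
    if math.isnan(precision) or math.isnan(recall):
        return math.nan
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class CategoryAgreement:
    """Confusion counts and metrics for one supplement category."""

    category: str
    tp: int
    fp: int
    fn: int
    tn: int
    prevalence: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def f1(self) -> float:
        return harmonic_f1(self.precision, self.recall)


@dataclass(frozen=True)
class SummaryMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class AgreementReport:
    per_category: list[CategoryAgreement]
    prevalence_threshold: Optional[float]
    included_categories: list[str]
    micro: SummaryMetrics
    macro: SummaryMetrics

    def to_dict(self) -> dict:
        return {
            "prevalence_threshold": self.prevalence_threshold,
            "included_categories": self.included_categories,
            "per_category": [
                {
                    "category": c.category,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "prevalence": c.prevalence,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                }
                for c in self.per_category
            ],
            "micro": vars(self.micro).copy(),
            "macro": vars(self.macro).copy(),
        }

    def table(self) -> str:
        lines = [f"{'Supplement Category':<24}{'Precision':>10}{'Recall':>10}{'F1':>10}"]

        def fmt(x: float) -> str:
            return f"{x:>10.2f}" if not math.isnan(x) else f"{'--':>10}"

        for c in self.per_category:
            if c.category in self.included_categories:
                lines.append(f"{c.category:<24}{fmt(c.precision)}{fmt(c.recall)}{fmt(c.f1)}")
        lines.append(
            f"{'micro-avg':<24}{fmt(self.micro.precision)}{fmt(self.micro.recall)}{fmt(self.micro.f1)}"
        )
        lines.append(
            f"{'macro-avg':<24}{fmt(self.macro.precision)}{fmt(self.macro.recall)}{fmt(self.macro.f1)}"
        )
        return "\n".join(lines)


def confusion(
    calls: Sequence[PatientSupplementCall],
    survey: Sequence[SurveyRecord],
    category: str,
) -> CategoryAgreement:
    """Confusion counts for one category, survey as reference.

    Patients absent from the NLP calls count as NLP-negative (no snippet
    evidence); a call for a patient the survey never covered is an error.
    """
    survey_patients = {r.patient_id for r in survey}
    reported = {
        r.patient_id: r.reported_use for r in survey if r.category == category
    }
    nlp = {c.patient_id: c.nlp_use for c in calls if c.category == category}
    unknown = set(nlp) - survey_patients
    if unknown:
        raise ValueError(
            f"patients in NLP calls but not in survey: {sorted(unknown)[:5]}"
        )
    tp = fp = fn = tn = 0
    for pid in sorted(survey_patients):
        ref = reported.get(pid, False)
        pred = nlp.get(pid, False)
        if pred and ref:
            tp += 1
        elif pred and not ref:
            fp += 1
        elif not pred and ref:
            fn += 1
        else:
            tn += 1
    n = len(survey_patients)
    return CategoryAgreement(
        category=category,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        prevalence=(tp + fn) / n if n else math.nan,
    )


def macro_mean(values: Iterable[float], what: str = "metric") -> float:
    """Unweighted mean, excluding undefined (NaN) entries with a warning."""
    vals = list(values)
    defined = [v for v in vals if not math.isnan(v)]
    if len(defined) < len(vals):
        warnings.warn(
            f"{len(vals) - len(defined)} undefined {what} value(s) excluded from macro mean",
            stacklevel=2,
        )
    if not defined:
        return math.nan
    return sum(defined) / len(defined)


def micro_metrics(per_category: Sequence[CategoryAgreement]) -> SummaryMetrics:
    """Metrics from confusion counts pooled across categories."""
    tp = sum(c.tp for c in per_category)
    fp = sum(c.fp for c in per_category)
    fn = sum(c.fn for c in per_category)
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    return SummaryMetrics(precision, recall, harmonic_f1(precision, recall))


def macro_metrics(per_category: Sequence[CategoryAgreement]) -> SummaryMetrics:
    """Unweighted means of the per-category metrics; macro F1 is the mean
    of per-category F1, never the harmonic mean of the macro P/R."""
    return SummaryMetrics(
        macro_mean((c.precision for c in per_category), "precision"),
        macro_mean((c.recall for c in per_category), "recall"),
        macro_mean((c.f1 for c in per_category), "f1"),
    )


def summarize(
    per_category: Sequence[CategoryAgreement],
    prevalence_threshold: Optional[float] = 0.10,
) -> AgreementReport:
    """Micro/macro summary over categories above the prevalence threshold.

    The filter is strict: only categories reported by *more than* the
    threshold fraction of participants are included.  Pass ``None`` for an
    unfiltered report.
    """
    if prevalence_threshold is None:
        included = list(per_category)
    else:
        included = [c for c in per_category if c.prevalence > prevalence_threshold]
    if not included:
        raise ValueError("no categories pass the prevalence filter")
    return AgreementReport(
        per_category=list(per_category),
        prevalence_threshold=prevalence_threshold,
        included_categories=[c.category for c in included],
        micro=micro_metrics(included),
        macro=macro_metrics(included),
    )


def evaluate(
    calls: Sequence[PatientSupplementCall],
    survey: Sequence[SurveyRecord],
    prevalence_threshold: Optional[float] = 0.10,
) -> AgreementReport:
    """Confusion per surveyed category, then the summary report."""
    categories = sorted({r.category for r in survey})
    per_category = [confusion(calls, survey, cat) for cat in categories]
    return summarize(per_category, prevalence_threshold)


def load_reference_agreement() -> pd.DataFrame:
    """Published per-category agreement values (precision/recall/F1 of NLP
    calls against survey self-report for the supplements reported by >10%
    of participants), packaged for worked examples and arithmetic checks."""
    import importlib.resources

    path = importlib.resources.files("suppnlp").joinpath("data/reference_agreement.tsv")
    return pd.read_csv(str(path), sep="\t")


# ---------------------------------------------------------------------------
# Survey CSV I/O

def read_survey_csv(path: str | Path) -> list[SurveyRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    records = [
        SurveyRecord(
            patient_id=str(row.patient_id),
            survey_date=_dt.date.fromisoformat(str(row.survey_date)),
            category=str(row.category),
            reported_use=_parse_bool(row.reported_use),
        )
        for row in df.itertuples()
    ]
    seen = set()
    for r in records:
        key = (r.patient_id, r.category)
        if key in seen:
            raise ValueError(f"duplicate survey record for {key}")
        seen.add(key)
    return records


def write_survey_csv(records: Iterable[SurveyRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "survey_date": r.survey_date.isoformat(),
                "category": r.category,
                "reported_use": r.reported_use,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")
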