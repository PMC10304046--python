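"""Synthetic note corpora and surveys with known ground truth.

Real clinical notes from an EHR warehouse cannot be redistributed, so this
module generates corpora that emulate their semi-structured phenomenology:
numbered active-medication lists, asterisk-delimited med runs, narrative
prose about current use, all-caps allergy lines, chemistry panels whose
analyte names are homonyms of supplement keywords (calcium, creatinine,
potassium), food and diet mentions (baked fish, ginger ale), and compound
drug names (atorvastatin calcium).  Every keyword occurrence the generator
emits carries a ground-truth active-use label, and patient-level truth is
the any-positive roll-up per category.

The survey generator starts from patient-level truth and injects
controllable discordance: ``underreport_prescribed`` flips true→false for
prescribed-style categories (patients often do not consider prescribed
folic acid, melatonin or multivitamins to be "supplements"), and
``overreport`` flips false→true anywhere.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .lexicon import Lexicon, load_lexicon, match_keywords
from .snippets import (
    DEFAULT_WINDOW,
    NoteDocument,
    SnippetObservation,
    corpus_observations,
    tokenize,
)
from .agreement import SurveyRecord

POSITIVE_FAMILIES = ("med_list", "asterisk_list", "narrative")
NEGATIVE_FAMILIES = ("allergy", "lab_panel", "food", "drug_name")

# Categories patients tend to drop from self-report when physician-prescribed
DEFAULT_PRESCRIBED_STYLE = ("folic acid", "melatonin", "multivitamin")

BASE_SURVEY_DATE = _dt.date(2016, 6, 15)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults: 377 surveyed patients (the size of the survey cohort the
    pipeline is evaluated against), four notes per patient, and a positive
    share of keyword occurrences of 0.58.
    """

    n_patients: int = 377
    notes_per_patient: int = 4
    positive_rate: float = 0.58
    template_mix: dict[str, float] = field(
        default_factory=lambda: {
            f: 1.0 for f in POSITIVE_FAMILIES + NEGATIVE_FAMILIES
        }
    )
    underreport_prescribed: float = 0.0
    overreport: float = 0.0
    prescribed_categories: tuple[str, ...] = DEFAULT_PRESCRIBED_STYLE
    sections_per_note: tuple[int, int] = (2, 4)
    include_fillers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("positive_rate", self.positive_rate),
            ("underreport_prescribed", self.underreport_prescribed),
            ("overreport", self.overreport),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        unknown = set(self.template_mix) - set(POSITIVE_FAMILIES + NEGATIVE_FAMILIES)
        if unknown:
            raise ValueError(f"unknown template families: {sorted(unknown)}")
        if any(w < 0 for w in self.template_mix.values()):
            raise ValueError("template weights must be non-negative")
        total = sum(self.template_mix.values())
        if total <= 0:
            raise ValueError("impossible config: no templates enabled")
        self.template_mix = {k: v / total for k, v in self.template_mix.items()}
        if self.n_patients < 1 or self.notes_per_patient < 1:
            raise ValueError("need at least one patient and one note per patient")
        lo, hi = self.sections_per_note
        if lo < 1 or hi < lo:
            raise ValueError("sections_per_note must be a non-empty range from >= 1")


@dataclass(frozen=True)
class GroundTruthObservation:
    """One emitted keyword occurrence with its true active-use label."""

    patient_id: str
    note_index: int  # index into the corpus note list
    occurrence_index: int  # order of the occurrence within the note
    keyword: str
    category: str
    label: str  # "yes" / "no"


@dataclass
class SyntheticCorpus:
    notes: list[NoteDocument]
    observations: list[GroundTruthObservation]
    patient_use: dict[str, frozenset[str]]  # patient -> truly-used categories
    survey_dates: dict[str, _dt.date]
    config: GeneratorConfig

    def labeled_observations(
        self, lexicon: Optional[Lexicon] = None, window: int = DEFAULT_WINDOW
    ) -> list[SnippetObservation]:
        """Run the real extraction pipeline and attach ground-truth labels.

        Alignment is by occurrence order within each note; a mismatch means
        a template leaked an unintended keyword and raises.
        """
        if lexicon is None:
            lexicon = load_lexicon()
        truth_by_note: dict[int, list[GroundTruthObservation]] = {}
        for gt in self.observations:
            truth_by_note.setdefault(gt.note_index, []).append(gt)
        out: list[SnippetObservation] = []
        for i, note in enumerate(self.notes):
            obs = corpus_observations([note], lexicon, window=window)
            truth = sorted(
                truth_by_note.get(i, []), key=lambda g: g.occurrence_index
            )
            if [o.keyword for o in obs] != [g.keyword for g in truth]:
                raise RuntimeError(
                    f"ground truth misaligned with extraction for note {i}"
                )
            for o, g in zip(obs, truth):
                o.label = g.label
                out.append(o)
        return out


# ---------------------------------------------------------------------------
# Template families.  Each section builder returns one line of note text;
# every lexicon keyword occurrence in that line shares the family's polarity.
# Filler lines must not contain any lexicon keyword.

_DOSES = ["1", "5", "25", "40", "100", "325", "500", "600", "1000"]
_FORMS = ["TAB", "CAP", "CAP/TAB", "SL CAP/TAB", "POWDER"]
_FREQS = ["QDAY", "BID", "TID", "QHS", "QPM"]

# (display name used in med lists, lowercase narrative name)
_POSITIVE_SUPPLEMENTS = [
    "MELATONIN",
    "LACTOBACILLUS ACIDOPHILUS",
    "FOLIC ACID",
    "CALCIUM CARBONATE",
    "FISH OIL",
    "MULTIVITAMIN",
    "CHOLECALCIFEROL",
    "ERGOCALCIFEROL",
    "THIAMINE HCL",
    "CYANOCOBALAMIN",
    "MAGNESIUM OXIDE",
    "ZINC SULFATE",
    "POTASSIUM CHLORIDE",
    "VITAMIN D3",
    "VITAMIN B12",
    "VITAMIN C",
    "COENZYME Q10",
    "GINKGO BILOBA",
    "GLUCOSAMINE",
    "CHONDROITIN SULFATE",
    "CRANBERRY EXTRACT",
    "IRON",
    "GARLIC",
    "GINSENG",
    "TURMERIC",
    "FIBER PSYLLIUM",
    "SAW PALMETTO",
    "ECHINACEA",
    "GINGER ROOT",
    "BIOTIN",
    "DHEA",
    "NIACIN",
    "RIBOFLAVIN",
    "PYRIDOXINE",
    "GREEN TEA EXTRACT",
    "CREATINE MONOHYDRATE",
    "ALOE VERA GEL",
    "MILK THISTLE",
    "LICORICE ROOT",
    "ASTRAGALUS",
    "OREGANO OIL",
    "WILLOW BARK",
    "BREWERS YEAST",
    "KRILL OIL",
    "CINNAMON",
]

_ALLERGY_ITEMS = ["NIACIN", "THIAMINE", "FISH", "IRON", "ECHINACEA", "GINGER"]

_FILLERS = [
    "Patient seen in clinic today for routine follow up.",
    "Vital signs stable. No acute distress noted on exam.",
    "Plan reviewed with patient who voices understanding and agreement.",
    "Will return to clinic in three months or sooner as needed.",
    "Sleep and appetite reported as fair. Mood stable per patient.",
]


def _med_list(rng: random.Random) -> str:
    n_items = rng.randint(2, 3)
    parts = []
    start = rng.randint(1, 20)
    for j in range(n_items):
        name = rng.choice(_POSITIVE_SUPPLEMENTS)
        dose = rng.choice(_DOSES)
        form = rng.choice(_FORMS)
        freq = rng.choice(_FREQS)
        parts.append(
            f"({start + j}) {name} {dose}MG {form} ACTIVE Give: {dose}MG PO {freq}"
        )
    return " ".join(parts)


def _asterisk_list(rng: random.Random) -> str:
    n_items = rng.randint(2, 3)
    items = []
    for _ in range(n_items):
        name = rng.choice(_POSITIVE_SUPPLEMENTS).title()
        dose = rng.choice(_DOSES)
        freq = rng.choice(_FREQS).lower()
        items.append(f"{name} {dose} mg po {freq}")
    return "*" + "*".join(items) + "*"


def _narrative(rng: random.Random) -> str:
    name = rng.choice(_POSITIVE_SUPPLEMENTS).lower()
    template = rng.choice(
        [
            f"Patient reports taking {name} daily over the counter for general health.",
            f"Currently on {name} purchased at the health food store.",
            f"Has been using {name} at home and reports good effect.",
        ]
    )
    return template


def _allergy(rng: random.Random) -> str:
    item = rng.choice(_ALLERGY_ITEMS)
    other = rng.choice(["SULFA DRUGS", "PENICILLIN", "CODEINE"])
    return f"REVIEW OF SYSTEMS noncontributory. ALLERGIES: {other}, {item} NO KNOWN FOOD ALLERGIES"


def _lab_panel(rng: random.Random) -> str:
    def v(lo: float, hi: float) -> str:
        return f"{rng.uniform(lo, hi):.1f}"

    template = rng.choice(
        [
            f"Chemistry shows a glucose of {v(80, 200)}, chloride {v(95, 110)}, and normal"
            f" creatinine of {v(0.6, 1.4)}. Calcium is {v(8.0, 10.5)}. Albumin {v(3.0, 5.0)}.",
            f"BMP: Na {v(130, 145)} K {v(3.2, 5.2)} Cl {v(95, 110)} creatinine {v(0.6, 1.4)}"
            f" calcium {v(8.0, 10.5)} magnesium {v(1.5, 2.5)} all within normal limits.",
            f"Anemia workup: Fe {v(40, 160)} TIBC {v(250, 450)} ferritin {v(20, 300)}"
            f" B12 level pending at this time.",
        ]
    )
    return template


def _food(rng: random.Random) -> str:
    return rng.choice(
        [
            "Group shared a lunch of baked fish, mashed potatoes, and mixed vegetables.",
            "Advised clear liquids only, such as ginger ale, broth, and weak tea before the procedure.",
            "Dietary recall notable for fried fish sandwiches most weekends.",
        ]
    )


def _drug_name(rng: random.Random) -> str:
    dose = rng.choice(_DOSES)
    return rng.choice(
        [
            f"ATORVASTATIN CALCIUM {dose}MG TAB Give: {dose}MG PO QPM as directed.",
            f"DOCUSATE CALCIUM 240MG CAP Give: 1 CAP PO BID prn constipation.",
            "Problem list includes Iron Deficiency Anemia and gastroesophageal reflux.",
            "Attempted placement using the tapered flex tip on the catheter without success.",
            "Digitalis toxicity was ruled out on telemetry review.",
        ]
    )


_SECTION_BUILDERS: dict[str, Callable[[random.Random], str]] = {
    "med_list": _med_list,
    "asterisk_list": _asterisk_list,
    "narrative": _narrative,
    "allergy": _allergy,
    "lab_panel": _lab_panel,
    "food": _food,
    "drug_name": _drug_name,
}


_E_OCCURRENCES_CACHE: dict[tuple[str, frozenset], float] = {}


def _expected_occurrences(family: str, lexicon: Lexicon, n_samples: int = 400) -> float:
    """Expected keyword occurrences per section of one template family.

    Estimated once per family by rendering sections with a fixed private
    RNG and counting matcher hits; deterministic, and self-maintaining as
    templates evolve.
    """
    key = (family, lexicon.keywords)
    if key not in _E_OCCURRENCES_CACHE:
        rng = random.Random(12345)
        total = sum(
            len(match_keywords(tokenize(_SECTION_BUILDERS[family](rng)), lexicon))
            for _ in range(n_samples)
        )
        _E_OCCURRENCES_CACHE[key] = total / n_samples
    return _E_OCCURRENCES_CACHE[key]


def _section_positive_prob(config: GeneratorConfig, lexicon: Lexicon) -> float:
    """Section-level polarity probability such that the *occurrence*-level
    positive fraction equals config.positive_rate in expectation.

    Positive sections (med lists) carry more keyword occurrences than
    negative ones (a single allergy item), so the section draw is rescaled
    by the expected per-family yields.
    """
    r = config.positive_rate
    if r in (0.0, 1.0):
        return r

    def mean_yield(families: tuple[str, ...]) -> float:
        weights = [config.template_mix.get(f, 0.0) for f in families]
        total = sum(weights)
        if total <= 0:
            return 1.0
        return (
            sum(
                w * _expected_occurrences(f, lexicon)
                for f, w in zip(families, weights)
            )
            / total
        )

    e_pos = mean_yield(POSITIVE_FAMILIES)
    e_neg = mean_yield(NEGATIVE_FAMILIES)
    return r * e_neg / (r * e_neg + (1 - r) * e_pos)


def _pick_family(rng: random.Random, config: GeneratorConfig, positive: bool) -> str:
    families = POSITIVE_FAMILIES if positive else NEGATIVE_FAMILIES
    weights = [config.template_mix.get(f, 0.0) for f in families]
    if sum(weights) <= 0:
        raise ValueError(
            f"impossible config: no {'positive' if positive else 'negative'} templates enabled"
        )
    return rng.choices(list(families), weights=weights, k=1)[0]


def generate_corpus(
    config: GeneratorConfig, lexicon: Optional[Lexicon] = None
) -> SyntheticCorpus:
    """Emit notes, per-occurrence ground truth, and patient-level truth.

    Deterministic for a fixed config (same seed → byte-identical corpus).
    Every note is dated inside the survey roll-up window.  The generator
    verifies its own output against the keyword matcher, so templates can
    never emit unlabeled (accidental) keyword occurrences.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    rng = random.Random(config.seed)
    p_section = _section_positive_prob(config, lexicon)
    notes: list[NoteDocument] = []
    truth: list[GroundTruthObservation] = []
    patient_use: dict[str, frozenset[str]] = {}
    survey_dates: dict[str, _dt.date] = {}

    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        survey_dates[pid] = BASE_SURVEY_DATE
        positive_cats: set[str] = set()
        for _ in range(config.notes_per_patient):
            note_index = len(notes)
            sections: list[tuple[str, Optional[str]]] = []  # (text, polarity)
            n_keyword_sections = rng.randint(*config.sections_per_note)
            for _ in range(n_keyword_sections):
                positive = rng.random() < p_section
                family = _pick_family(rng, config, positive)
                text = _SECTION_BUILDERS[family](rng)
                sections.append((text, "yes" if positive else "no"))
                if config.include_fillers and rng.random() < 0.4:
                    sections.append((rng.choice(_FILLERS), None))
            note_text = "\n".join(s for s, _ in sections)
            # Per-section labels, concatenated in emission order
            labels: list[str] = []
            for text, polarity in sections:
                n_hits = len(match_keywords(tokenize(text), lexicon))
                if polarity is None and n_hits:
                    raise RuntimeError(f"filler line contains a keyword: {text!r}")
                labels.extend([polarity] * n_hits)  # type: ignore[list-item]
            matches = match_keywords(tokenize(note_text), lexicon)
            if len(matches) != len(labels):
                raise RuntimeError("template produced unaccounted keyword occurrences")
            offset = int(rng.random() * 396) - 365  # uniform in [-365, +30]
            note_date = survey_dates[pid] + _dt.timedelta(days=offset)
            notes.append(NoteDocument(pid, note_date, note_text))
            for occ, (m, label) in enumerate(zip(matches, labels)):
                truth.append(
                    GroundTruthObservation(
                        patient_id=pid,
                        note_index=note_index,
                        occurrence_index=occ,
                        keyword=m.keyword,
                        category=m.category,
                        label=label,
                    )
                )
                if label == "yes":
                    positive_cats.add(m.category)
        patient_use[pid] = frozenset(positive_cats)

    return SyntheticCorpus(
        notes=notes,
        observations=truth,
        patient_use=patient_use,
        survey_dates=survey_dates,
        config=config,
    )


def generate_survey(
    patient_use: dict[str, frozenset[str]],
    config: GeneratorConfig,
    categories: Optional[Sequence[str]] = None,
    survey_dates: Optional[dict[str, _dt.date]] = None,
) -> list[SurveyRecord]:
    """Self-report records derived from truth plus injected discordance.

    ``underreport_prescribed`` flips true→false for the prescribed-style
    categories only; ``overreport`` flips false→true for any category.
    Deterministic per config seed (independent of the corpus RNG stream).
    """
    if categories is None:
        categories = sorted(load_lexicon().categories)
    rng = random.Random(config.seed + 1)
    records: list[SurveyRecord] = []
    for pid in sorted(patient_use):
        date = (survey_dates or {}).get(pid, BASE_SURVEY_DATE)
        for category in categories:
            reported = category in patient_use[pid]
            if reported and category in config.prescribed_categories:
                if rng.random() < config.underreport_prescribed:
                    reported = False
            elif not reported and rng.random() < config.overreport:
                reported = True
            records.append(SurveyRecord(pid, date, category, reported))
    return records


def separable_fixture(
    n_observations: int = 1000,
    seed: int = 0,
    lexicon: Optional[Lexicon] = None,
) -> list[SnippetObservation]:
    """Labeled observations from a linearly separable corpus.

    Notes carry exactly one template section each, so no snippet window
    ever mixes positive and negative template text: every observation's
    context comes from a single family, whose stable bigrams (together
    with the keyword indicator) determine the label without noise.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    config = GeneratorConfig(
        n_patients=max(1, -(-n_observations // 6)),
        notes_per_patient=4,
        sections_per_note=(1, 1),
        include_fillers=False,
        seed=seed,
    )
    obs = generate_corpus(config, lexicon).labeled_observations(lexicon)
    if len(obs) < n_observations:
        raise RuntimeError("fixture under-generated; increase n_patients")
    return obs[:n_observations]


def oracle_predictions(
    observations: Sequence[SnippetObservation],
) -> list[tuple[str, str]]:
    """(category, label) pairs read straight from ground-truth labels —
    the perfect-classifier stand-in for pipeline identity checks."""
    out = []
    for obs in observations:
        if obs.label is None:
            raise ValueError("oracle requires labeled observations")
        out.append((obs.category, obs.label))
    return out
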