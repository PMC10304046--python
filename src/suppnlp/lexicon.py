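"""Keyword → supplement-category lexicon and token-level keyword matching.

The lexicon maps surface forms found in clinical notes (including common
misspellings and truncations such as ``creatinin`` or ``potasium``) to
canonical supplement categories.  Matching is case-insensitive whole-token
equality: ``CALCIUM`` inside ``ATORVASTATIN CALCIUM 40MG TAB`` *is* a match,
because deciding whether an occurrence indicates active supplement use is the
classifier's job, not the matcher's.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon files."""


@dataclass(frozen=True)
class LexiconEntry:
    """One lowercase keyword surface form and its supplement category."""

    keyword: str
    category: str

    def __post_init__(self) -> None:
        if not self.keyword or any(ch.isspace() for ch in self.keyword):
            raise LexiconError(f"invalid keyword {self.keyword!r}: empty or contains whitespace")
        if not self.category:
            raise LexiconError("empty category")


@dataclass(frozen=True)
class KeywordMatch:
    """A lexicon keyword occurring at ``token_index`` of a token sequence."""

    keyword: str
    token_index: int
    category: str


# Generic vitamin stems whose category is refined by the next token
# ("vitamin d" -> vitamin d3); everything else maps straight through.
VITAMIN_STEMS = frozenset(
    {"vit", "vita", "vits", "vitamin", "vitamine", "vitmain", "viamin", "viatmin"}
)

# Next-token refinements for the generic stems.  Unrecognised (or absent)
# following tokens fall back to the stem's own category, "multivitamin".
_VITAMIN_REFINEMENTS = {
    "a": "vitamin a",
    "b1": "thiamine",
    "b2": "vitamin b2",
    "b3": "vitamin b3",
    "b6": "vitamin b6",
    "b12": "vitamin b12",
    "c": "vitamin c",
    "d": "vitamin d3",
    "d2": "vitamin d2",
    "d3": "vitamin d3",
}


class Lexicon:
    """A validated set of :class:`LexiconEntry` plus the category universe."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        entries = list(entries)
        if not entries:
            raise LexiconError("empty lexicon")
        mapping: dict[str, str] = {}
        for e in entries:
            if e.keyword in mapping:
                raise LexiconError(f"duplicate keyword {e.keyword!r}")
            mapping[e.keyword] = e.category
        self._mapping = mapping
        self.entries = frozenset(entries)
        self.categories = frozenset(mapping.values())

    @property
    def keywords(self) -> frozenset[str]:
        return frozenset(self._mapping)

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, keyword: str) -> bool:
        return keyword in self._mapping

    def category_of(self, keyword: str) -> str:
        try:
            return self._mapping[keyword]
        except KeyError:
            raise LexiconError(f"unknown keyword {keyword!r}") from None


def default_lexicon_path() -> Path:
    """Path of the packaged lexicon table."""
    return Path(str(importlib.resources.files("suppnlp").joinpath("data/lexicon.tsv")))


def load_lexicon(
    path: str | Path | None = None, categories: Optional[Iterable[str]] = None
) -> Lexicon:
    """Load and validate a two-column ``keyword<TAB>category`` table.

    Parameters
    ----------
    path
        Lexicon file; ``None`` loads the packaged default (83 keywords
        spanning 44 supplement categories).
    categories
        Optional closed category universe; entries mapping outside it are
        rejected.

    Raises
    ------
    LexiconError
        On malformed rows (with line number), duplicate keywords, a keyword
        mapped outside the category universe, or an empty table.
    """
    allowed = None if categories is None else {c.casefold() for c in categories}
    if path is None:
        path = default_lexicon_path()
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise LexiconError(f"{path}:{lineno}: malformed row {line!r}")
            keyword, category = parts[0].strip().casefold(), parts[1].strip().casefold()
            if lineno == 1 and (keyword, category) == ("keyword", "category"):
                continue  # header
            if allowed is not None and category not in allowed:
                raise LexiconError(f"{path}:{lineno}: unknown category {category!r}")
            if any(e.keyword == keyword for e in entries):
                raise LexiconError(f"{path}:{lineno}: duplicate keyword {keyword!r}")
            entries.append(LexiconEntry(keyword, category))
    return Lexicon(entries)


def match_keywords(tokens: Sequence[str], lexicon: Lexicon) -> list[KeywordMatch]:
    """Whole-token, case-insensitive keyword scan.

    Returns one :class:`KeywordMatch` per token whose case-folded form equals
    a lexicon keyword, ordered by token index.  Substring hits never match;
    disambiguation of non-use contexts (labs, allergies, drug names) is left
    to the downstream classifier.
    """
    out: list[KeywordMatch] = []
    for i, tok in enumerate(tokens):
        folded = tok.casefold()
        if folded in lexicon:
            category = keyword_to_category(
                folded,
                tokens[i + 1].casefold() if i + 1 < len(tokens) else None,
                lexicon,
            )
            out.append(KeywordMatch(keyword=folded, token_index=i, category=category))
    return out


def keyword_to_category(
    keyword: str, following_token: Optional[str] = None, lexicon: Lexicon | None = None
) -> str:
    """Resolve a keyword occurrence to its supplement category.

    Generic vitamin stems (``vit``, ``vitamin`` ...) are refined by a
    one-token lookahead — ``vitamin d`` resolves to ``vitamin d3`` — and fall
    back to ``multivitamin`` when the next token is unrecognised.
    """
    if lexicon is None:
        lexicon = load_lexicon()
    base = lexicon.category_of(keyword)
    if keyword in VITAMIN_STEMS and following_token is not None:
        return _VITAMIN_REFINEMENTS.get(following_token.casefold(), base)
    return base
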