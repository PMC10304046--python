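"""Tokenisation and keyword-centred snippet extraction.

Clinical notes are often semi-structured — numbered active-medication lists,
asterisk-delimited med runs, all-caps allergy lines — and sentence splitting
is unreliable on them.  The unit of context here is therefore a fixed window
of +/-20 tokens around each matched keyword.  Punctuation is kept as tokens
(an ``*`` or ``(14)`` is real signal in these notes), with a small set of
intra-word exceptions so that ``CAP/TAB``, ``QID-INSULIN`` and ``0.97``
survive as single tokens.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .lexicon import KeywordMatch, Lexicon, match_keywords

DEFAULT_WINDOW = 20


@dataclass(frozen=True)
class NoteDocument:
    """One clinical note: patient, date, free text."""

    patient_id: str
    note_date: _dt.date
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("note text must be non-empty")
        if not isinstance(self.note_date, _dt.date):
            raise TypeError("note_date must be a datetime.date")


@dataclass(frozen=True)
class Snippet:
    """A keyword occurrence with its clamped +/-window token context.

    ``anchor_index`` is the anchor's position in the *document* token
    sequence; ``keyword_matches`` hold indices relative to ``tokens``.
    """

    source: NoteDocument
    anchor_index: int
    tokens: tuple[str, ...]
    keyword_matches: tuple[KeywordMatch, ...]

    @property
    def anchor_match(self) -> KeywordMatch:
        """The match this snippet is centred on."""
        for m in self.keyword_matches:
            if m.token_index == self._anchor_offset:
                return m
        raise ValueError("anchor keyword missing from keyword_matches")

    @property
    def _anchor_offset(self) -> int:
        return self.anchor_index - self.window_start

    @property
    def window_start(self) -> int:
        return max(0, self.anchor_index - self._window)

    # window size recovered from the clamp geometry is ambiguous, so carry it
    _window: int = field(default=DEFAULT_WINDOW, compare=False)


@dataclass
class SnippetObservation:
    """One (snippet, keyword occurrence) pair — the unit of classification."""

    snippet: Snippet
    keyword_match: KeywordMatch
    label: Optional[str] = None  # "yes" / "no" / None

    @property
    def keyword(self) -> str:
        return self.keyword_match.keyword

    @property
    def category(self) -> str:
        return self.keyword_match.category

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.snippet.tokens


_INTRAWORD = {"/", "-"}


def _is_alnum(ch: str) -> bool:
    return ch.isalnum()


def tokenize(text: str) -> list[str]:
    """Split text into tokens, preserving structural punctuation.

    Rules: whitespace runs separate tokens; every punctuation character
    becomes its own token except ``/`` and ``-`` between alphanumerics and
    ``.`` between digits, which stay inside the word.  Original casing is
    preserved; callers case-fold for matching.  Joining the output with
    single spaces and re-tokenising reproduces the same token sequence.
    """
    tokens: list[str] = []
    for chunk in text.split():
        buf: list[str] = []
        n = len(chunk)
        for i, ch in enumerate(chunk):
            if _is_alnum(ch):
                buf.append(ch)
                continue
            prev_ok = bool(buf) and _is_alnum(buf[-1])
            nxt = chunk[i + 1] if i + 1 < n else ""
            if ch in _INTRAWORD and prev_ok and _is_alnum(nxt):
                buf.append(ch)
            elif ch == "." and buf and buf[-1].isdigit() and nxt.isdigit():
                buf.append(ch)
            else:
                if buf:
                    tokens.append("".join(buf))
                    buf = []
                tokens.append(ch)
        if buf:
            tokens.append("".join(buf))
    return tokens


def extract_snippets(
    doc: NoteDocument, lexicon: Lexicon, window: int = DEFAULT_WINDOW
) -> list[Snippet]:
    """One snippet per keyword occurrence, window clamped at note edges.

    Nearby keywords yield overlapping snippets; each occurrence is its own
    anchor.  Output is ordered by anchor position and fully deterministic.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    doc_tokens = tokenize(doc.text)
    doc_matches = match_keywords(doc_tokens, lexicon)
    snippets: list[Snippet] = []
    for anchor in doc_matches:
        start = max(0, anchor.token_index - window)
        stop = min(len(doc_tokens), anchor.token_index + window + 1)
        window_tokens = tuple(doc_tokens[start:stop])
        local = tuple(
            KeywordMatch(m.keyword, m.token_index - start, m.category)
            for m in doc_matches
            if start <= m.token_index < stop
        )
        snippets.append(
            Snippet(
                source=doc,
                anchor_index=anchor.token_index,
                tokens=window_tokens,
                keyword_matches=local,
                _window=window,
            )
        )
    return snippets


def snippet_to_observations(snippet: Snippet) -> list[SnippetObservation]:
    """Every keyword in the snippet window is a separate observation."""
    return [SnippetObservation(snippet, m) for m in snippet.keyword_matches]


def corpus_observations(
    notes: Iterable[NoteDocument], lexicon: Lexicon, window: int = DEFAULT_WINDOW
) -> list[SnippetObservation]:
    """Extract snippets from every note, anchored per occurrence, and emit
    one observation per anchor.

    Each keyword occurrence appears exactly once as an anchored observation,
    so the total equals the corpus-wide keyword occurrence count.
    """
    out: list[SnippetObservation] = []
    for doc in notes:
        for sn in extract_snippets(doc, lexicon, window=window):
            out.append(SnippetObservation(sn, sn.anchor_match))
    return out


# ---------------------------------------------------------------------------
# JSON-lines corpus I/O

def write_notes_jsonl(notes: Iterable[NoteDocument], path: str | Path) -> int:
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in notes:
            fh.write(
                json.dumps(
                    {
                        "patient_id": doc.patient_id,
                        "note_date": doc.note_date.isoformat(),
                        "text": doc.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


def read_notes_jsonl(path: str | Path) -> Iterator[NoteDocument]:
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            yield NoteDocument(
                patient_id=str(rec["patient_id"]),
                note_date=_dt.date.fromisoformat(rec["note_date"]),
                text=rec["text"],
            )
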