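"""Terminology model and a deterministic phrase-prediction engine.

A *terminology* is a closed list of selectable clinical labels (e.g. a
hospital problem list), each with a canonical text and optional synonyms
("avc" for "accident vasculaire cérébral").  The *completion engine* maps a
partial typed query to a ranked, repetition-free list of candidate labels,
the way a type-ahead widget would.

The matching semantics implemented here are a documented, deterministic
stand-in for a production autocomplete ranker: a label is a candidate when
every query token is a prefix of some word of the label text (canonical or
synonym), or when the query occurs verbatim inside it.  Exact matches
outrank word-prefix matches, which outrank substring-only matches; ties are
broken by shorter canonical text, then by label id.  All downstream
analyses only require the engine to be a fixed function from queries to
ranked label lists.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Alphabet",
    "DEFAULT_ALPHABET",
    "Label",
    "Terminology",
    "CompletionResult",
    "CompletionEngine",
    "normalize",
    "string_space_size",
    "complete",
    "rank_of",
    "load_terminology",
    "save_terminology",
]

#: Default query alphabet: 26 lowercase letters, 10 digits and the space
#: character (37 symbols).  Accented characters are folded onto their base
#: letter by :func:`normalize` before matching.
DEFAULT_SYMBOLS = "abcdefghijklmnopqrstuvwxyz0123456789 "

#: Default cap on the length of a suggestion list.
DEFAULT_J = 30


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of characters queries may be written in."""

    symbols: str = DEFAULT_SYMBOLS

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("alphabet must be non-empty")
        if " " not in self.symbols:
            raise ValueError("alphabet must contain the space character")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet contains duplicate symbols")
        object.__setattr__(self, "_charset", frozenset(self.symbols))

    def __contains__(self, ch: str) -> bool:
        return ch in self._charset  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.symbols)


DEFAULT_ALPHABET = Alphabet()


def normalize(text: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    """Project arbitrary text onto the query alphabet.

    Lowercases, folds accented characters onto their base character
    (é→e, ç→c, …), maps all whitespace to plain spaces, drops every
    character outside the alphabet, collapses runs of spaces and strips
    the ends.  The result may be empty.
    """
    decomposed = unicodedata.normalize("NFKD", text.lower())
    out = []
    for ch in decomposed:
        if unicodedata.combining(ch):
            continue
        if ch.isspace():
            ch = " "
        if ch in alphabet:
            out.append(ch)
    return " ".join("".join(out).split())


def string_space_size(alphabet: Alphabet, L: int) -> int:
    """Number of non-empty strings over ``alphabet`` of length at most ``L``.

    Equals ``sum(|A|**i for i in 1..L)``, i.e. the geometric closed form
    ``(|A|**(L+1) - |A|) / (|A| - 1)`` for ``|A| > 1``.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    base = len(alphabet)
    if base == 1:
        return L
    return (base ** (L + 1) - base) // (base - 1)


@dataclass(frozen=True)
class Label:
    """One selectable expression of the terminology."""

    label_id: int
    canonical_text: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label_id <= 0:
            raise ValueError("label_id must be a positive integer")
        if not normalize(self.canonical_text):
            raise ValueError(
                f"label {self.label_id}: canonical text empty after normalization"
            )
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


@dataclass(frozen=True)
class Terminology:
    """A closed list of labels; ``L`` is the longest normalized label length."""

    labels: tuple[Label, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise ValueError("terminology must contain at least one label")
        ids = [lab.label_id for lab in self.labels]
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")

    @property
    def L(self) -> int:
        return max(len(normalize(lab.canonical_text)) for lab in self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def get(self, label_id: int) -> Label:
        for lab in self.labels:
            if lab.label_id == label_id:
                return lab
        raise ValueError(f"unknown label_id {label_id}")

    @property
    def ids(self) -> frozenset[int]:
        return frozenset(lab.label_id for lab in self.labels)


@dataclass(frozen=True)
class CompletionResult:
    """Ranked, repetition-free label suggestions for one query.

    ``ranked_ids[0]`` is rank 1.  ``J`` is the cap the list was truncated
    to (``None`` for an uncapped candidate list).
    """

    ranked_ids: tuple[int, ...]
    J: Optional[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranked_ids", tuple(self.ranked_ids))
        if len(set(self.ranked_ids)) != len(self.ranked_ids):
            raise ValueError("suggestion list repeats a label")
        if self.J is not None and len(self.ranked_ids) > self.J:
            raise ValueError("suggestion list longer than its cap")

    def rank(self, label_id: int) -> Optional[int]:
        try:
            return self.ranked_ids.index(label_id) + 1
        except ValueError:
            return None

    def __len__(self) -> int:
        return len(self.ranked_ids)


# Match scores, higher is better.
_EXACT, _WORD_PREFIX, _SUBSTRING = 3, 2, 1


class CompletionEngine:
    """Deterministic completion over a fixed terminology, with caching.

    Matching per label, evaluated on the normalized canonical text and on
    each normalized synonym:

    * exact: the query equals the text;
    * word-prefix: every space-separated query token is a prefix of some
      word of the text;
    * substring: the query is a contiguous substring of the text.

    Candidates are ordered by best score (exact > word-prefix > substring),
    then by shorter normalized canonical text, then by ascending label id.
    Results are memoised per normalized query, so bulk pipelines (log
    enrichment, Pareto-front construction, simulation) pay the label scan
    once per distinct query.
    """

    def __init__(
        self,
        terminology: Terminology,
        alphabet: Alphabet = DEFAULT_ALPHABET,
        J: int = DEFAULT_J,
    ) -> None:
        if J is not None and J < 1:
            raise ValueError("J must be a positive integer")
        self.terminology = terminology
        self.alphabet = alphabet
        self.J = J
        self._cache: dict[str, tuple[int, ...]] = {}
        self._rank_cache: dict[str, dict[int, int]] = {}
        # Precompute normalized variants once per label.
        self._index: list[tuple[int, int, str, tuple[tuple[str, tuple[str, ...]], ...]]] = []
        for lab in terminology:
            canon = normalize(lab.canonical_text, alphabet)
            variants = [canon] + [
                s for s in (normalize(sy, alphabet) for sy in lab.synonyms) if s
            ]
            packed = tuple((v, tuple(v.split())) for v in variants)
            self._index.append((lab.label_id, len(canon), canon, packed))

    @staticmethod
    def _score(query: str, tokens: tuple[str, ...], variants) -> int:
        best = 0
        for text, words in variants:
            if query == text:
                return _EXACT
            if best < _WORD_PREFIX and all(
                any(w.startswith(tok) for w in words) for tok in tokens
            ):
                best = _WORD_PREFIX
            elif best < _SUBSTRING and query in text:
                best = _SUBSTRING
        return best

    def _ranked_ids(self, query: str) -> tuple[int, ...]:
        """Full (uncapped) ranked candidate list for a normalized query."""
        hit = self._cache.get(query)
        if hit is not None:
            return hit
        tokens = tuple(query.split())
        scored = []
        for label_id, canon_len, _canon, variants in self._index:
            s = self._score(query, tokens, variants)
            if s:
                scored.append((-s, canon_len, label_id))
        scored.sort()
        ranked = tuple(lid for _neg, _len, lid in scored)
        self._cache[query] = ranked
        self._rank_cache[query] = {lid: i + 1 for i, lid in enumerate(ranked)}
        return ranked

    def complete(self, query: str, J: Optional[int] = -1) -> CompletionResult:
        """Ranked suggestions for ``query``; ``J=None`` disables the cap."""
        if J == -1:
            J = self.J
        q = normalize(query, self.alphabet)
        if not q:
            raise ValueError("query is empty after normalization")
        ranked = self._ranked_ids(q)
        if J is not None:
            ranked = ranked[:J]
        return CompletionResult(ranked_ids=ranked, J=J)

    def rank_of(self, label_id: int, query: str, J: Optional[int] = -1) -> Optional[int]:
        """1-based rank of ``label_id`` for ``query``, or ``None`` beyond the cap."""
        if J == -1:
            J = self.J
        if label_id not in self.terminology.ids:
            raise ValueError(f"unknown label_id {label_id}")
        q = normalize(query, self.alphabet)
        if not q:
            raise ValueError("query is empty after normalization")
        self._ranked_ids(q)
        r = self._rank_cache[q].get(label_id)
        if r is None or (J is not None and r > J):
            return None
        return r


def complete(
    query: str,
    terminology: Terminology,
    J: Optional[int] = DEFAULT_J,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> CompletionResult:
    """One-shot completion; build a :class:`CompletionEngine` for bulk use."""
    return CompletionEngine(terminology, alphabet=alphabet, J=J).complete(query, J=J)


def rank_of(
    label_id: int,
    query: str,
    terminology: Terminology,
    J: Optional[int] = DEFAULT_J,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> Optional[int]:
    """One-shot rank lookup; ``None`` when the label is not within the cap."""
    return CompletionEngine(terminology, alphabet=alphabet, J=J).rank_of(
        label_id, query, J=J
    )


# ---------------------------------------------------------------------------
# File formats: CSV with pipe-separated synonyms, or a JSON list.

def load_terminology(path: str | Path) -> Terminology:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        labels = [
            Label(int(d["id"]), d["text"], tuple(d.get("synonyms", ())))
            for d in data
        ]
        return Terminology(tuple(labels))
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    labels = [
        Label(
            int(r["label_id"]),
            r["canonical_text"],
            tuple(s for s in r.get("synonyms", "").split("|") if s),
        )
        for r in rows
    ]
    return Terminology(tuple(labels))


def save_terminology(terminology: Terminology, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = [
            {"id": lab.label_id, "text": lab.canonical_text, "synonyms": list(lab.synonyms)}
            for lab in terminology
        ]
        path.write_text(json.dumps(data, ensure_ascii=False, indent=1), encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label_id", "canonical_text", "synonyms"])
        for lab in terminology:
            writer.writerow([lab.label_id, lab.canonical_text, "|".join(lab.synonyms)])
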