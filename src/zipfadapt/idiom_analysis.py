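"""Tracking of medical-jargon expressions (acronyms/abbreviations) in logs.

Clinicians often query a phrase-prediction tool with jargon such as "hta"
(hypertension artérielle) or "bpco" (the French COPD).  Given a curated
lexicon of such expressions, this module measures how their use evolves
with user-label seniority and produces per-label case-study tables
(which queries were used in early vs. late selections of one label).

Idiom membership is exact-match after normalization: lexicon entries are
standalone queries, not substrings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .terminology_completion import (
    Alphabet,
    CompletionEngine,
    DEFAULT_ALPHABET,
    normalize,
)

__all__ = [
    "IdiomLexicon",
    "is_idiom",
    "labels_with_idiom_queries",
    "idiom_proportion_by_seniority",
    "query_case_study",
    "top_idioms",
]


@dataclass(frozen=True)
class IdiomLexicon:
    """A set of normalized jargon expressions."""

    expressions: frozenset[str]

    def __post_init__(self) -> None:
        if any(not e for e in self.expressions):
            raise ValueError("lexicon contains an empty expression")

    @classmethod
    def from_strings(
        cls, expressions: Iterable[str], alphabet: Alphabet = DEFAULT_ALPHABET
    ) -> "IdiomLexicon":
        norm = {normalize(e, alphabet) for e in expressions}
        norm.discard("")
        return cls(frozenset(norm))

    @classmethod
    def load(cls, path: str | Path) -> "IdiomLexicon":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_strings(line for line in lines if line.strip())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "\n".join(sorted(self.expressions)) + "\n", encoding="utf-8"
        )

    def __contains__(self, expression: str) -> bool:
        return expression in self.expressions

    def __len__(self) -> int:
        return len(self.expressions)


def is_idiom(
    query: str, lexicon: IdiomLexicon, alphabet: Alphabet = DEFAULT_ALPHABET
) -> bool:
    """True iff the normalized query is exactly a lexicon expression."""
    return normalize(query, alphabet) in lexicon


def _idiom_mask(df: pd.DataFrame, lexicon: IdiomLexicon) -> pd.Series:
    normalized = df["query"].map(lambda q: normalize(q))
    return normalized.isin(lexicon.expressions)


def labels_with_idiom_queries(df: pd.DataFrame, lexicon: IdiomLexicon) -> set[int]:
    """Labels having at least one record whose query is an idiom."""
    mask = _idiom_mask(df, lexicon)
    return set(df.loc[mask, "label_id"].unique().tolist())


def idiom_proportion_by_seniority(
    df: pd.DataFrame,
    lexicon: IdiomLexicon,
    s_cap: int,
    restrict: bool = True,
) -> pd.DataFrame:
    """Per-seniority-level idiom share among labels that ever used an idiom.

    Returns a frame with columns ``level``, ``n`` (total records at the
    level — the activity count), ``n_idiom`` and ``proportion``.  Levels in
    1..``s_cap`` with no records are omitted (gaps, not interpolated).
    When ``restrict`` is true (default) the log is first narrowed to
    labels returned by :func:`labels_with_idiom_queries`.
    """
    if s_cap < 1:
        raise ValueError("s_cap must be >= 1")
    work = df
    if restrict:
        keep = labels_with_idiom_queries(df, lexicon)
        work = df[df["label_id"].isin(keep)]
    work = work[work["seniority"] <= s_cap]
    if work.empty:
        return pd.DataFrame(columns=["level", "n", "n_idiom", "proportion"])
    mask = _idiom_mask(work, lexicon)
    grouped = (
        pd.DataFrame({"level": work["seniority"], "idiom": mask})
        .groupby("level")["idiom"]
        .agg(n="size", n_idiom="sum")
        .reset_index()
    )
    grouped["proportion"] = grouped["n_idiom"] / grouped["n"]
    return grouped


def _zone_labels(n_zones: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n_zones)]


def query_case_study(
    df: pd.DataFrame,
    label_id: int,
    zone_boundaries: Sequence[int],
    lexicon: IdiomLexicon,
    engine: Optional[CompletionEngine] = None,
) -> pd.DataFrame:
    """Per-zone query statistics for one label.

    ``zone_boundaries`` are strictly increasing seniority cut points: with
    ``[5, 10]`` the zones are A = levels 1–5, B = 6–10, C = 11+.  Within
    each zone, queries are sorted by count descending, ties alphabetical.
    When an ``engine`` is given, each query's current rank of the label is
    reported (NaN when outside the suggestion cap).
    """
    if label_id not in set(df["label_id"].unique()):
        raise ValueError(f"label {label_id} not present in the log")
    bounds = list(zone_boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or (
        bounds and bounds[0] < 1
    ):
        raise ValueError("zone boundaries must be strictly increasing and >= 1")
    sub = df[df["label_id"] == label_id]
    edges = [0] + bounds + [float("inf")]
    names = _zone_labels(len(edges) - 1)
    rows = []
    for zone, lo, hi in zip(names, edges[:-1], edges[1:]):
        zdf = sub[(sub["seniority"] > lo) & (sub["seniority"] <= hi)]
        if zdf.empty:
            continue
        counts = (
            zdf.groupby("query")
            .size()
            .reset_index(name="count")
            .sort_values(["count", "query"], ascending=[False, True])
        )
        for _, r in counts.iterrows():
            rank = (
                engine.rank_of(label_id, r["query"]) if engine is not None else None
            )
            rows.append(
                {
                    "zone": zone,
                    "query": r["query"],
                    "count": int(r["count"]),
                    "is_idiom": is_idiom(r["query"], lexicon),
                    "current_rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=["zone", "query", "count", "is_idiom", "current_rank"])


def top_idioms(df: pd.DataFrame, lexicon: IdiomLexicon, n: int = 30) -> pd.DataFrame:
    """The ``n`` most used idiom expressions with their modal selected label.

    Columns: ``expression``, ``occurrences``, ``top_label`` (the label most
    often selected with that expression; ties broken by smaller label id).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    normalized = df["query"].map(lambda q: normalize(q))
    work = pd.DataFrame({"expression": normalized, "label_id": df["label_id"]})
    work = work[work["expression"].isin(lexicon.expressions)]
    if work.empty:
        return pd.DataFrame(columns=["expression", "occurrences", "top_label"])
    rows = []
    for expr, grp in work.groupby("expression"):
        by_label = grp.groupby("label_id").size()
        top_label = by_label.sort_index().sort_values(kind="stable", ascending=False).index[0]
        rows.append(
            {"expression": expr, "occurrences": len(grp), "top_label": int(top_label)}
        )
    out = pd.DataFrame(rows).sort_values(
        ["occurrences", "expression"], ascending=[False, True]
    )
    return out.head(n).reset_index(drop=True)
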