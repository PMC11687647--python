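"""Two-objective Pareto optimisation of empirical queries, per target label.

For a target label *t*, every query observed anywhere in the log (the
empirical query space ℙ*) that retrieves *t* within the suggestion cap
defines a point (k, j): its length and the rank of *t*.  Both objectives
are minimised — short queries are concise, top ranks are distinctive —
and the non-dominated points form the label's Pareto front.  The
Euclidean distance from an interaction's (QLen, Rank) point to its
nearest front member measures how far that interaction sits from the
conciseness/distinctiveness optimum.

Distances are computed on raw units (characters × rank positions) by
default; a min–max normalized variant is available and reported
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .terminology_completion import (
    Alphabet,
    CompletionEngine,
    DEFAULT_ALPHABET,
    Terminology,
    normalize,
)

__all__ = [
    "QueryPoint",
    "ParetoFront",
    "empirical_queries",
    "feasible_points",
    "pareto_front",
    "extreme_optima",
    "distance_to_front",
    "compute_fronts",
    "annotate_distance",
    "fronts_to_frame",
]


class QueryPoint(NamedTuple):
    """A query with its two objective values for some target label."""

    query: str
    k: int  # query length (conciseness objective)
    j: int  # rank of the target label (distinctiveness objective)


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated query points for one label, k ascending / j strictly falling."""

    label_id: int
    points: tuple[QueryPoint, ...]

    def __post_init__(self) -> None:
        ks = [p.k for p in self.points]
        js = [p.j for p in self.points]
        if ks != sorted(ks) or any(b >= a for a, b in zip(js, js[1:])):
            raise ValueError("front must have k ascending and j strictly decreasing")
        if not self.points:
            raise ValueError("front must be non-empty")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def empirical_queries(
    df: pd.DataFrame, alphabet: Alphabet = DEFAULT_ALPHABET
) -> list[str]:
    """Distinct normalized queries observed at least once in the log (ℙ*)."""
    seen = {normalize(str(q), alphabet) for q in df["query"]}
    seen.discard("")
    return sorted(seen)


def feasible_points(
    queries: Iterable[str],
    label_id: int,
    engine: CompletionEngine,
    J: Optional[int] = -1,
) -> list[QueryPoint]:
    """Points (query, k, j) for every query that retrieves ``label_id`` in top J."""
    if label_id not in engine.terminology.ids:
        raise ValueError(f"unknown label_id {label_id}")
    points = []
    for q in queries:
        nq = normalize(q, engine.alphabet)
        if not nq:
            continue
        j = engine.rank_of(label_id, nq, J=J)
        if j is not None:
            points.append(QueryPoint(nq, len(nq), j))
    return points


def pareto_front(
    points: Sequence[QueryPoint], label_id: int = 0
) -> ParetoFront:
    """Non-dominated subset under simultaneous minimisation of (k, j).

    Point a dominates b iff a.k ≤ b.k and a.j ≤ b.j with at least one
    strict.  Duplicate (k, j) pairs keep the lexicographically smallest
    query.
    """
    if not points:
        raise ValueError("cannot build a Pareto front from no points")
    best_query: dict[tuple[int, int], str] = {}
    for p in points:
        key = (p.k, p.j)
        if key not in best_query or p.query < best_query[key]:
            best_query[key] = p.query
    ordered = sorted((k, j, q) for (k, j), q in best_query.items())
    front: list[QueryPoint] = []
    best_j = math.inf
    for k, j, q in ordered:
        if j < best_j:
            front.append(QueryPoint(q, k, j))
            best_j = j
    return ParetoFront(label_id=label_id, points=tuple(front))


def extreme_optima(points: Sequence[QueryPoint]) -> tuple[QueryPoint, QueryPoint]:
    """The two arms of the optimum: shortest feasible query and best-rank query.

    The first minimises k (ties: smaller j, then query); the second
    minimises j (ties: smaller k, then query).  Both always lie on the
    Pareto front of ``points``.
    """
    if not points:
        raise ValueError("no points")
    shortest = min(points, key=lambda p: (p.k, p.j, p.query))
    best_rank = min(points, key=lambda p: (p.j, p.k, p.query))
    return shortest, best_rank


def distance_to_front(
    point: tuple[float, float],
    front: ParetoFront,
    normalized: bool = False,
) -> float:
    """Euclidean distance from (k, j) to the nearest front member.

    With ``normalized=True`` each axis is scaled by the front's span on
    that axis (span 0 → scale 1) before measuring.
    """
    if not front.points:
        raise ValueError("front is empty")
    k, j = point
    if normalized:
        ks = [p.k for p in front.points]
        js = [p.j for p in front.points]
        sk = (max(ks) - min(ks)) or 1.0
        sj = (max(js) - min(js)) or 1.0
    else:
        sk = sj = 1.0
    return min(
        math.hypot((k - p.k) / sk, (j - p.j) / sj) for p in front.points
    )


def compute_fronts(
    df: pd.DataFrame,
    engine: CompletionEngine,
    J: Optional[int] = -1,
    per_label_queries: bool = False,
) -> dict[int, ParetoFront]:
    """Pareto fronts for every label selected in the log.

    The empirical query space is global (all queries observed anywhere)
    with per-label feasibility filtering.  ``per_label_queries=True``
    restricts each label's candidate queries to those used when that
    label was selected (a stricter sensitivity variant).
    """
    if J == -1:
        J = engine.J
    targets = sorted(int(l) for l in df["label_id"].unique())
    buckets: dict[int, list[QueryPoint]] = {t: [] for t in targets}
    target_set = set(targets)
    if per_label_queries:
        allowed: dict[int, set[str]] = {t: set() for t in targets}
        for q, l in zip(df["query"], df["label_id"]):
            allowed[int(l)].add(normalize(str(q), engine.alphabet))
    for q in empirical_queries(df, engine.alphabet):
        ranked = engine.complete(q, J=J).ranked_ids
        for pos, lid in enumerate(ranked, start=1):
            if lid in target_set:
                if per_label_queries and q not in allowed[lid]:
                    continue
                buckets[lid].append(QueryPoint(q, len(q), pos))
    return {
        t: pareto_front(pts, label_id=t) for t, pts in buckets.items() if pts
    }


def annotate_distance(
    df: pd.DataFrame,
    fronts: dict[int, ParetoFront],
    normalized: bool = False,
    column: str = "distance",
) -> pd.DataFrame:
    """Append each record's distance from its label's front.

    Uses the record's (qlen, rank) point; records with no rank (infeasible)
    or whose label has no front get NaN.
    """
    out = df.copy()
    cache: dict[tuple[int, float, float], float] = {}
    values = []
    for lid, k, j in zip(out["label_id"], out["qlen"], out["rank"]):
        if pd.isna(j) or int(lid) not in fronts:
            values.append(math.nan)
            continue
        key = (int(lid), float(k), float(j))
        if key not in cache:
            cache[key] = distance_to_front(
                (float(k), float(j)), fronts[int(lid)], normalized=normalized
            )
        values.append(cache[key])
    out[column] = values
    return out


def fronts_to_frame(fronts: dict[int, ParetoFront]) -> pd.DataFrame:
    """Tidy per-label front table (label_id, query, k, j)."""
    rows = [
        (lid, p.query, p.k, p.j)
        for lid in sorted(fronts)
        for p in fronts[lid].points
    ]
    return pd.DataFrame(rows, columns=["label_id", "query", "k", "j"])
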