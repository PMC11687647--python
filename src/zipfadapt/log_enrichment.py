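"""Derived features of a raw interaction log: QLen, seniority, Rank.

A raw log row records (user, query, selected label id, timestamp).  Three
features drive all downstream analyses:

* **QLen** — raw character count of the query, spaces included;
* **user-label seniority** — how many times this user has selected this
  label so far (1 for the first interaction, +1 each repeat): the
  pseudo-time axis of user adaptation;
* **Rank** — the 1-based position of the selected label in the
  suggestion list the completion engine returns for the query.  Records
  whose label is not retrievable within the cap are flagged infeasible,
  never silently dropped.

Logs are held as pandas DataFrames with columns
``user, query, label_id, timestamp`` (plus the enrichment columns).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .synthetic_data import InteractionRecord
from .terminology_completion import CompletionEngine, Terminology

logger = logging.getLogger(__name__)

__all__ = [
    "LOG_COLUMNS",
    "ENRICHED_COLUMNS",
    "qlen",
    "records_to_frame",
    "assign_seniority",
    "annotate_qlen",
    "annotate_rank",
    "enrich",
    "read_log",
    "write_log",
]

LOG_COLUMNS = ["user", "query", "label_id", "timestamp"]
ENRICHED_COLUMNS = LOG_COLUMNS + ["rank", "qlen", "seniority", "infeasible"]


def qlen(query: str) -> int:
    """Character count of the raw query, spaces included."""
    if not query:
        raise ValueError("query must be non-empty")
    return len(query)


def records_to_frame(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    """Simulator records -> raw log frame (ticks become timestamps)."""
    rows = [(r.user, r.query, r.label_id, r.tick) for r in records]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _validated(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"log is missing columns {missing}")
    bad = df.index[df["query"].astype(str).str.len() == 0]
    if len(bad):
        raise ValueError(f"empty query at row {bad[0]}")
    return df


def assign_seniority(
    df: pd.DataFrame,
    initial: Optional[Mapping[tuple[str, int], int]] = None,
) -> pd.DataFrame:
    """Fill the ``seniority`` column.

    Records are ordered chronologically (stable on timestamp ties); each
    (user, label) pair's records then count ``start, start+1, …`` where
    ``start`` comes from ``initial`` (default 1) — useful when a log
    continues an earlier one.  The returned frame is in chronological
    order.
    """
    df = _validated(df).sort_values("timestamp", kind="stable").reset_index(drop=True)
    counts = df.groupby(["user", "label_id"], sort=False).cumcount()
    if initial:
        starts = pd.Series(
            [initial.get((u, l), 1) for u, l in zip(df["user"], df["label_id"])],
            index=df.index,
        )
    else:
        starts = 1
    out = df.copy()
    out["seniority"] = counts + starts
    return out


def annotate_qlen(df: pd.DataFrame) -> pd.DataFrame:
    out = _validated(df).copy()
    out["qlen"] = out["query"].astype(str).str.len()
    return out


def annotate_rank(
    df: pd.DataFrame,
    terminology: Terminology,
    J: int = 30,
    engine: Optional[CompletionEngine] = None,
    recompute: bool = True,
) -> pd.DataFrame:
    """Fill ``rank`` (nullable) and ``infeasible`` columns.

    Ranks are recomputed by the completion engine from each record's
    query.  With ``recompute=False`` an existing ``rank`` column (a log
    that recorded the historical rank at selection time) is kept and only
    validated.  Unknown label ids are an error.
    """
    df = _validated(df)
    unknown = set(df["label_id"].unique()) - set(terminology.ids)
    if unknown:
        raise ValueError(f"log references unknown label ids {sorted(unknown)[:5]}")
    out = df.copy()
    if not recompute:
        if "rank" not in out.columns:
            raise ValueError("recompute=False requires a recorded rank column")
        out["rank"] = out["rank"].astype("Int64")
        out["infeasible"] = out["rank"].isna()
        return out
    if engine is None:
        engine = CompletionEngine(terminology, J=J)
    cache: dict[tuple[str, int], Optional[int]] = {}

    def lookup(query: str, label_id: int) -> Optional[int]:
        key = (query, label_id)
        if key not in cache:
            cache[key] = engine.rank_of(label_id, query, J=J)
        return cache[key]

    ranks = [lookup(q, l) for q, l in zip(out["query"], out["label_id"])]
    out["rank"] = pd.array(ranks, dtype="Int64")
    out["infeasible"] = out["rank"].isna()
    n_bad = int(out["infeasible"].sum())
    if n_bad:
        logger.warning(
            "%d of %d records are infeasible (label beyond the top-%s suggestions)",
            n_bad, len(out), J,
        )
    return out


def enrich(
    df: pd.DataFrame,
    terminology: Terminology,
    J: int = 30,
    initial: Optional[Mapping[tuple[str, int], int]] = None,
    engine: Optional[CompletionEngine] = None,
) -> pd.DataFrame:
    """Full enrichment: seniority, qlen and rank in one pass."""
    out = assign_seniority(df, initial=initial)
    out = annotate_qlen(out)
    out = annotate_rank(out, terminology, J=J, engine=engine)
    return out[[c for c in ENRICHED_COLUMNS if c in out.columns]]


def read_log(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        df = pd.read_json(path, lines=True)
    else:
        # keep empty query cells as "" so validation can flag them
        df = pd.read_csv(path, keep_default_na=False, dtype={"query": str})
    return _validated(df)


def write_log(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)
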