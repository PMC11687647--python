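"""Rank-frequency distributions and power-law fits.

Zipf's law predicts that the frequency of an item decays as a power of
its frequency rank.  This module builds rank-frequency tables for any
token stream (words of queries, whole queries, selected label ids) and
fits the exponent by ordinary least squares in log10-log10 space over a
configurable rank range — transparent and adequate for checking that a
log's selection frequencies have the expected power-law structure.
Ties in frequency receive distinct consecutive ranks (alphabetical
within a tie).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .terminology_completion import Alphabet, DEFAULT_ALPHABET, normalize

__all__ = [
    "tokenize",
    "rank_frequency",
    "PowerLawFit",
    "powerlaw_fit",
]


def tokenize(text: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> list[str]:
    """Normalize then split on spaces; empty tokens dropped."""
    return normalize(text, alphabet).split()


def rank_frequency(tokens: Iterable[str]) -> pd.DataFrame:
    """Rank-frequency table: columns item, frequency, rank (1 = most frequent)."""
    counts = Counter(tokens)
    if not counts:
        raise ValueError("token list is empty")
    items = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return pd.DataFrame(
        {
            "item": [k for k, _ in items],
            "frequency": [v for _, v in items],
            "rank": np.arange(1, len(items) + 1),
        }
    )


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(frequency) on log10(rank)."""

    slope: float
    intercept: float
    r_squared: float
    min_rank: int
    max_rank: int
    n_points: int


def powerlaw_fit(
    table: pd.DataFrame,
    min_rank: int = 1,
    max_rank: Optional[int] = None,
) -> PowerLawFit:
    """Fit frequency ≈ C·rank^slope on the rank range [min_rank, max_rank].

    An exact Zipf table f(r) = C·r^(−s) recovers slope −s and r² = 1.
    The range matters on sampled data: the low-frequency tail flattens,
    so fits are usually restricted to the head.
    """
    if max_rank is None:
        max_rank = int(table["rank"].max())
    sub = table[(table["rank"] >= min_rank) & (table["rank"] <= max_rank)]
    if len(sub) < 3:
        raise ValueError(
            f"need at least 3 ranks in [{min_rank}, {max_rank}], got {len(sub)}"
        )
    x = np.log10(sub["rank"].to_numpy(dtype=float))
    y = np.log10(sub["frequency"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        min_rank=min_rank,
        max_rank=max_rank,
        n_points=len(sub),
    )
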