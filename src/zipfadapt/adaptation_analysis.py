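"""Trajectories of query quality against user-label seniority.

The headline analysis: average distance from the Pareto front (and each
objective separately) as a function of how many times a user has selected
a label.  Includes the supporting machinery — filtering to labels used
consistently across the seniority range, a finite-population
representativeness cap on the seniority axis, Savitzky–Golay smoothing of
the mean curves, and a cluster-bootstrap trend test used as a null check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "consistency_filter",
    "RepresentativenessReport",
    "representative_cap",
    "curve_by_seniority",
    "smooth_curve",
    "TrendResult",
    "trend_slope_bootstrap",
    "plot_curves",
]


def consistency_filter(df: pd.DataFrame, s_max: int) -> pd.DataFrame:
    """Keep records of labels attained at seniority ``s_max`` by some pair.

    Rare labels never reach high seniority, so the population of labels
    would otherwise change along the seniority axis; restricting to
    labels that some (user, label) pair has selected at least ``s_max``
    times makes the label set constant across levels 1..``s_max``.
    """
    if "seniority" not in df.columns:
        raise ValueError("log must be enriched with seniority first")
    top = int(df["seniority"].max())
    if s_max > top:
        raise ValueError(f"s_max={s_max} exceeds the maximum observed seniority {top}")
    keep = set(df.loc[df["seniority"] >= s_max, "label_id"].unique())
    out = df[df["label_id"].isin(keep)]
    logger.info(
        "consistency filter at level %d: kept %d/%d records (%d/%d labels)",
        s_max, len(out), len(df), len(keep), df["label_id"].nunique(),
    )
    return out


@dataclass(frozen=True)
class RepresentativenessReport:
    """Margin of error of each seniority level's pair sample.

    ``table`` has columns level, N (user-label pairs at level 1), n
    (pairs reaching the level), margin_of_error.  ``s_max`` is the
    largest level such that every level up to it meets the requested
    margin at the requested confidence.
    """

    table: pd.DataFrame
    s_max: int
    margin: float
    confidence: float
    z: float


def representative_cap(
    df: pd.DataFrame,
    margin: float = 0.03,
    confidence: float = 0.95,
) -> RepresentativenessReport:
    """Choose the seniority cap keeping each level a representative sample.

    The pairs reaching level ℓ are a sample of the N pairs observed at
    level 1.  The margin of error for a proportion at worst-case p = 0.5
    with finite-population correction is
    ``e = z * sqrt(0.25 / n) * sqrt((N - n) / (N - 1))``;
    the cap is the largest level where ``e <= margin`` holds at every
    level up to it.
    """
    if not 0 < margin < 1 or not 0 < confidence < 1:
        raise ValueError("margin and confidence must lie in (0, 1)")
    if df.empty:
        raise ValueError("empty log")
    z = float(norm.ppf(0.5 + confidence / 2))
    pair_max = df.groupby(["user", "label_id"])["seniority"].max()
    N = len(pair_max)
    levels = np.arange(1, int(pair_max.max()) + 1)
    rows = []
    s_max = 0
    contiguous = True
    for level in levels:
        n = int((pair_max >= level).sum())
        if n == 0:
            break
        if N == 1:
            e = 0.0
        else:
            e = z * math.sqrt(0.25 / n) * math.sqrt((N - n) / (N - 1))
        rows.append({"level": int(level), "N": N, "n": n, "margin_of_error": e})
        if contiguous and e <= margin:
            s_max = int(level)
        else:
            contiguous = False
    return RepresentativenessReport(
        table=pd.DataFrame(rows),
        s_max=s_max,
        margin=margin,
        confidence=confidence,
        z=z,
    )


_EXTRACTORS = {"distance": "distance", "qlen": "qlen", "rank": "rank"}


def curve_by_seniority(
    df: pd.DataFrame,
    value: str = "distance",
    s_max: Optional[int] = None,
) -> pd.DataFrame:
    """Mean and population std of a tracked value per seniority level.

    ``value`` is one of ``distance``, ``qlen``, ``rank`` (or any numeric
    column of the frame).  Returns columns level, n, mean, std; levels
    with no records are absent (gaps are reported, not interpolated).
    """
    col = _EXTRACTORS.get(value, value)
    if col not in df.columns:
        raise ValueError(f"no column {col!r} in the log")
    work = df.dropna(subset=[col])
    if s_max is not None:
        work = work[work["seniority"] <= s_max]
    vals = work[col].astype(float)
    grouped = (
        pd.DataFrame({"level": work["seniority"].astype(int), "v": vals})
        .groupby("level")["v"]
        .agg(n="size", mean="mean", std=lambda x: float(np.std(x)))  # population std
        .reset_index()
        .sort_values("level")
        .reset_index(drop=True)
    )
    return grouped


def smooth_curve(
    means: Sequence[float], window: int = 11, polyorder: int = 2
) -> np.ndarray:
    """Savitzky–Golay smoothing of a mean curve.

    The window must be odd, larger than the polynomial order and no
    longer than the curve.  Edges are handled by a polynomial fit on the
    truncated end windows (``mode='interp'``), so inputs that are exact
    polynomials of degree ≤ ``polyorder`` pass through unchanged.
    """
    y = np.asarray(means, dtype=float)
    if window % 2 == 0 or window <= polyorder or window > len(y):
        raise ValueError(
            f"window must be odd, > polyorder and <= {len(y)} (got window={window}, "
            f"polyorder={polyorder})"
        )
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


@dataclass(frozen=True)
class TrendResult:
    """Linear trend of a level-mean curve with a cluster-bootstrap CI."""

    slope: float
    ci_low: float
    ci_high: float
    n_boot: int
    confidence: float

    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def trend_slope_bootstrap(
    df: pd.DataFrame,
    value: str = "distance",
    max_level: Optional[int] = None,
    n_boot: int = 300,
    seed: int = 0,
    confidence: float = 0.95,
    balanced: bool = True,
) -> TrendResult:
    """Slope of mean-value-vs-seniority with a bootstrap CI over pairs.

    Records of one (user, label) pair are a trajectory, not independent
    draws, so the bootstrap resamples whole pairs.  Each replicate
    recomputes the per-level means and fits an ordinary least-squares
    line across levels; the CI is the percentile interval of the slopes.

    With ``balanced=True`` (default) only pairs observed at every level
    up to ``max_level`` enter, so the cohort is constant along the
    seniority axis and the slope measures within-pair change.  An
    unbalanced panel mixes composition drift (short-lived pairs leaving
    the sample) into the trend.
    """
    col = _EXTRACTORS.get(value, value)
    work = df.dropna(subset=[col])
    if max_level is not None:
        work = work[work["seniority"] <= max_level]
    if balanced:
        top = max_level if max_level is not None else int(work["seniority"].max())
        reach = work.groupby(["user", "label_id"])["seniority"].max()
        cohort = reach[reach >= top].index
        idx = pd.MultiIndex.from_frame(work[["user", "label_id"]])
        work = work[idx.isin(cohort)]
        if work.empty:
            raise ValueError(f"no pair reaches level {top}; cannot balance the panel")
    levels = np.sort(work["seniority"].unique()).astype(int)
    if len(levels) < 3:
        raise ValueError("need at least 3 seniority levels for a trend")
    level_pos = {lv: i for i, lv in enumerate(levels)}
    pair_codes = work.groupby(["user", "label_id"], sort=False).ngroup().to_numpy()
    n_pairs = pair_codes.max() + 1
    li = work["seniority"].map(level_pos).to_numpy()
    v = work[col].to_numpy(dtype=float)
    # per-pair, per-level sums and counts
    S = np.zeros((n_pairs, len(levels)))
    C = np.zeros((n_pairs, len(levels)))
    np.add.at(S, (pair_codes, li), v)
    np.add.at(C, (pair_codes, li), 1.0)

    def slope_from(sel: np.ndarray) -> float:
        cnt = C[sel].sum(axis=0)
        ok = cnt > 0
        if ok.sum() < 3:
            return math.nan
        means = S[sel].sum(axis=0)[ok] / cnt[ok]
        return float(np.polyfit(levels[ok], means, 1)[0])

    rng = np.random.default_rng(seed)
    point = slope_from(np.arange(n_pairs))
    slopes = np.array(
        [slope_from(rng.integers(0, n_pairs, n_pairs)) for _ in range(n_boot)]
    )
    slopes = slopes[~np.isnan(slopes)]
    alpha = 1 - confidence
    lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    return TrendResult(
        slope=point, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, confidence=confidence,
    )


def plot_curves(
    curves: dict[str, pd.DataFrame],
    path: str,
    window: int = 11,
    polyorder: int = 2,
) -> None:
    """Write a small multi-panel figure of mean ± std per seniority level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(5 * len(curves), 3.5))
    if len(curves) == 1:
        axes = [axes]
    for ax, (name, curve) in zip(axes, curves.items()):
        x, m, s = curve["level"], curve["mean"], curve["std"]
        ax.fill_between(x, m - s, m + s, alpha=0.2)
        ax.plot(x, m, label="mean")
        if window <= len(m) and window > polyorder and window % 2 == 1:
            ax.plot(x, smooth_curve(m, window, polyorder), label="smoothed")
        ax.set_xlabel("user-label seniority")
        ax.set_ylabel(name)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
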