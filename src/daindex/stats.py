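"""Group summaries, cross-correlation, regression and compound ranking.

Summaries follow the standard study-report layout: incidence as a
rounded percentage of animals above threshold, onset mean +/- SD over
arthritic animals only, severity mean +/- SD over all animals.
Compound ranking uses competition ranks on per-method severity means
(rank 1 = largest attenuation; ties share the minimal rank and the
next rank is skipped: 1, 2, 2, 4).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DaindexError

__all__ = [
    "incidence_percent",
    "pearson_r",
    "fit_regression",
    "StatResult",
    "rank_compounds",
    "dose_effect_ordering",
    "summarize_group",
    "summarize_groups",
    "correlation_table",
]


def incidence_percent(n_arthritic: int, n_total: int) -> int:
    """Percent of animals above threshold, rounded half-up to an integer."""
    if n_total <= 0:
        raise DaindexError("n_total must be positive")
    if not (0 <= n_arthritic <= n_total):
        raise DaindexError("need 0 <= n_arthritic <= n_total")
    return int(math.floor(100.0 * n_arthritic / n_total + 0.5))


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DaindexError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DaindexError("need at least 3 paired observations")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either input has zero variance."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class StatResult:
    """Simple-regression summary; r_squared is pearson_r**2."""

    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    n: int


def fit_regression(x, y) -> StatResult:
    """Least-squares fit of y on x with the paired-data filtering of
    :func:`pearson_r`.  A constant y gives slope 0 and R^2 = 0."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0:
        raise DaindexError("x has zero variance")
    if np.ptp(y) == 0:
        return StatResult(math.nan, 0.0, 0.0, float(y[0]), len(x))
    fit = sps.linregress(x, y)
    return StatResult(
        float(fit.rvalue), float(fit.rvalue) ** 2,
        float(fit.slope), float(fit.intercept), len(x),
    )


def _competition_ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="min")


def rank_compounds(means: pd.DataFrame) -> pd.DataFrame:
    """Competition ranks of per-compound severity means, per method.

    ``means``: index = compound, one column per assessment method, cells
    = mean severity (lower = stronger attenuation = better rank).  A
    missing mean excludes the compound from that method's ranking.
    Returns an integer-rank table with the same shape (NaN where
    excluded).
    """
    if len(means) < 2:
        raise DaindexError("need at least 2 compounds to rank")
    if means.shape[1] < 1:
        raise DaindexError("need at least 1 method")
    ranks = pd.DataFrame(index=means.index, columns=means.columns, dtype="Float64")
    for method in means.columns:
        col = means[method].astype(float)
        ok = col.notna()
        if ok.sum() == 0:
            continue
        ranks.loc[ok, method] = _competition_ranks(col[ok].to_numpy())
    return ranks


def dose_effect_ordering(reductions: Mapping[str, float]) -> str:
    """Render dose labels sorted by attenuation, e.g. ``"High > Low > Medium"``.

    ``reductions`` maps dose label -> reduction vs vehicle (larger =
    stronger effect).  Tied doses are joined with ``=``.
    """
    if not reductions:
        raise DaindexError("no dose reductions given")
    canonical = {"low": 0, "medium": 1, "mid": 1, "high": 2}

    def _key(kv):
        label, reduction = kv
        return (-reduction, canonical.get(str(label).lower(), 3), str(label))

    items = sorted(reductions.items(), key=_key)
    parts: list[str] = [items[0][0]]
    for (_, prev), (label, cur) in zip(items, items[1:]):
        parts.append("=" if cur == prev else ">")
        parts.append(label)
    return " ".join(parts)


def summarize_group(outcomes: pd.DataFrame) -> dict:
    """Incidence/onset/severity summary for one group x metric slice.

    Onset statistics cover arthritic animals only (NaN when none);
    severity statistics cover all animals, arthritic or not.
    """
    if outcomes.empty:
        raise DaindexError("no outcomes to summarize")
    n = len(outcomes)
    arthritic = outcomes[outcomes["arthritic"].astype(bool)]
    onsets = arthritic["onset_day"].dropna().astype(float)
    severities = outcomes["severity"].dropna().astype(float)
    return {
        "n": n,
        "n_arthritic": int(len(arthritic)),
        "incidence_pct": incidence_percent(len(arthritic), n),
        "onset_mean": float(onsets.mean()) if len(onsets) else math.nan,
        "onset_sd": float(onsets.std(ddof=1)) if len(onsets) > 1 else
        (0.0 if len(onsets) == 1 else math.nan),
        "severity_mean": float(severities.mean()) if len(severities) else math.nan,
        "severity_sd": float(severities.std(ddof=1)) if len(severities) > 1 else
        (0.0 if len(severities) == 1 else math.nan),
    }


def summarize_groups(
    outcomes: pd.DataFrame, animals: pd.DataFrame
) -> pd.DataFrame:
    """Per group x metric summary table (study-report shape)."""
    merged = outcomes.merge(animals[["animal_id", "group"]], on="animal_id")
    rows = []
    for (group, metric), sub in merged.groupby(["group", "metric"], sort=True):
        rows.append({"group": group, "metric": metric, **summarize_group(sub)})
    return pd.DataFrame(rows)


def correlation_table(severity: pd.DataFrame, columns: Optional[list[str]] = None) -> pd.DataFrame:
    """Pairwise Pearson correlations between per-animal severity measures.

    ``severity``: one row per animal, one column per measure (e.g. dai,
    delta_joint_in, arthritis_score, histopathology subscores and
    total).  Undefined correlations (zero variance, n < 3) are NaN.
    """
    cols = columns or [c for c in severity.columns if c != "animal_id"]
    out = pd.DataFrame(index=cols, columns=cols, dtype=float)
    for a in cols:
        for b in cols:
            if a == b:
                out.loc[a, b] = 1.0
                continue
            try:
                out.loc[a, b] = pearson_r(severity[a], severity[b])
            except DaindexError:
                out.loc[a, b] = math.nan
    return out
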