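"""Within-participant screening across the four collection points.

The Friedman rank test (tie-corrected) is the omnibus test of any temporal
change per feature; the Nemenyi post-hoc procedure localises the change to
one of the C(4,2) = 6 time-point intervals. An interval summary lists, per
cohort and interval, the features whose Nemenyi p (BH-adjusted across the
feature family within the interval) falls below alpha, and flags the subset
whose cohort-median concentration changed by at least 30 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import GROUP_CONTROL, GROUP_STRESS, FeatureTable, ValidationError
from .univariate import bh_adjust

__all__ = ["friedman", "nemenyi_posthoc", "longitudinal_screen", "interval_summary"]

COHORTS = ("all", GROUP_CONTROL, GROUP_STRESS)


def _check_block(block) -> np.ndarray:
    m = np.asarray(block, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("need a complete participants x time-points matrix (>= 2 x 2)")
    if not np.isfinite(m).all():
        raise ValidationError("block matrix has missing cells; the design must be complete")
    return m


def friedman(block) -> tuple[float, float]:
    """Tie-corrected Friedman test on a participants x time-points matrix.

    Returns (chi-square statistic, p from the chi-square distribution with
    k-1 df). Degenerate all-tied input (every participant constant across
    time points) yields (0, 1).
    """
    m = _check_block(block)
    if np.all(m == m[:, [0]]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*m.T)
    if not np.isfinite(stat):  # full tie correction collapse
        return 0.0, 1.0
    return float(stat), float(p)


def nemenyi_posthoc(block) -> pd.DataFrame:
    """Nemenyi pairwise post-hoc p-values for all time-point pairs.

    For each pair (a, b) the statistic |Rbar_a - Rbar_b| / sqrt(k(k+1)/(6n))
    is referred to the studentized-range distribution (k groups, infinite
    df) after multiplying by sqrt(2). Returns a symmetric k x k DataFrame
    of p-values with ones on the diagonal.
    """
    m = _check_block(block)
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rbar = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    p = np.ones((k, k))
    for a, b in combinations(range(k), 2):
        q = abs(rbar[a] - rbar[b]) / se * np.sqrt(2.0)
        pv = float(np.clip(stats.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
        p[a, b] = p[b, a] = pv
    return pd.DataFrame(p)


@dataclass
class LongitudinalResult:
    """Per-feature longitudinal screen for one cohort."""

    cohort: str
    time_points: list
    omnibus: pd.DataFrame  # feature, statistic, p, q
    intervals: pd.DataFrame  # feature x interval rows: nemenyi_p, q, pct_change, direction


def _cohort_blocks(table: FeatureTable, cohort: str) -> tuple[np.ndarray, list, list]:
    """(participants x time points x features) array for one cohort."""
    if cohort not in COHORTS:
        raise ValidationError(f"unknown cohort {cohort!r} (expected one of {COHORTS})")
    t = table if cohort == "all" else table.subset_samples(
        (table.samples["group"] == cohort).to_numpy()
    )
    tps = t.time_points
    parts = t.participants
    vals = t.values.to_numpy()
    pi = pd.Categorical(t.samples["participant"], categories=parts).codes
    ti = pd.Categorical(t.samples["time_point"], categories=tps).codes
    cube = np.full((len(parts), len(tps), t.n_features), np.nan)
    cube[pi, ti, :] = vals
    if np.isnan(cube).any():
        raise ValidationError("incomplete design: some participant misses a time point")
    return cube, tps, list(t.values.columns)


def longitudinal_screen(table: FeatureTable, cohort: str = "all") -> LongitudinalResult:
    """Friedman omnibus + Nemenyi interval p-values for every feature.

    The omnibus q is BH across features; each interval's Nemenyi p-values
    are BH-adjusted across the feature family within that interval.
    Per-interval percent change is measured between cohort medians,
    relative to the earlier time point's median.
    """
    cube, tps, feats = _cohort_blocks(table, cohort)
    pairs = list(combinations(range(len(tps)), 2))
    omni, rows = [], []
    for j, f in enumerate(feats):
        block = cube[:, :, j]
        stat, p = friedman(block)
        omni.append({"feature": f, "cohort": cohort, "statistic": stat, "p": p})
        nem = nemenyi_posthoc(block).to_numpy()
        med = np.median(block, axis=0)
        for a, b in pairs:
            change = (med[b] - med[a]) / med[a] if med[a] != 0 else np.nan
            rows.append(
                {
                    "feature": f,
                    "cohort": cohort,
                    "interval": f"{tps[a]}->{tps[b]}",
                    "nemenyi_p": nem[a, b],
                    "pct_change": 100.0 * change,
                    "direction": int(np.sign(med[b] - med[a])),
                }
            )
    omnibus = pd.DataFrame(omni)
    omnibus["q"] = bh_adjust(omnibus["p"].to_numpy())
    intervals = pd.DataFrame(rows)
    intervals["q"] = np.nan
    for iv in intervals["interval"].unique():
        sel = intervals["interval"] == iv
        intervals.loc[sel, "q"] = bh_adjust(intervals.loc[sel, "nemenyi_p"].to_numpy())
    return LongitudinalResult(cohort=cohort, time_points=tps, omnibus=omnibus, intervals=intervals)


def interval_summary(
    table: FeatureTable,
    cohort: str = "all",
    alpha: float = 0.05,
    magnitude: float = 0.30,
    result: LongitudinalResult | None = None,
) -> pd.DataFrame:
    """Significant interval changes and the large-magnitude highlight subset.

    Per interval: features with BH-adjusted Nemenyi q < ``alpha``; the
    ``highlighted`` flag additionally requires the cohort-median percent
    change to reach ``magnitude`` (fractional, default 0.30) in absolute
    value.
    """
    if magnitude < 0:
        raise ValidationError("magnitude must be >= 0")
    res = result if result is not None else longitudinal_screen(table, cohort)
    iv = res.intervals
    sig = iv[iv["q"] < alpha].copy()
    sig["highlighted"] = np.abs(sig["pct_change"]) >= 100.0 * magnitude
    sig["direction_label"] = np.where(sig["direction"] > 0, "increase", "decrease")
    return sig.reset_index(drop=True)
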