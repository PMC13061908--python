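"""Cross-sectional two-group screening.

Per feature: two-sided Mann-Whitney U between the control and high-stress
groups, either at a single collection point, on per-participant medians
across the four points, or pooled over all samples. P-values are adjusted
within each stratum's feature family with Benjamini-Hochberg. Fisher's
exact test covers categorical demographics (e.g. the sex split).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import GROUP_CONTROL, GROUP_STRESS, FeatureTable, ValidationError

__all__ = ["mann_whitney", "bh_adjust", "fisher_exact_2x2", "group_screen"]

#: use exact U enumeration up to this per-sample size when tie-free
EXACT_N_MAX = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of ``x``, p).

    The exact null distribution is enumerated when both samples have at
    most 8 observations and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= EXACT_N_MAX and y.size <= EXACT_N_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table -> (odds ratio, p)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValidationError("fisher_exact_2x2 needs a 2x2 table of non-negative integers")
        t = t.astype(int)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def _stratum_values(table: FeatureTable, stratum: str) -> tuple[pd.DataFrame, pd.Series]:
    """Per-unit feature values and group labels for one stratum.

    Units are participants for single time points and for ``"median"``
    (per-participant median across time points); for ``"all"`` every sample
    is a unit.
    """
    tps = table.time_points
    if stratum in tps:
        sub = table.at_time_point(stratum)
        vals = sub.values.set_index(sub.samples["participant"])
        groups = sub.samples.set_index("participant")["group"]
        return vals, groups.loc[vals.index]
    if stratum == "median":
        part = table.samples["participant"]
        vals = table.values.groupby(part.to_numpy()).median()
        vals.index.name = "participant"
        groups = table.samples.drop_duplicates("participant").set_index("participant")["group"]
        return vals, groups.loc[vals.index]
    if stratum == "all":
        return table.values, table.samples["group"]
    raise ValidationError(f"unknown stratum {stratum!r} (expected one of {tps}, 'median', 'all')")


def group_screen(table: FeatureTable, stratum: str) -> pd.DataFrame:
    """Mann-Whitney screen of every feature in one stratum.

    Returns a DataFrame with one row per feature: U statistic, two-sided p,
    BH q within this stratum's family, and the direction of the high-stress
    group relative to control (sign of the median difference).
    """
    vals, groups = _stratum_values(table, stratum)
    a = vals.loc[(groups == GROUP_STRESS).to_numpy()].to_numpy()
    b = vals.loc[(groups == GROUP_CONTROL).to_numpy()].to_numpy()
    rows = []
    for j, feature in enumerate(vals.columns):
        u, p = mann_whitney(a[:, j], b[:, j])
        rows.append(
            {
                "feature": feature,
                "stratum": stratum,
                "U": u,
                "p": p,
                "direction": int(np.sign(np.median(a[:, j]) - np.median(b[:, j]))),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["feature", "stratum", "U", "p", "q", "direction"]]
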