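"""Feature-inclusion filtering, below-LOD substitution and z-scoring.

Metabolite-class features are retained only if their analytical validation
passes: recovery within 100 +/- 30 % (closed interval [70, 130]), RSD <= 20 %,
and detection (quantified above the LOD) in at least 50 % of the samples of
either group, pooled across time points. Steroid- and protein-class features
were assayed on separate platforms and bypass these criteria.

Censored cells are substituted with one-fifth of the feature's minimum
quantifiable value. Z-scoring standardises each feature to mean 0 / SD 1
(sample SD, ddof=1) and stores the transform so it can be inverted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CLASS_METABOLITE, GROUPS, FeatureTable, ValidationError

__all__ = ["FilterReport", "filter_features", "impute_below_lod", "zscore"]

RECOVERY_LOW = 70.0
RECOVERY_HIGH = 130.0
RSD_MAX = 20.0
DETECTION_MIN = 0.5


@dataclass
class FilterReport:
    """Per-feature pass/fail decisions and survivor counts per stage."""

    decisions: pd.DataFrame  # one row per feature, one column per criterion
    stage_counts: dict  # ordered stage -> surviving feature count

    def excluded(self) -> pd.DataFrame:
        return self.decisions[~self.decisions["retained"]]


def filter_features(
    table: FeatureTable,
    *,
    recovery_window: tuple = (RECOVERY_LOW, RECOVERY_HIGH),
    rsd_max: float = RSD_MAX,
    detection_min: float = DETECTION_MIN,
    detection_per_time_point: bool = False,
) -> tuple[FeatureTable, FilterReport]:
    """Apply the inclusion criteria; return the filtered table and a report.

    ``detection_per_time_point=False`` (default) pools each group's samples
    across time points when evaluating the >=50 % detection criterion;
    ``True`` requires the rate within at least one group at some single
    time point.
    """
    feats = table.features
    is_met = feats["feature_class"] == CLASS_METABOLITE
    missing = feats.index[is_met & (feats["recovery"].isna() | feats["rsd"].isna())]
    if len(missing):
        raise ValidationError(
            f"metabolite feature {missing[0]!r} is missing QC fields (recovery/rsd)"
        )

    lo, hi = recovery_window
    pass_recovery = (~is_met) | ((feats["recovery"] >= lo) & (feats["recovery"] <= hi))
    pass_rsd = (~is_met) | (feats["rsd"] <= rsd_max)

    detected = ~table.below_lod
    group = table.samples["group"]
    rates = []
    for g in GROUPS:
        sub = detected.loc[(group == g).to_numpy()]
        if detection_per_time_point:
            tp = table.samples.loc[sub.index, "time_point"]
            rate = sub.groupby(tp.to_numpy()).mean().max(axis=0)
        else:
            rate = sub.mean(axis=0)
        rates.append(rate)
    detect_rate = pd.concat(rates, axis=1).max(axis=1)
    pass_detection = (~is_met) | (detect_rate >= detection_min)

    retained = pass_recovery & pass_rsd & pass_detection
    reason = np.where(
        ~pass_recovery, "recovery", np.where(~pass_rsd, "rsd", np.where(~pass_detection, "detection", ""))
    )
    decisions = pd.DataFrame(
        {
            "feature_class": feats["feature_class"],
            "subject_to_qc": is_met,
            "pass_recovery": pass_recovery,
            "pass_rsd": pass_rsd,
            "detection_rate": detect_rate,
            "pass_detection": pass_detection,
            "retained": retained,
            "exclusion_reason": reason,
        },
        index=feats.index,
    )
    n = len(feats)
    stage_counts = {
        "input": n,
        "after_recovery_rsd": int((pass_recovery & pass_rsd).sum()),
        "after_detection": int(retained.sum()),
    }
    out = table.subset_features(feats.index[retained])
    return out, FilterReport(decisions=decisions, stage_counts=stage_counts)


def impute_below_lod(table: FeatureTable) -> FeatureTable:
    """Replace every below-LOD cell with min_quantifiable / 5."""
    if table.features["min_quantifiable"].isna().any():
        f = table.features.index[table.features["min_quantifiable"].isna()][0]
        raise ValidationError(f"feature {f!r} has no min_quantifiable value")
    out = table.copy()
    fill = table.features["min_quantifiable"].to_numpy() / 5.0
    mask = out.below_lod.to_numpy()
    all_censored = mask.all(axis=0)
    if all_censored.any():
        names = list(table.features.index[all_censored])
        warnings.warn(
            f"feature(s) entirely below LOD (constant after imputation): {names}",
            stacklevel=2,
        )
    vals = out.values.to_numpy().copy()
    vals[mask] = np.broadcast_to(fill, vals.shape)[mask]
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.below_lod = pd.DataFrame(False, index=out.values.index, columns=out.values.columns)
    return out


def zscore(table: FeatureTable) -> FeatureTable:
    """Standardise each feature to mean 0 / SD 1 (sample SD, ddof=1).

    The per-feature mean and SD are stored in ``features['z_mean']`` /
    ``features['z_sd']`` so the transform is invertible. Constant features
    map to all-zeros with a warning (their stored SD is 1).
    """
    out = table.copy()
    vals = out.values.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    constant = sd == 0
    if constant.any():
        names = list(table.features.index[constant])
        warnings.warn(f"constant feature(s) z-scored to all zeros: {names}", stacklevel=2)
    safe_sd = np.where(constant, 1.0, sd)
    z = (vals - mean) / safe_sd
    out.values = pd.DataFrame(z, index=out.values.index, columns=out.values.columns)
    out.features["z_mean"] = mean
    out.features["z_sd"] = safe_sd
    return out
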