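"""Core in-memory containers for a mouth-rinse metabolomics study.

A study is a samples x features concentration matrix with an explicit
below-LOD (limit of detection) mask, plus per-sample and per-feature
metadata. Sample metadata carries the study design (participant, group,
collection time point, sex, age group); feature metadata carries the
analyte class and QC fields driving the inclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical group labels
GROUP_CONTROL = "control"
GROUP_STRESS = "high-stress"
GROUPS = (GROUP_CONTROL, GROUP_STRESS)

#: canonical collection points: rest, after the Uchida-Kraepelin test,
#: after recovery, and after the working-memory test
TIME_POINTS = ("Rest", "Post-UK", "Recover", "Post-WM")

#: analyte classes
CLASS_METABOLITE = "metabolite"
CLASS_STEROID = "steroid"
CLASS_PROTEIN = "protein"
FEATURE_CLASSES = (CLASS_METABOLITE, CLASS_STEROID, CLASS_PROTEIN)

SAMPLE_COLUMNS = ("participant", "group", "time_point", "sex", "age_group")


class ValidationError(ValueError):
    """A table or config failed a structural invariant."""


@dataclass
class FeatureTable:
    """Samples x features concentration matrix with design and QC metadata.

    Attributes
    ----------
    values : DataFrame
        Non-negative concentrations, index = sample ids, columns = feature
        ids. Cells flagged in ``below_lod`` hold the (unreliable) raw value
        until :func:`rinsemet.qc.impute_below_lod` substitutes them.
    below_lod : DataFrame
        Boolean mask aligned with ``values``; True means the cell is
        censored below the feature's limit of detection.
    samples : DataFrame
        One row per sample: participant, group, time_point, sex, age_group.
    features : DataFrame
        One row per feature: feature_class plus QC fields (recovery, rsd,
        min_quantifiable) and, for synthetic studies, decoy bookkeeping.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        v, m = self.values, self.below_lod
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicated sample id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicated feature id: {dup!r}")
        if m.shape != v.shape or not m.index.equals(v.index) or not m.columns.equals(v.columns):
            raise ValidationError("below_lod mask is not aligned with values")
        if not self.samples.index.equals(v.index):
            raise ValidationError("sample metadata rows do not align with the matrix")
        if not self.features.index.equals(v.columns):
            raise ValidationError("feature metadata rows do not align with the matrix")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        if "feature_class" not in self.features.columns:
            raise ValidationError("feature metadata missing 'feature_class'")
        bad = set(self.features["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ValidationError(f"unknown feature class(es): {sorted(bad)}")
        # z-scored tables (marked by a stored transform) may hold negatives
        if "z_mean" not in self.features.columns:
            arr = v.to_numpy(dtype=float)
            if np.isfinite(arr).all() and (arr < 0).any():
                raise ValidationError("negative concentration found")
        # group/sex/age constant within participant; one sample per
        # participant x time point
        key = self.samples[["participant", "time_point"]]
        if key.duplicated().any():
            p, t = key[key.duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample for participant {p!r} at {t!r}")
        for col in ("group", "sex", "age_group"):
            per = self.samples.groupby("participant", sort=False)[col].nunique()
            if (per > 1).any():
                p = per[per > 1].index[0]
                raise ValidationError(f"{col!r} varies within participant {p!r}")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def participants(self) -> list:
        return list(self.samples["participant"].unique())

    @property
    def time_points(self) -> list:
        seen: dict = {}
        for t in self.samples["time_point"]:
            seen.setdefault(t, None)
        return list(seen)

    def feature_ids(self, feature_class: str | None = None) -> list:
        f = self.features
        if feature_class is None:
            return list(f.index)
        return list(f.index[f["feature_class"] == feature_class])

    def subset_samples(self, mask) -> "FeatureTable":
        idx = self.samples.index[np.asarray(mask)]
        return FeatureTable(
            values=self.values.loc[idx],
            below_lod=self.below_lod.loc[idx],
            samples=self.samples.loc[idx],
            features=self.features.copy(),
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            values=self.values[ids],
            below_lod=self.below_lod[ids],
            samples=self.samples.copy(),
            features=self.features.loc[ids],
        )

    def at_time_point(self, time_point: str) -> "FeatureTable":
        if time_point not in set(self.samples["time_point"]):
            raise ValidationError(f"unknown time point: {time_point!r}")
        return self.subset_samples((self.samples["time_point"] == time_point).to_numpy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            below_lod=self.below_lod.copy(),
            samples=self.samples.copy(),
            features=self.features.copy(),
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.below_lod.equals(other.below_lod)
            and self.samples.equals(other.samples)
            and self.features.equals(other.features)
        )
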