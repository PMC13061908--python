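"""Plain-CSV interchange for feature tables.

A study on disk is a directory of three CSVs: ``matrix.csv`` (rows =
samples, columns = features, below-LOD cells serialized as the literal
token ``<LOD``), ``samples.csv`` and ``features.csv`` sidecars carrying the
metadata. Concentrations are stored in plain units, never pre-transformed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tables import SAMPLE_COLUMNS, FeatureTable, ValidationError

__all__ = ["read_study", "write_study", "LOD_TOKEN"]

LOD_TOKEN = "<LOD"

MATRIX_CSV = "matrix.csv"
SAMPLES_CSV = "samples.csv"
FEATURES_CSV = "features.csv"


def write_study(table: FeatureTable, out_dir) -> Path:
    """Write a study as the matrix + samples + features CSV triplet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = table.values.astype(object).copy()
    mask = table.below_lod.to_numpy()
    arr = matrix.to_numpy()
    arr[mask] = LOD_TOKEN
    pd.DataFrame(arr, index=table.values.index, columns=table.values.columns).to_csv(
        out / MATRIX_CSV, index_label="sample"
    )
    table.samples.to_csv(out / SAMPLES_CSV, index_label="sample")
    table.features.to_csv(out / FEATURES_CSV, index_label="feature")
    return out


def read_study(path) -> FeatureTable:
    """Read a study directory written by :func:`write_study`.

    ``<LOD`` tokens become True in the below-LOD mask (the stored cell value
    is 0 until imputation). Schema violations raise with row/column context.
    """
    p = Path(path)
    for name in (MATRIX_CSV, SAMPLES_CSV, FEATURES_CSV):
        if not (p / name).exists():
            raise ValidationError(f"study directory {p} is missing {name}")
    raw = pd.read_csv(p / MATRIX_CSV, index_col="sample", dtype=str)
    samples = pd.read_csv(p / SAMPLES_CSV, index_col="sample")
    features = pd.read_csv(p / FEATURES_CSV, index_col="feature")
    if "decoy_violation" in features.columns:  # empty string round-trips as NaN
        features["decoy_violation"] = features["decoy_violation"].fillna("")

    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"samples.csv missing columns: {missing}")
    if not raw.index.equals(samples.index):
        extra = set(raw.index) ^ set(samples.index)
        raise ValidationError(f"matrix and samples.csv disagree on sample ids: {sorted(extra)[:5]}")
    if not raw.columns.equals(features.index):
        extra = set(raw.columns) ^ set(features.index)
        raise ValidationError(f"matrix and features.csv disagree on feature ids: {sorted(extra)[:5]}")

    mask = raw == LOD_TOKEN
    vals = raw.mask(mask, "0")
    try:
        values = vals.astype(float)
        if values.isna().any().any():
            col = values.columns[values.isna().any(axis=0)][0]
            row = values.index[values[col].isna()][0]
            raise ValidationError(f"empty/non-numeric cell at sample {row!r}, feature {col!r}")
    except ValueError:
        for col in vals.columns:
            bad = pd.to_numeric(vals[col], errors="coerce").isna()
            if bad.any():
                row = vals.index[bad][0]
                raise ValidationError(
                    f"non-numeric cell at sample {row!r}, feature {col!r}: {vals.loc[row, col]!r}"
                ) from None
        raise
    return FeatureTable(values=values, below_lod=mask.astype(bool), samples=samples, features=features)
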