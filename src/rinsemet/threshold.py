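"""Single-feature and metabolite-ratio threshold classifiers.

The predictive core of the pipeline: every feature (and every unordered
feature pair, used as the ratio numerator/denominator) defines a candidate
one-dimensional classifier whose cutoff is set by maximising the Youden
index J = sensitivity + specificity - 1. Candidates are screened by
full-data AUC, then evaluated by leave-one-participant-out cross-validation
nested inside a stratified participant bootstrap; mean AUC / accuracy / F1
with percentile confidence intervals are reported, AUC significance is
tested with DeLong's variance estimator and a one-sided Z-test, and models
are selected by per-stratum thresholds on the CI lower bounds.

Ratios are the key trick: a per-sample multiplicative dilution factor and
any participant-level intensity signature common to both features cancel in
the ratio, so a pair can discriminate where single features cannot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import GROUP_CONTROL, GROUP_STRESS, FeatureTable, ValidationError

__all__ = [
    "ModelSpec",
    "ThresholdModel",
    "DeLongResult",
    "ResampledEvaluation",
    "auc",
    "youden_fit",
    "delong_test",
    "score",
    "predict",
    "fit_threshold_model",
    "loocv_evaluate",
    "bootstrap_loocv",
    "search_models",
    "select_models",
    "transfer_evaluate",
    "SELECTION_THRESHOLDS",
]

ORIENT_HIGH = "high-scores-predict-stress"
ORIENT_LOW = "low-scores-predict-stress"

#: CI-lower-bound selection thresholds per training stratum
#: (AUC bound varies by stratum; accuracy and F1 bounds are common)
SELECTION_THRESHOLDS = {
    "Rest": {"auc": 0.60, "accuracy": 0.50, "f1": 0.50},
    "Post-UK": {"auc": 0.60, "accuracy": 0.50, "f1": 0.50},
    "Recover": {"auc": 0.60, "accuracy": 0.50, "f1": 0.50},
    "Post-WM": {"auc": 0.65, "accuracy": 0.50, "f1": 0.50},
    "All": {"auc": 0.50, "accuracy": 0.50, "f1": 0.50},
}


@dataclass(frozen=True)
class ModelSpec:
    """A candidate feature: a single analyte or a numerator/denominator pair."""

    numerator: str
    denominator: str | None = None

    @property
    def is_ratio(self) -> bool:
        return self.denominator is not None

    @property
    def label(self) -> str:
        return self.numerator if not self.is_ratio else f"{self.numerator}/{self.denominator}"

    def __post_init__(self):
        if self.is_ratio and self.numerator == self.denominator:
            raise ValidationError("ratio numerator and denominator must differ")


@dataclass(frozen=True)
class ThresholdModel:
    """A fitted threshold classifier."""

    spec: ModelSpec
    orientation: str  # ORIENT_HIGH or ORIENT_LOW
    cutoff: float
    training_stratum: str | None = None
    youden_j: float = 0.0


@dataclass(frozen=True)
class DeLongResult:
    auc: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


@dataclass
class ResampledEvaluation:
    """Bootstrap-of-LOOCV evaluation summary for one candidate."""

    spec: ModelSpec
    stratum: str
    n_boot: int
    mean_auc: float
    auc_ci: tuple
    mean_accuracy: float
    accuracy_ci: tuple
    mean_f1: float
    f1_ci: tuple
    delong: DeLongResult
    direction: str  # "up" if higher score associates with high stress
    full_auc: float
    samples: pd.DataFrame = field(repr=False, default=None)  # per-iteration metrics


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """ROC area via the rank (Mann-Whitney) formula, ties counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("auc requires both classes present")
    r = stats.rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _youden_core(s: np.ndarray, y: np.ndarray):
    """Exhaustive Youden search over all threshold placements.

    Candidate cutoffs are midpoints between consecutive unique scores plus
    sentinels below/above the range. Returns (orientation_is_high, cutoff,
    J, sensitivity, specificity). Tie-break: max J, then max specificity,
    then smaller cutoff, then the high orientation.
    """
    n1 = int(y.sum())
    n0 = y.size - n1
    u, inv = np.unique(s, return_inverse=True)
    if u.size == 1:
        return True, float(u[0]), 0.0, 1.0, 0.0
    c1 = np.bincount(inv[y], minlength=u.size)
    c0 = np.bincount(inv[~y], minlength=u.size)
    # F[k] = fraction of the class with score < u[k], k = 0..U
    f1 = np.concatenate([[0], np.cumsum(c1)]) / n1
    f0 = np.concatenate([[0], np.cumsum(c0)]) / n0
    pad = 0.5 * max(u[-1] - u[0], 1.0)
    cuts = np.concatenate([[u[0] - pad], (u[:-1] + u[1:]) / 2.0, [u[-1] + pad]])
    j_high = f0 - f1  # predict stress iff score >= cutoff
    best = None
    for is_high, j_vec, spec_vec, sens_vec in (
        (True, j_high, f0, 1.0 - f1),
        (False, -j_high, 1.0 - f0, f1),
    ):
        k = int(np.lexsort((cuts, -spec_vec, -j_vec))[0])
        cand = (j_vec[k], spec_vec[k], -cuts[k], is_high, sens_vec[k])
        if best is None or cand[:3] > best[:3] or (cand[:3] == best[:3] and best[3] is False):
            best = cand
    j, spec_v, neg_cut, is_high, sens_v = best
    return bool(is_high), float(-neg_cut), float(max(j, 0.0)), float(sens_v), float(spec_v)


def youden_fit(scores, labels, spec: ModelSpec | None = None, stratum: str | None = None) -> ThresholdModel:
    """Fit the Youden-optimal (orientation, cutoff) threshold classifier."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValidationError("youden_fit requires both classes present")
    is_high, cutoff, j, _, _ = _youden_core(s, y)
    if np.unique(s).size == 1:
        warnings.warn("all scores identical; degenerate threshold model (J = 0)", stacklevel=2)
    return ThresholdModel(
        spec=spec if spec is not None else ModelSpec("score"),
        orientation=ORIENT_HIGH if is_high else ORIENT_LOW,
        cutoff=cutoff,
        training_stratum=stratum,
        youden_j=j,
    )


def predict(model: ThresholdModel, scores) -> np.ndarray:
    """Predicted label: high-stress iff (score >= cutoff) XOR low orientation."""
    s = np.asarray(scores, dtype=float)
    ge = s >= model.cutoff
    return ge if model.orientation == ORIENT_HIGH else ~ge


def delong_test(scores, labels) -> DeLongResult:
    """DeLong placement-value AUC variance and one-sided Z-test of AUC > 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    n1, n0 = pos.size, neg.size
    if n1 < 2 or n0 < 2:
        raise ValidationError("delong_test requires >= 2 observations per class")
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n0 for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n1 for q in neg])
    a = float(v10.mean())
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    if var <= 0:
        return DeLongResult(auc=a, variance=0.0, z=np.inf if a > 0.5 else 0.0,
                            p=0.0 if a > 0.5 else 0.5, degenerate=True)
    z = (a - 0.5) / np.sqrt(var)
    return DeLongResult(auc=a, variance=float(var), z=float(z), p=float(stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# scores per analysis unit
# ---------------------------------------------------------------------------

def score(model_or_spec, table: FeatureTable, sample_ids=None) -> pd.Series:
    """Per-sample score: the concentration, or numerator/denominator ratio."""
    spec = model_or_spec.spec if isinstance(model_or_spec, ThresholdModel) else model_or_spec
    ids = table.values.index if sample_ids is None else sample_ids
    for f in filter(None, (spec.numerator, spec.denominator)):
        if f not in table.values.columns:
            raise ValidationError(f"feature {f!r} not present in the table")
    num = table.values.loc[ids, spec.numerator]
    if not spec.is_ratio:
        return num.astype(float)
    den = table.values.loc[ids, spec.denominator]
    if (den == 0).any():
        raise ValidationError(f"zero denominator in ratio {spec.label}")
    return (num / den).astype(float)


def _unit_scores(table: FeatureTable, spec: ModelSpec, stratum: str):
    """Participant-level scores and labels for one stratum.

    Single time points use the participant's sample at that point; the
    pooled ``"All"`` stratum summarises each participant by the median of
    their per-sample scores (the participant is always the resampling and
    cross-validation unit).
    """
    s = score(spec, table)
    return _units_from_scores(table, s, stratum)


def _units_from_scores(table: FeatureTable, sample_scores: pd.Series, stratum: str):
    tps = table.time_points
    if stratum in tps:
        sel = (table.samples["time_point"] == stratum).to_numpy()
        part = table.samples.loc[sel, "participant"]
        sc = sample_scores.loc[sel].groupby(part.to_numpy()).first()
    elif stratum == "All":
        sc = sample_scores.groupby(table.samples["participant"].to_numpy()).median()
    else:
        raise ValidationError(f"unknown stratum {stratum!r} (expected one of {tps} or 'All')")
    groups = table.samples.drop_duplicates("participant").set_index("participant")["group"]
    y = (groups.loc[sc.index] == GROUP_STRESS).to_numpy()
    return sc.to_numpy(dtype=float), y, list(sc.index)


# ---------------------------------------------------------------------------
# LOOCV and bootstrap
# ---------------------------------------------------------------------------

def _metrics(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    accuracy = (tp + tn) / y.size
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return accuracy, f1


def _loocv_core(s: np.ndarray, y: np.ndarray) -> dict:
    """Leave-one-unit-out evaluation of the Youden threshold classifier.

    Held-out AUC is computed on the raw held-out scores with the single
    orientation of the full-data fit (per-fold orientation flips would make
    a pooled AUC incoherent).
    """
    n = y.size
    if y.all() or not y.any():
        raise ValidationError("loocv requires both classes present")
    pred = np.empty(n, dtype=bool)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yi = y[mask]
        if yi.all() or not yi.any():
            warnings.warn("training fold with a single class; fold skipped", stacklevel=2)
            pred[i] = False
            mask[i] = True
            continue
        is_high, cutoff, _, _, _ = _youden_core(s[mask], yi)
        pred[i] = (s[i] >= cutoff) == is_high
        mask[i] = True
    accuracy, f1 = _metrics(pred, y)
    full_high, _, _, _, _ = _youden_core(s, y)
    oriented = s if full_high else -s
    return {
        "accuracy": accuracy,
        "f1": f1,
        "auc": auc(oriented, y),
        "predictions": pred,
        "orientation_high": full_high,
    }


def loocv_evaluate(spec: ModelSpec, table: FeatureTable, stratum: str) -> dict:
    """Leave-one-participant-out metrics for one candidate in one stratum."""
    s, y, units = _unit_scores(table, spec, stratum)
    out = _loocv_core(s, y)
    out["units"] = units
    return out


def bootstrap_loocv(
    spec: ModelSpec,
    table: FeatureTable,
    stratum: str,
    n_boot: int = 100,
    seed: int | np.random.SeedSequence = 0,
    ci_level: float = 0.95,
) -> ResampledEvaluation:
    """Mean AUC / accuracy / F1 with percentile CIs over bootstrap-of-LOOCV.

    Each iteration resamples participants with replacement within each
    group (stratified, so group balance is preserved), reruns LOOCV on the
    resampled cohort (duplicates count as distinct units), and records the
    three metrics. The DeLong test is computed once on the full-data
    oriented scores.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    s, y, _ = _unit_scores(table, spec, stratum)
    return _bootstrap_core(s, y, spec, stratum, n_boot, seed, ci_level)


def _bootstrap_core(s, y, spec, stratum, n_boot, seed, ci_level=0.95) -> ResampledEvaluation:
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y)
    idx0 = np.flatnonzero(~y)
    rows = []
    for _ in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx1, size=idx1.size, replace=True),
             rng.choice(idx0, size=idx0.size, replace=True)]
        )
        r = _loocv_core(s[take], y[take])
        rows.append((r["auc"], r["accuracy"], r["f1"]))
    boot = pd.DataFrame(rows, columns=["auc", "accuracy", "f1"])
    lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2

    full_high, _, _, _, _ = _youden_core(s, y)
    oriented = s if full_high else -s
    dl = delong_test(oriented, y)

    def ci(col):
        return (float(np.percentile(boot[col], lo)), float(np.percentile(boot[col], hi)))

    return ResampledEvaluation(
        spec=spec,
        stratum=stratum,
        n_boot=n_boot,
        mean_auc=float(boot["auc"].mean()),
        auc_ci=ci("auc"),
        mean_accuracy=float(boot["accuracy"].mean()),
        accuracy_ci=ci("accuracy"),
        mean_f1=float(boot["f1"].mean()),
        f1_ci=ci("f1"),
        delong=dl,
        direction="up" if full_high else "down",
        full_auc=dl.auc,
        samples=boot,
    )


# ---------------------------------------------------------------------------
# exhaustive search, selection, transfer
# ---------------------------------------------------------------------------

def _candidate_matrix(table: FeatureTable, stratum: str, family: str):
    """Unit-score matrix for every candidate of a family, plus specs."""
    tps = table.time_points
    if stratum in tps:
        sub = table.at_time_point(stratum)
        vals = sub.values.to_numpy(dtype=float)
        part = sub.samples["participant"]
        groups = sub.samples.set_index("participant")["group"]
        y = (groups.loc[part].to_numpy() == GROUP_STRESS)
    elif stratum == "All":
        med = table.values.groupby(table.samples["participant"].to_numpy()).median()
        vals = med.to_numpy(dtype=float)
        groups = table.samples.drop_duplicates("participant").set_index("participant")["group"]
        y = (groups.loc[med.index].to_numpy() == GROUP_STRESS)
    else:
        raise ValidationError(f"unknown stratum {stratum!r}")
    feats = list(table.values.columns)
    if family == "single":
        return vals, y, [ModelSpec(f) for f in feats]
    if family == "ratio":
        i, j = np.triu_indices(len(feats), k=1)
        specs = [ModelSpec(feats[a], feats[b]) for a, b in zip(i, j)]
        return vals[:, i] / vals[:, j], y, specs
    raise ValidationError(f"unknown family {family!r} (expected 'single' or 'ratio')")


def _full_auc_matrix(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Oriented full-data AUC for every column (max of AUC, 1 - AUC)."""
    n1 = int(y.sum())
    n0 = y.size - n1
    r = stats.rankdata(scores, axis=0)
    a = (r[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return np.maximum(a, 1.0 - a)


def search_models(
    table: FeatureTable,
    stratum: str,
    family: str = "ratio",
    n_boot: int = 100,
    seed: int = 0,
    top_k: int = 50,
) -> pd.DataFrame:
    """Exhaustive candidate search ranked by resampled mean AUC.

    Every feature (``family="single"``) or unordered feature pair as one
    canonical ratio (``family="ratio"``; the reciprocal is redundant under
    threshold models) is scored by full-data oriented AUC; the ``top_k``
    candidates then get the full bootstrap-of-LOOCV evaluation and are
    ranked by mean AUC. Columns mirror the reporting convention: candidate
    label, mean metric with CI bounds, DeLong p, association direction.
    """
    scores, y, specs = _candidate_matrix(table, stratum, family)
    full = _full_auc_matrix(scores, y)
    order = np.argsort(-full, kind="stable")
    keep = order[: min(top_k, len(specs))] if top_k else order
    children = np.random.SeedSequence(seed).spawn(len(keep))
    rows = []
    for c, ss in zip(keep, children):
        ev = _bootstrap_core(scores[:, c], y, specs[c], stratum, n_boot, ss)
        rows.append(
            {
                "stratum": stratum,
                "candidate": specs[c].label,
                "numerator": specs[c].numerator,
                "denominator": specs[c].denominator,
                "family": family,
                "mean_auc": ev.mean_auc,
                "auc_lo": ev.auc_ci[0],
                "auc_hi": ev.auc_ci[1],
                "mean_accuracy": ev.mean_accuracy,
                "accuracy_lo": ev.accuracy_ci[0],
                "accuracy_hi": ev.accuracy_ci[1],
                "mean_f1": ev.mean_f1,
                "f1_lo": ev.f1_ci[0],
                "f1_hi": ev.f1_ci[1],
                "delong_p": ev.delong.p,
                "direction": ev.direction,
                "full_auc": float(full[c]),
                "n_candidates_screened": len(specs),
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_auc", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def select_models(candidates: pd.DataFrame, stratum: str | None = None,
                  thresholds: dict | None = None) -> pd.DataFrame:
    """Apply the per-stratum CI-lower-bound selection rule (strict >)."""
    df = candidates
    if stratum is None:
        strata = df["stratum"].unique()
        if len(strata) != 1:
            raise ValidationError("pass stratum explicitly for multi-stratum candidate sets")
        stratum = strata[0]
    if thresholds is None:
        if stratum not in SELECTION_THRESHOLDS:
            raise ValidationError(f"unknown stratum {stratum!r}; no selection thresholds defined")
        thresholds = SELECTION_THRESHOLDS[stratum]
    ok = (
        (df["auc_lo"] > thresholds["auc"])
        & (df["accuracy_lo"] > thresholds["accuracy"])
        & (df["f1_lo"] > thresholds["f1"])
    )
    out = df[ok].sort_values("mean_auc", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def fit_threshold_model(spec: ModelSpec, table: FeatureTable, stratum: str) -> ThresholdModel:
    """Full-data Youden fit of one candidate in one stratum."""
    s, y, _ = _unit_scores(table, spec, stratum)
    return youden_fit(s, y, spec=spec, stratum=stratum)


def transfer_evaluate(model: ThresholdModel, table: FeatureTable, target_strata) -> pd.DataFrame:
    """Apply a fitted model's fixed cutoff/orientation to other strata."""
    rows = []
    for stratum in target_strata:
        s, y, _ = _unit_scores(table, model.spec, stratum)
        pred = predict(model, s)
        accuracy, f1 = _metrics(pred, y)
        oriented = s if model.orientation == ORIENT_HIGH else -s
        rows.append(
            {
                "candidate": model.spec.label,
                "training_stratum": model.training_stratum,
                "target_stratum": stratum,
                "accuracy": accuracy,
                "f1": f1,
                "auc": auc(oriented, y),
            }
        )
    return pd.DataFrame(rows)
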