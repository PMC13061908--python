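"""Youden threshold models, DeLong inference, LOOCV/bootstrap, search."""

import warnings

import numpy as np
import pandas as pd
import pytest

import rinsemet as rm
from rinsemet.synth import PlantedEffect
from rinsemet.tables import ValidationError
from rinsemet.threshold import (
    ORIENT_HIGH,
    ORIENT_LOW,
    ModelSpec,
    ThresholdModel,
    _loocv_core,
    _youden_core,
    predict,
)

from conftest import null_config, prepared


# -- AUC --------------------------------------------------------------------

def test_auc_pair_enumeration():
    assert rm.auc([3, 1, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_perfect_separation():
    assert rm.auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0


def test_auc_single_class_rejected():
    with pytest.raises(ValidationError):
        rm.auc([1, 2], [1, 1])


def test_auc_equals_scaled_u_statistic():
    """AUC = U / (n1 * n0): algebraic identity, including ties."""
    rng = np.random.default_rng(12)
    for _ in range(300):
        n1, n0 = rng.integers(2, 15, size=2)
        scores = np.round(rng.normal(size=n1 + n0), rng.integers(0, 3))
        y = np.zeros(n1 + n0, dtype=bool)
        y[:n1] = True
        u, _ = rm.mann_whitney(scores[y], scores[~y])
        assert rm.auc(scores, y) == pytest.approx(u / (n1 * n0))


# -- Youden fit -------------------------------------------------------------

def _brute_force_youden(scores, y):
    """Independent exhaustive search over all cuts and both orientations."""
    best = 0.0
    cand = np.unique(scores)
    cuts = np.concatenate([[cand[0] - 1], (cand[:-1] + cand[1:]) / 2, [cand[-1] + 1]])
    for c in cuts:
        for hi in (True, False):
            pred = (scores >= c) == hi
            sens = np.mean(pred[y])
            spec = np.mean(~pred[~y])
            best = max(best, sens + spec - 1)
    return best


def test_youden_separable_midpoint():
    model = rm.youden_fit([1, 2, 3, 4], [0, 0, 1, 1])
    assert model.cutoff == pytest.approx(2.5)
    assert model.orientation == ORIENT_HIGH
    assert model.youden_j == pytest.approx(1.0)


def test_youden_matches_brute_force():
    rng = np.random.default_rng(13)
    for _ in range(300):
        n = int(rng.integers(6, 25))
        scores = np.round(rng.normal(size=n), rng.integers(0, 3))
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            continue
        model = rm.youden_fit(scores, y)
        assert model.youden_j == pytest.approx(_brute_force_youden(scores, y))
        # the returned model actually achieves its claimed J
        pred = predict(model, scores)
        j = np.mean(pred[y]) + np.mean(~pred[~y]) - 1
        assert j == pytest.approx(model.youden_j)


def test_youden_degenerate_scores_warn():
    with pytest.warns(UserWarning):
        model = rm.youden_fit([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
    assert model.youden_j == 0.0


def test_youden_j_nonnegative_on_null():
    """J >= 0 by construction and small on average under independence."""
    rng = np.random.default_rng(14)
    js = []
    for _ in range(100):
        y = np.zeros(16, dtype=bool)
        y[:8] = True
        model = rm.youden_fit(rng.normal(size=16), y)
        js.append(model.youden_j)
    assert min(js) >= 0
    assert np.mean(js) < 0.7


# -- scoring / ratio algebra ------------------------------------------------

def test_ratio_score(tiny_table):
    tiny_table.values.loc["P1_Rest", ["fA", "fB"]] = [2.0, 4.0]
    s = rm.threshold.score(ModelSpec("fA", "fB"), tiny_table)
    assert s.loc["P1_Rest"] == pytest.approx(0.5)


def test_low_orientation_prediction():
    model = ThresholdModel(ModelSpec("x"), ORIENT_LOW, cutoff=1.0)
    assert predict(model, [0.5])[0]  # low score -> high stress
    assert not predict(model, [1.5])[0]


def test_reciprocal_ratio_equivalence():
    """A fixed threshold model on a/b == reciprocal cutoff + flipped
    orientation on b/a (algebraic identity), and refitting the reciprocal
    attains the same Youden J."""
    rng = np.random.default_rng(15)
    for _ in range(50):
        a = rng.lognormal(size=12)
        b = rng.lognormal(size=12)
        y = np.zeros(12, dtype=bool)
        y[:6] = True
        m1 = rm.youden_fit(a / b, y)
        flipped = ORIENT_LOW if m1.orientation == ORIENT_HIGH else ORIENT_HIGH
        m2 = ThresholdModel(ModelSpec("b", "a"), flipped, 1.0 / m1.cutoff)
        assert np.array_equal(predict(m1, a / b), predict(m2, b / a))
        refit = rm.youden_fit(b / a, y)
        assert refit.youden_j == pytest.approx(m1.youden_j)


def test_ratio_spec_rejects_same_feature():
    with pytest.raises(ValidationError):
        ModelSpec("fA", "fA")


# -- DeLong -----------------------------------------------------------------

def _delong_independent(scores, y):
    """Second implementation via explicit pairwise indicator matrices."""
    pos = scores[y]
    neg = scores[~y]
    n1, n0 = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    a = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    return a, var


def test_delong_symmetric_null():
    res = rm.delong_test([1, 2, 3, 4], [1, 0, 0, 1])
    assert res.auc == pytest.approx(0.5)
    assert res.z == pytest.approx(0.0)
    assert res.p == pytest.approx(0.5)


def test_delong_matches_independent_implementation():
    rng = np.random.default_rng(16)
    res = rm.delong_test([3, 1, 2, 4], [0, 0, 1, 1])
    a, var = _delong_independent(np.array([3, 1, 2, 4.0]), np.array([0, 0, 1, 1], bool))
    assert res.auc == pytest.approx(0.75)
    assert res.auc == pytest.approx(a)
    assert res.variance == pytest.approx(var)
    for _ in range(100):
        scores = rng.normal(size=24)
        y = np.zeros(24, dtype=bool)
        y[:10] = True
        res = rm.delong_test(scores, y)
        a, var = _delong_independent(scores, y)
        assert res.auc == pytest.approx(a)
        assert res.variance == pytest.approx(var)


def test_delong_perfect_separation_flagged():
    res = rm.delong_test([1, 1, 9, 9], [0, 0, 1, 1])
    assert res.degenerate
    assert res.p == 0.0


def test_delong_variance_close_to_bootstrap():
    """DeLong variance tracks the bootstrap variance of the AUC (n=32)."""
    rng = np.random.default_rng(17)
    ratios = []
    for _ in range(10):
        scores = np.concatenate([rng.normal(0.8, 1, 16), rng.normal(0, 1, 16)])
        y = np.zeros(32, dtype=bool)
        y[:16] = True
        dl = rm.delong_test(scores, y)
        boot = []
        for _ in range(2000):
            i1 = rng.integers(0, 16, 16)
            i0 = rng.integers(16, 32, 16)
            idx = np.concatenate([i1, i0])
            boot.append(rm.auc(scores[idx], y[idx]))
        ratios.append(dl.variance / np.var(boot))
    assert abs(np.mean(ratios) - 1) < 0.2


# -- LOOCV ------------------------------------------------------------------

def test_loocv_perfect_marker():
    cfg = null_config(19, planted_effects=[
        PlantedEffect("met001", group_log_fc=6.0), PlantedEffect("met002", group_log_fc=-6.0)],
        lod_quantile=1e-9)  # keep the separation free of censoring artifacts
    table = prepared(cfg)
    res = rm.loocv_evaluate(ModelSpec("met001", "met002"), table, "Rest")
    assert res["accuracy"] == 1.0
    assert res["f1"] == 1.0
    assert res["auc"] == 1.0


def test_loocv_sample_order_invariance(filtered_imputed):
    spec = ModelSpec("met001", "met002")
    res = rm.loocv_evaluate(spec, filtered_imputed, "Rest")
    perm = np.random.default_rng(0).permutation(filtered_imputed.n_samples)
    shuffled = rm.FeatureTable(
        values=filtered_imputed.values.iloc[perm],
        below_lod=filtered_imputed.below_lod.iloc[perm],
        samples=filtered_imputed.samples.iloc[perm],
        features=filtered_imputed.features,
    )
    res2 = rm.loocv_evaluate(spec, shuffled, "Rest")
    for k in ("accuracy", "f1", "auc"):
        assert res[k] == pytest.approx(res2[k])


def test_loocv_null_calibration():
    """Accuracy ~ 0.5 when labels are independent of scores."""
    rng = np.random.default_rng(20)
    accs = []
    for _ in range(150):
        s = rng.normal(size=16)
        y = np.zeros(16, dtype=bool)
        y[:8] = True
        accs.append(_loocv_core(s, y)["accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.06


# -- bootstrap --------------------------------------------------------------

def test_bootstrap_deterministic(filtered_imputed):
    spec = ModelSpec("met001", "met002")
    a = rm.bootstrap_loocv(spec, filtered_imputed, "Rest", n_boot=10, seed=5)
    b = rm.bootstrap_loocv(spec, filtered_imputed, "Rest", n_boot=10, seed=5)
    assert a.mean_auc == b.mean_auc
    assert a.auc_ci == b.auc_ci
    assert a.mean_f1 == b.mean_f1
    c = rm.bootstrap_loocv(spec, filtered_imputed, "Rest", n_boot=10, seed=6)
    assert (a.mean_auc, a.mean_accuracy) != (c.mean_auc, c.mean_accuracy)


def test_bootstrap_ci_brackets_mean(filtered_imputed):
    ev = rm.bootstrap_loocv(ModelSpec("met001", "met002"), filtered_imputed, "Rest",
                            n_boot=25, seed=1)
    for mean, (lo, hi) in [(ev.mean_auc, ev.auc_ci), (ev.mean_accuracy, ev.accuracy_ci),
                           (ev.mean_f1, ev.f1_ci)]:
        assert lo <= mean <= hi
        assert 0 <= lo <= hi <= 1


def test_bootstrap_requires_iterations(filtered_imputed):
    with pytest.raises(ValidationError):
        rm.bootstrap_loocv(ModelSpec("met001"), filtered_imputed, "Rest", n_boot=1)


def test_planted_ratio_clears_selection_bar(filtered_imputed):
    ev = rm.bootstrap_loocv(ModelSpec("met001", "met002"), filtered_imputed, "Rest",
                            n_boot=25, seed=2)
    assert ev.auc_ci[0] > 0.60
    assert ev.accuracy_ci[0] > 0.50
    assert ev.f1_ci[0] > 0.50
    assert ev.direction == "up"  # met001 up, met002 down => ratio up with stress


# -- search / select / transfer ---------------------------------------------

def test_search_candidate_counts(filtered_imputed):
    single = rm.search_models(filtered_imputed, "Rest", "single", n_boot=5, seed=0, top_k=5)
    assert single["n_candidates_screened"].iloc[0] == 127
    ratio = rm.search_models(filtered_imputed, "Rest", "ratio", n_boot=5, seed=0, top_k=5)
    assert ratio["n_candidates_screened"].iloc[0] == 8001  # C(127, 2)
    assert (ratio["mean_auc"].to_numpy() == np.sort(ratio["mean_auc"])[::-1]).all()


def test_search_unknown_family(filtered_imputed):
    with pytest.raises(ValidationError):
        rm.search_models(filtered_imputed, "Rest", "triple")


def test_reciprocal_invariance_of_search(filtered_imputed):
    """Ordered pairs cannot beat the canonical unordered search."""
    from rinsemet.threshold import _candidate_matrix, _full_auc_matrix

    sc, y, specs = _candidate_matrix(filtered_imputed, "Rest", "ratio")
    full = _full_auc_matrix(sc, y)
    inv = _full_auc_matrix(1.0 / sc, y)
    assert np.allclose(full, inv)  # oriented AUC identical for reciprocals


def test_select_models_thresholds():
    base = dict(stratum="Rest", candidate="x", numerator="x", denominator=None,
                family="single", mean_auc=0.8, auc_hi=0.9, mean_accuracy=0.7,
                accuracy_hi=0.8, mean_f1=0.7, f1_hi=0.8, delong_p=0.01,
                direction="up", full_auc=0.8, n_candidates_screened=1)
    rows = [
        dict(base, candidate="at_bar", auc_lo=0.60, accuracy_lo=0.64, f1_lo=0.67),
        dict(base, candidate="passes", auc_lo=0.669, accuracy_lo=0.640, f1_lo=0.667),
        dict(base, candidate="fails_f1", auc_lo=0.70, accuracy_lo=0.60, f1_lo=0.50),
    ]
    df = pd.DataFrame(rows)
    sel = rm.select_models(df, "Rest")
    assert list(sel["candidate"]) == ["passes"]  # strict >, boundary excluded
    with pytest.raises(ValidationError):
        rm.select_models(df, "Siesta")


def test_select_post_wm_stricter():
    row = dict(stratum="Post-WM", candidate="x", numerator="x", denominator=None,
               family="single", mean_auc=0.8, auc_lo=0.62, auc_hi=0.9,
               mean_accuracy=0.7, accuracy_lo=0.55, accuracy_hi=0.8,
               mean_f1=0.7, f1_lo=0.55, f1_hi=0.8, delong_p=0.01,
               direction="up", full_auc=0.8, n_candidates_screened=1)
    df = pd.DataFrame([row])
    assert len(rm.select_models(df, "Post-WM")) == 0  # needs auc_lo > 0.65
    assert len(rm.select_models(df.assign(stratum="Rest"), "Rest")) == 1


def test_transfer_identity_on_training_stratum(filtered_imputed):
    spec = ModelSpec("met001", "met002")
    model = rm.fit_threshold_model(spec, filtered_imputed, "Rest")
    res = rm.transfer_evaluate(model, filtered_imputed, ["Rest"])
    # full-data (non-CV) metrics recomputed by hand
    from rinsemet.threshold import _unit_scores, _metrics

    s, y, _ = _unit_scores(filtered_imputed, spec, "Rest")
    pred = predict(model, s)
    acc, f1 = _metrics(pred, y)
    assert res.iloc[0]["accuracy"] == pytest.approx(acc)
    assert res.iloc[0]["f1"] == pytest.approx(f1)


def test_transfer_time_invariant_vs_rest_only_effect():
    spec = ModelSpec("met001", "met002")
    # chronic (time-invariant) effect: transfer holds up
    chronic = prepared(null_config(23, planted_effects=[
        PlantedEffect("met001", group_log_fc=2.0), PlantedEffect("met002", group_log_fc=-2.0)],
        latent_pairs=[("met001", "met002", 1.0)]))
    model = rm.fit_threshold_model(spec, chronic, "Rest")
    res = rm.transfer_evaluate(model, chronic, ["Rest", "Post-UK", "Recover", "Post-WM"])
    train_f1 = res[res["target_stratum"] == "Rest"]["f1"].iloc[0]
    others = res[res["target_stratum"] != "Rest"]["f1"]
    assert (others > train_f1 - 0.25).all()
    # acute Rest-only effect: transfer degrades toward chance
    rest_only = prepared(null_config(23, planted_effects=[
        PlantedEffect("met001", group_log_fc=2.5, group_time_points=("Rest",)),
        PlantedEffect("met002", group_log_fc=-2.5, group_time_points=("Rest",))],
        latent_pairs=[("met001", "met002", 1.0)]))
    model2 = rm.fit_threshold_model(spec, rest_only, "Rest")
    res2 = rm.transfer_evaluate(model2, rest_only, ["Rest", "Post-UK", "Recover", "Post-WM"])
    train2 = res2[res2["target_stratum"] == "Rest"]["f1"].iloc[0]
    others2 = res2[res2["target_stratum"] != "Rest"]["f1"]
    assert (others2 < train2).all()


def test_missing_feature_in_transfer(filtered_imputed):
    model = ThresholdModel(ModelSpec("unobtainium"), ORIENT_HIGH, 1.0, "Rest")
    with pytest.raises(ValidationError, match="unobtainium"):
        rm.transfer_evaluate(model, filtered_imputed, ["Rest"])
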