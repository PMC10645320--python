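"""Suitability modelling: selection, fitting, evaluation, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spreadca import RasterLayer
from spreadca.errors import DegenerateInputError, SpreadcaError
from spreadca.habitat import (
    LABEL_COLUMN, SelectionConfig, boyce_index, confusion_metrics,
    evaluate_model, extract_covariates, fit_suitability, max_tss_threshold,
    partial_dependence, project_suitability, select_variables,
    split_train_test, variable_importance, vif,
)


def _labelled_table(n=600, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    x3 = rng.normal(size=n)
    label = (x1 > 0).astype(int) if informative else rng.integers(0, 2, n)
    return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, LABEL_COLUMN: label})


# -- variable selection -----------------------------------------------------


def test_orthogonal_covariates_all_kept():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(rng.normal(size=(300, 5)),
                         columns=[f"v{i}" for i in range(5)])
    res = select_variables(table)
    assert res.kept == list(table.columns)
    assert res.log == []


def test_duplicated_covariate_reduced_to_one():
    rng = np.random.default_rng(2)
    base = rng.normal(size=400)
    table = pd.DataFrame({"a": base, "b": base.copy(),
                          "c": rng.normal(size=400)})
    res = select_variables(table)
    assert sorted(res.kept) in (["a", "c"], ["b", "c"])
    assert len(res.log) == 1 and res.log[0]["rule"] == "correlation-pair"


def test_survivors_keep_input_order():
    rng = np.random.default_rng(3)
    z = rng.normal(size=500)
    table = pd.DataFrame({
        "zeta": z + rng.normal(0, 0.05, 500),
        "alpha": rng.normal(size=500),
        "zed": z + rng.normal(0, 0.05, 500),
    })
    res = select_variables(table)
    assert res.kept == [c for c in table.columns if c in res.kept]


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_terminal_state_has_all_vif_below_threshold(seed):
    """The stopping rule: the loop ends only when every VIF < 4."""
    rng = np.random.default_rng(seed)
    n, k = 200, 6
    latent = rng.normal(size=(n, 2))
    mix = rng.normal(size=(2, k))
    noise = rng.uniform(0.05, 1.0, size=k)
    X = latent @ mix + rng.normal(size=(n, k)) * noise
    table = pd.DataFrame(X, columns=[f"v{i}" for i in range(k)])
    res = select_variables(table)
    if len(res.kept) >= 2:
        final_vif = vif(table[res.kept])
        assert (final_vif < 4.0).all()


def test_vif_duplicate_column_is_infinite():
    rng = np.random.default_rng(4)
    a = rng.normal(size=100)
    out = vif(pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)}))
    assert np.isinf(out["a"]) and np.isinf(out["b"])
    assert out["c"] < 2


# -- split / fit ------------------------------------------------------------


def test_split_is_stratified_disjoint_exhaustive():
    table = _labelled_table(n=1000, seed=5)
    train, test = split_train_test(table, ratio=0.7, seed=1)
    assert len(train) == 700 and len(test) == 300
    assert len(set(train.index) & set(test.index)) == 0
    assert set(train.index) | set(test.index) == set(table.index)
    p_all = table[LABEL_COLUMN].mean()
    assert abs(train[LABEL_COLUMN].mean() - p_all) < 0.01
    t2, _ = split_train_test(table, ratio=0.7, seed=1)
    assert list(t2.index) == list(train.index)


def test_separable_data_classified_accurately():
    table = _labelled_table(n=1200, seed=6)
    train, test = split_train_test(table, seed=0)
    model = fit_suitability(train, n_trees=200, seed=0)
    pred = (model.predict(test) >= 0.5).astype(int)
    assert (pred == test[LABEL_COLUMN]).mean() > 0.95


def test_constant_covariates_predict_prevalence():
    n = 400
    table = pd.DataFrame({"x1": np.ones(n), "x2": np.zeros(n),
                          LABEL_COLUMN: np.r_[np.ones(100), np.zeros(300)].astype(int)})
    model = fit_suitability(table, n_trees=100, seed=0)
    assert np.allclose(model.predict(table), 0.25, atol=0.05)


def test_single_class_training_raises():
    table = _labelled_table(200, seed=7)
    table[LABEL_COLUMN] = 1
    with pytest.raises(DegenerateInputError):
        fit_suitability(table)


def test_fit_is_deterministic_and_serializable(tmp_path):
    table = _labelled_table(400, seed=8)
    a = fit_suitability(table, n_trees=100, seed=3)
    b = fit_suitability(table, n_trees=100, seed=3)
    assert np.array_equal(a.predict(table), b.predict(table))
    a.save(tmp_path / "model.joblib")
    from spreadca.habitat import SuitabilityModel
    loaded = SuitabilityModel.load(tmp_path / "model.joblib")
    assert np.array_equal(loaded.predict(table), a.predict(table))


# -- Boyce index ------------------------------------------------------------


def _boyce_sim(mode, n=5000, seed=0):
    rng = np.random.default_rng(seed)
    bg = rng.random(20_000)
    if mode == "calibrated":
        w = bg
    elif mode == "inverted":
        w = 1.0 - bg
    else:
        w = np.ones_like(bg)
    pres = rng.choice(bg, size=n, p=w / w.sum())
    return pres, bg


def test_boyce_calibrated_uninformative_inverted_limits():
    pres, bg = _boyce_sim("calibrated")
    assert boyce_index(pres, bg) > 0.9
    # an uninformative model's CBI is Spearman over ~1/window_width nearly
    # independent windows, so single draws scatter widely; the mean over
    # independent simulations must sit near zero
    vals = [boyce_index(*_boyce_sim("uniform", seed=s)) for s in range(10)]
    assert abs(np.mean(vals)) < 0.3
    pres, bg = _boyce_sim("inverted", seed=2)
    assert boyce_index(pres, bg) < -0.9


def test_boyce_invariant_to_monotone_rescaling():
    pres, bg = _boyce_sim("calibrated", seed=3)
    raw = boyce_index(pres, bg)
    # a strictly monotone map of the scores leaves the rank statistic alone
    assert boyce_index(pres**3, bg**3) == pytest.approx(raw, abs=0.05)


def test_boyce_needs_three_windows():
    with pytest.raises(DegenerateInputError):
        boyce_index([0.5] * 10, [0.5] * 10)


# -- confusion metrics ------------------------------------------------------


def test_perfect_classifier_scores_one():
    labels = np.r_[np.ones(50), np.zeros(50)]
    probs = np.r_[np.full(50, 0.9), np.full(50, 0.1)]
    m = confusion_metrics(labels, probs, threshold=0.5)
    assert m["auc"] == 1.0 and m["tss"] == 1.0 and m["kappa"] == 1.0


def test_hand_computed_confusion_table():
    # TP=40, FP=10, FN=10, TN=40 at threshold 0.5
    labels = np.r_[np.ones(50), np.zeros(50)]
    probs = np.r_[np.full(40, 0.8), np.full(10, 0.2),   # presences
                  np.full(10, 0.8), np.full(40, 0.2)]   # absences
    m = confusion_metrics(labels, probs, threshold=0.5)
    assert m["sens"] == pytest.approx(0.8)
    assert m["spec"] == pytest.approx(0.8)
    assert m["tss"] == pytest.approx(0.6)
    assert m["kappa"] == pytest.approx(0.6)


def test_random_probs_give_auc_half():
    rng = np.random.default_rng(9)
    labels = rng.integers(0, 2, 10_000)
    probs = rng.random(10_000)
    m = confusion_metrics(labels, probs, threshold=0.5)
    assert m["auc"] == pytest.approx(0.5, abs=0.02)


def test_auc_equals_pairwise_rank_probability():
    """AUC must equal the brute-force probability that a random presence
    outranks a random absence (ties counted half)."""
    rng = np.random.default_rng(10)
    labels = rng.integers(0, 2, 150)
    labels[:5] = 1
    labels[5:10] = 0
    probs = np.round(rng.random(150), 1)  # coarse grid forces ties
    pres = probs[labels == 1]
    absent = probs[labels == 0]
    cmp = (pres[:, None] > absent[None, :]).sum() + \
        0.5 * (pres[:, None] == absent[None, :]).sum()
    brute = cmp / (len(pres) * len(absent))
    m = confusion_metrics(labels, probs, threshold=0.5)
    assert m["auc"] == pytest.approx(brute, abs=1e-12)


def test_max_tss_threshold_recorded_in_report():
    labels = np.r_[np.ones(60), np.zeros(140)]
    rng = np.random.default_rng(11)
    probs = np.clip(labels * 0.5 + rng.random(200) * 0.5, 0, 1)
    report = evaluate_model(labels, probs)
    best = max_tss_threshold(labels, probs)
    assert report.threshold == best
    m = confusion_metrics(labels, probs, best)
    assert report.tss == pytest.approx(m["tss"])


# -- response diagnostics ---------------------------------------------------


def test_partial_dependence_monotone_through_threshold():
    rng = np.random.default_rng(12)
    n = 1500
    x1 = rng.uniform(-2, 2, n)
    x2 = rng.normal(size=n)
    table = pd.DataFrame({"x1": x1, "x2": x2,
                          LABEL_COLUMN: (x1 > 0.3).astype(int)})
    model = fit_suitability(table, n_trees=150, seed=0)
    grid = np.linspace(-2, 2, 21)
    curve = partial_dependence(model, "x1", grid)
    assert np.all((curve >= 0) & (curve <= 1))
    assert curve[grid > 0.6].mean() > curve[grid < 0.0].mean() + 0.5
    flat = partial_dependence(model, "x2", grid)
    assert flat.max() - flat.min() < 0.1
    with pytest.raises(KeyError):
        partial_dependence(model, "nope", grid)


def test_informative_variable_ranked_first():
    rng = np.random.default_rng(13)
    n = 800
    x = {f"noise{i}": rng.normal(size=n) for i in range(4)}
    x["signal"] = rng.normal(size=n)
    table = pd.DataFrame(x)
    table[LABEL_COLUMN] = (table["signal"] > 0).astype(int)
    model = fit_suitability(table, n_trees=200, seed=0)
    ranking = variable_importance(model)
    assert ranking[0][0] == "signal"
    assert all(score >= 0 for _, score in ranking)


def test_all_noise_covariates_have_no_dominant_importance():
    table = _labelled_table(n=900, seed=14, informative=False)
    model = fit_suitability(table, n_trees=200, seed=0)
    scores = [s for _, s in variable_importance(model)]
    assert max(scores) <= 3 * np.median(scores)


# -- projection -------------------------------------------------------------


def _cov_rasters(values_by_name, cell=200.0):
    first = next(iter(values_by_name.values()))
    return {name: RasterLayer(np.asarray(v, float), origin_y=first.shape[0] * cell,
                              cell_size=cell)
            for name, v in values_by_name.items()}


def test_projection_constant_inputs_constant_output():
    table = _labelled_table(400, seed=15)
    model = fit_suitability(table[["x1", "x2", LABEL_COLUMN]], n_trees=100, seed=0)
    rasters = _cov_rasters({"x1": np.full((6, 6), 0.7), "x2": np.full((6, 6), -0.2)})
    out = project_suitability(model, rasters)
    assert np.ptp(out.values) == 0.0
    assert 0.0 <= out.values[0, 0] <= 1.0


def test_projection_agrees_with_pointwise_predictions():
    table = _labelled_table(600, seed=16)
    model = fit_suitability(table[["x1", "x2", LABEL_COLUMN]], n_trees=100, seed=0)
    rng = np.random.default_rng(17)
    rasters = _cov_rasters({"x1": rng.normal(size=(5, 7)),
                            "x2": rng.normal(size=(5, 7))})
    out = project_suitability(model, rasters)
    flat = pd.DataFrame({"x1": rasters["x1"].values.ravel(),
                         "x2": rasters["x2"].values.ravel()})
    assert np.allclose(out.values.ravel(), model.predict(flat))


def test_projection_missing_raster_raises():
    table = _labelled_table(300, seed=18)
    model = fit_suitability(table[["x1", "x2", LABEL_COLUMN]], n_trees=50, seed=0)
    with pytest.raises(SpreadcaError, match="missing"):
        project_suitability(model, _cov_rasters({"x1": np.zeros((3, 3))}))


def test_extract_covariates_drops_outside_and_nodata(small_bundle):
    from spreadca import gen_occurrences
    occ = gen_occurrences(small_bundle.suitability_truth, n=200, seed=3)
    table = extract_covariates(occ, small_bundle.covariates)
    assert len(table) == 200
    assert set(table.columns) == set(small_bundle.covariates) | {LABEL_COLUMN}
    assert (table[LABEL_COLUMN] == 1).all()
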