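"""Regression forest: split criterion, training, prediction, diagnostics."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from craniage import features as fe
from craniage import forest as fo
from craniage import pipeline as pl


def _toy_example(age, feature_value, hemisphere="right", n_points=30):
    """Example whose only informative feature is a preset inner-HC value
    (used to probe the splitting machinery in isolation)."""
    rng = np.random.default_rng(int(age * 1000) % 2**31)
    pts = rng.random((n_points, 3)) * 50 + 10
    hs = fe.HemisphereSampling(side=hemisphere, points=pts,
                               normals=np.tile([0.0, 0, 1], (n_points, 1)),
                               plane_point=np.zeros(3),
                               plane_normal=np.array([1.0, 0, 0]))
    ex = fo.TrainingExample(volume=np.zeros((4, 4, 4)), spacing=1.0,
                            hs=hs, mesh=None, surface_points=pts,
                            tt=None, age=age, hemisphere=hemisphere)
    ex._cache["inner_hc"] = float(feature_value)
    return ex


# -- information gain ------------------------------------------------------

def brute_ig(parent, left, right):
    def lv(a):
        m = sum(a) / len(a)
        v = sum((x - m) ** 2 for x in a) / len(a)
        return math.log(max(v, fo.VAR_FLOOR))
    return (lv(parent) - len(left) / len(parent) * lv(left)
            - len(right) / len(parent) * lv(right))


def test_information_gain_no_reduction():
    # children mirror the parent distribution: zero gain
    assert fo.information_gain([20, 30, 20, 30], [20, 30], [20, 30]) == \
        pytest.approx(0.0, abs=1e-12)


def test_information_gain_clean_split_ln26():
    # parent variance 26, child variances 1 -> gain ln 26
    got = fo.information_gain([20, 22, 30, 32], [20, 22], [30, 32])
    assert got == pytest.approx(math.log(26), abs=1e-12)


def test_information_gain_matches_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(4, 40))
        ages = rng.uniform(18, 34, n)
        cut = int(rng.integers(1, n))
        perm = rng.permutation(n)
        l, r = ages[perm[:cut]], ages[perm[cut:]]
        got = fo.information_gain(ages[perm], l, r)
        assert got == pytest.approx(brute_ig(list(ages[perm]), list(l),
                                             list(r)), abs=1e-12)


def test_information_gain_degenerate_cases():
    assert fo.information_gain([20, 21], [], [20, 21]) == -math.inf
    with pytest.raises(ValueError):
        fo.information_gain([20, 21, 22], [20], [21])


# -- split search ----------------------------------------------------------

def test_best_split_constant_ages_is_none():
    exs = [_toy_example(25.0, v) for v in np.linspace(0, 1, 12)]
    ages = np.array([e.age for e in exs])
    got = fo.best_split(exs, ages, 5, np.random.default_rng(0),
                        ["inner_hc"], min_samples=2, hemisphere="right")
    assert got is None or got[2] <= 1e-9


def test_best_split_separable_feature_splits_at_median(rng):
    ages = np.linspace(18, 34, 20)
    exs = [_toy_example(a, a + rng.normal(scale=1e-3)) for a in ages]
    got = fo.best_split(exs, ages, 1, np.random.default_rng(1),
                        ["inner_hc"], min_samples=2, hemisphere="right")
    assert got is not None
    d, tau, gain, left = got
    assert d.kind == "inner_hc"        # m=1: the single drawn descriptor
    assert gain > 0
    med = np.median(ages)
    assert np.all(ages[left] < med + 2) and np.all(ages[~left] > med - 2)


def test_trained_tree_memorises_clean_feature():
    rng = np.random.default_rng(2)
    ages = rng.uniform(18, 34, 40)
    exs = [_toy_example(a, a + rng.normal(scale=1e-3)) for a in ages]
    hp = fo.ForestHyperparams(n_trees=5, max_depth=15,
                              candidates_per_node=5, min_samples=1,
                              min_gain=1e-6, seed=0)
    f = fo.train_forest(exs, hp, enabled_banks=["inner_hc"])
    preds = [fo.predict(f, e).age for e in exs]
    assert fo.rmse(preds, ages) < 0.5          # near-memorisation


def test_forest_defaults_match_reported_settings():
    hp = fo.ForestHyperparams()
    assert hp.n_trees == 20 and hp.max_depth == 15
    assert hp.candidates_per_node == 200
    assert hp.sigma_max2 == 1.0


def test_leaf_depths_bounded(rng):
    ages = rng.uniform(18, 34, 30)
    exs = [_toy_example(a, a) for a in ages]
    hp = fo.ForestHyperparams(n_trees=3, max_depth=4,
                              candidates_per_node=3, min_samples=1, seed=1)
    f = fo.train_forest(exs, hp, enabled_banks=["inner_hc"])
    for tree in f.trees:
        for node, depth in fo._walk(tree):
            if isinstance(node, fo.LeafNode):
                assert depth <= hp.max_depth
            else:
                assert node.gain > hp.min_gain


def test_train_rejects_mixed_hemispheres():
    exs = [_toy_example(20, 1.0, "left"), _toy_example(30, 2.0, "right")]
    with pytest.raises(ValueError, match="hemisphere"):
        fo.train_forest(exs)
    with pytest.raises(ValueError):
        fo.train_forest([])


# -- prediction (variance-filtered mean) -----------------------------------

def _leaf_forest(leaves, hemisphere="right"):
    trees = [fo.LeafNode(m, v, 10) for m, v in leaves]
    return fo.RegressionForest(trees=trees, hemisphere=hemisphere,
                               hyperparams=fo.ForestHyperparams(
                                   n_trees=len(trees)),
                               enabled_banks=("inner_hc",))


def test_prediction_variance_filter():
    ex = _toy_example(0, 0)
    f = _leaf_forest([(20.0, 0.5), (30.0, 2.0)])
    pr = fo.predict(f, ex, sigma_max2=1.0)
    assert pr.age == 20.0 and pr.used_leaves == 1 and not pr.fallback_used

    f = _leaf_forest([(20.0, 0.5), (22.0, 0.9)])
    pr = fo.predict(f, ex, sigma_max2=1.0)
    assert pr.age == 21.0 and pr.used_leaves == 2

    f = _leaf_forest([(20.0, 2.0), (30.0, 2.0)])
    pr = fo.predict(f, ex, sigma_max2=1.0)
    assert pr.age == 25.0 and pr.fallback_used


def test_prediction_bounds_and_filter_monotonicity(rng):
    leaves = [(float(rng.uniform(18, 34)), float(rng.uniform(0.1, 3)))
              for _ in range(10)]
    f = _leaf_forest(leaves)
    ex = _toy_example(0, 0)
    prev_used = None
    for smax in (3.0, 1.5, 0.8, 0.3):
        pr = fo.predict(f, ex, sigma_max2=smax)
        included = [m for m, v in leaves if v < smax]
        if included:
            assert min(included) <= pr.age <= max(included)
            assert pr.used_leaves == len(included)
        if prev_used is not None:
            assert pr.used_leaves <= prev_used   # shrinking filter
        prev_used = pr.used_leaves


def test_predict_hemisphere_mismatch():
    f = _leaf_forest([(20.0, 0.5)], hemisphere="left")
    with pytest.raises(ValueError, match="hemisphere"):
        fo.predict(f, _toy_example(0, 0, "right"))


# -- rmse ------------------------------------------------------------------

def test_rmse_closed_form_and_oracle(rng):
    assert fo.rmse([21, 28], [20, 30]) == pytest.approx(math.sqrt(2.5))
    assert fo.rmse([20, 30], [20, 30]) == 0.0
    for _ in range(10):
        p = rng.uniform(18, 34, 25)
        t = rng.uniform(18, 34, 25)
        naive = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, t)) / 25)
        assert fo.rmse(p, t) == pytest.approx(naive, abs=1e-12)
    with pytest.raises(ValueError):
        fo.rmse([], [])


# -- serialisation ---------------------------------------------------------

def test_model_roundtrip_identical_predictions(rng):
    ages = rng.uniform(18, 34, 25)
    exs = [_toy_example(a, a) for a in ages]
    f = fo.train_forest(exs, fo.ForestHyperparams(
        n_trees=3, max_depth=6, candidates_per_node=3, min_samples=2,
        seed=3), enabled_banks=["inner_hc"])
    back = pl.roundtrip_model(f)
    for e in exs:
        assert fo.predict(back, e).age == fo.predict(f, e).age


def test_model_version_and_corruption_guards(tmp_path):
    f = _leaf_forest([(20.0, 0.5)])
    d = json.loads(f.to_json())
    d["format_version"] = 99
    with pytest.raises(ValueError, match="version"):
        fo.RegressionForest.from_json(json.dumps(d))
    with pytest.raises(json.JSONDecodeError):
        fo.RegressionForest.from_json("{not json")


# -- diagnostics -----------------------------------------------------------

def test_profile_single_bank_pure(rng):
    ages = rng.uniform(18, 34, 30)
    exs = [_toy_example(a, a) for a in ages]
    f = fo.train_forest(exs, fo.ForestHyperparams(
        n_trees=3, max_depth=5, candidates_per_node=3, min_samples=2,
        seed=4), enabled_banks=["inner_hc"])
    prof = fo.feature_selection_profile(f)
    kinds = list(fe.ALL_KINDS)
    assert np.allclose(prof[kinds].sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(prof["inner_hc"], 1.0)


def test_error_margin_constant_residuals():
    truths = np.linspace(18, 34, 40)
    preds = truths + np.where(np.arange(40) % 2 == 0, 1 / 7.0, -1 / 7.0)
    em = fo.error_margin(preds, truths)
    assert np.allclose(em.delta_w, 2.0, atol=1e-8)    # +/- 1 day
    eps = 3 / 7.0
    em = fo.error_margin(truths + np.where(np.arange(40) % 2 == 0,
                                           eps, -eps), truths)
    assert np.allclose(em.delta_w, 2 * eps * 7, atol=1e-8)


def test_error_margin_matches_normal_equations(rng):
    truths = rng.uniform(18, 34, 60)
    preds = truths + rng.normal(scale=0.5, size=60)
    em = fo.error_margin(preds, truths)
    resid = (preds - truths) * 7
    for mask, zeta in ((resid > 0, em.zeta_plus),
                       (resid < 0, em.zeta_minus)):
        V = np.vander(truths[mask], 3)
        ref, *_ = np.linalg.lstsq(V, resid[mask], rcond=None)
        assert np.abs(zeta - ref).max() < 1e-9
    assert np.all(em.delta_w >= 0)


def test_error_margin_needs_both_groups():
    truths = np.linspace(18, 34, 20)
    with pytest.raises(ValueError, match="under"):
        fo.error_margin(truths + 1.0, truths)   # only over-estimations


def test_longitudinal_consistency():
    df = pd.DataFrame({
        "subject": [1, 1, 1, 2, 2, 3],
        "true_age": [20.0, 24.0, 28.0, 19.0, 30.0, 25.0],
        "predicted_age": [20.0, 24.0, 28.0, 19.0, 30.0, 25.0]})
    out = fo.longitudinal_consistency(df)
    assert out["mean_interval_error"] == 0.0
    assert out["monotone_fraction"] == 1.0
    assert out["n_skipped"] == 1
    # constant bias cancels in intervals
    df2 = df.assign(predicted_age=df.predicted_age + 1.5)
    assert fo.longitudinal_consistency(df2)["mean_interval_error"] == 0.0
    # random predictions match a direct pairwise recomputation
    rng = np.random.default_rng(0)
    df3 = df.assign(predicted_age=rng.uniform(18, 34, len(df)))
    out3 = fo.longitudinal_consistency(df3)
    errs = []
    for _, g in df3.groupby("subject"):
        if len(g) < 2:
            continue
        g = g.sort_values("true_age")
        errs.extend(np.abs(np.diff(g.predicted_age.to_numpy())
                           - np.diff(g.true_age.to_numpy())))
    assert out3["mean_interval_error"] == pytest.approx(np.mean(errs))
    with pytest.raises(ValueError):
        fo.longitudinal_consistency(df.iloc[[5]])
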