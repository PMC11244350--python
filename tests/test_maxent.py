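import numpy as np
import pandas as pd
import pytest

import niche_shift as ns
from niche_shift.features import FeatureDef, FeatureSet, auto_feature_classes
from niche_shift.geo import extract_values
from niche_shift.maxent import (MaxEnt, SplitConfig, auc,
                                predict_from_saved, split)
from niche_shift.occurrences import OccurrenceRecord, OccurrenceSet
from niche_shift.geo import GeoPoint


def df(values, name="x"):
    return pd.DataFrame({name: np.asarray(values, dtype=float)})


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

def test_feature_scaling_examples():
    fs = FeatureSet.from_background(
        ["x"], np.array([[10.0], [30.0]]), ("linear", "quadratic"))
    F = fs.transform(np.array([[20.0]]))
    linear = F[0][fs.labels.index("x")]
    quad = F[0][fs.labels.index("x^2")]
    assert linear == pytest.approx(0.5)
    assert quad == pytest.approx(0.25)


def test_hinge_form():
    fs = FeatureSet(["x"], {"x": (0.0, 1.0)},
                    [FeatureDef("hinge", ("x",), 0.5)])
    assert fs.transform(np.array([[0.75]]))[0, 0] == pytest.approx(0.5)
    assert fs.transform(np.array([[0.25]]))[0, 0] == 0.0


def test_prediction_scaling_is_clamped():
    fs = FeatureSet(["x"], {"x": (0.0, 10.0)}, [FeatureDef("linear", ("x",))])
    assert fs.transform(np.array([[20.0]]))[0, 0] == 1.0
    assert fs.transform(np.array([[-5.0]]))[0, 0] == 0.0


def test_auto_feature_classes_presence_count():
    assert auto_feature_classes(5) == ("linear",)
    assert auto_feature_classes(12) == ("linear", "quadratic")
    assert auto_feature_classes(40) == ("linear", "quadratic", "hinge")
    assert set(auto_feature_classes(200)) == {"linear", "quadratic", "product",
                                              "hinge", "threshold"}


# ---------------------------------------------------------------------------
# Fitting: grid-search oracle on tiny models
# ---------------------------------------------------------------------------

def grid_search_lambda(F_pres, F_bg, beta, bounds=(-30.0, 30.0), rounds=4,
                       n_grid=2001):
    """Independent 1-D/2-D minimizer of the penalized objective by iterative
    grid refinement (no coordinate descent involved)."""
    n_feat = F_pres.shape[1]

    def objective(lam):
        lam = np.asarray(lam, dtype=float)
        s_bg = F_bg @ lam
        m = s_bg.max()
        log_z = m + np.log(np.exp(s_bg - m).sum())
        return (-(F_pres @ lam).mean() + log_z + (beta * np.abs(lam)).sum())

    if n_feat == 1:
        lo, hi = bounds
        best = 0.0
        for _ in range(rounds):
            grid = np.linspace(lo, hi, n_grid)
            vals = [objective([g]) for g in grid]
            best = grid[int(np.argmin(vals))]
            width = (hi - lo) / n_grid
            lo, hi = best - 2 * width, best + 2 * width
        return np.array([best])
    assert n_feat == 2
    lo = np.array([bounds[0]] * 2)
    hi = np.array([bounds[1]] * 2)
    best = np.zeros(2)
    for _ in range(rounds):
        g0 = np.linspace(lo[0], hi[0], 101)
        g1 = np.linspace(lo[1], hi[1], 101)
        vals = np.array([[objective([a, b]) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        best = np.array([g0[i], g1[j]])
        width = (hi - lo) / 101
        lo, hi = best - 2 * width, best + 2 * width
    return best


def test_fit_matches_grid_oracle_balanced_feature():
    """A feature with equal presence/background means gets weight 0."""
    vals = np.linspace(0, 10, 11)
    model = MaxEnt(df(vals), df(vals), feature_classes=("linear",),
                   add_presence_to_background=False)
    res = model.fit(tol=1e-10, max_iter=2000)
    oracle = grid_search_lambda(model._F_pres, model._F_bg, model._betas())
    assert abs(oracle[0]) < 1e-3
    assert res.params[0] == pytest.approx(oracle[0], abs=1e-3)


def test_fit_matches_grid_oracle_informative_feature():
    """Presences concentrated at high values drive a positive weight."""
    bg = np.linspace(0, 10, 21)
    pres = np.array([8.0, 9.0, 9.5, 10.0])
    model = MaxEnt(df(pres), df(bg), feature_classes=("linear",),
                   add_presence_to_background=False)
    res = model.fit(tol=1e-12, max_iter=5000)
    oracle = grid_search_lambda(model._F_pres, model._F_bg, model._betas())
    assert oracle[0] > 0
    assert res.params[0] == pytest.approx(oracle[0], abs=1e-3)


def test_fit_matches_grid_oracle_two_features():
    rng = np.random.default_rng(0)
    pres = pd.DataFrame({"x": [7.0, 8.0, 8.5, 9.0, 9.5],
                         "y": [2.0, 1.0, 3.0, 2.5, 1.5]})
    bg = pd.DataFrame({"x": np.linspace(0, 10, 25),
                       "y": rng.permutation(np.linspace(0, 10, 25))})
    model = MaxEnt(pres, bg, feature_classes=("linear",),
                   add_presence_to_background=False)
    res = model.fit(tol=1e-12, max_iter=5000)
    oracle = grid_search_lambda(model._F_pres, model._F_bg, model._betas())
    assert oracle[0] > 0 and oracle[1] < 0
    np.testing.assert_allclose(res.params, oracle, atol=1e-3)


def test_objective_monotone_and_raw_sums_to_one():
    rng = np.random.default_rng(2)
    pres = pd.DataFrame({"x": rng.normal(3, 1, 60), "y": rng.normal(0, 1, 60)})
    bg = pd.DataFrame({"x": rng.normal(0, 2, 400), "y": rng.normal(0, 1, 400)})
    res = MaxEnt(pres, bg).fit()
    hist = np.array(res.objective_history)
    assert np.all(np.diff(hist) <= 1e-12)
    assert res.raw_background_probs().sum() == pytest.approx(1.0, abs=1e-9)
    assert res.entropy >= 0.0
    assert np.isfinite(res.params).all()


def test_empty_model_is_uniform_with_zero_gain():
    """With no usable features the raw distribution is uniform and gain 0."""
    pres = df([5.0, 5.0, 5.0])
    bg = df([5.0] * 10)  # constant variable -> no features
    res = MaxEnt(pres, bg, add_presence_to_background=False).fit()
    assert len(res.model.features) == 0
    q = res.raw_background_probs()
    np.testing.assert_allclose(q, np.full(10, 0.1), atol=1e-12)
    assert res.gain == pytest.approx(0.0, abs=1e-12)
    # uniform model: cloglog p = 1 - exp(-1) at every cell
    p = res.predict_values(df([5.0]), link="cloglog")
    assert p[0] == pytest.approx(1 - np.exp(-1), abs=1e-9)


def test_gain_hand_computed_one_feature():
    """Fix lambda = 1 on a single linear feature and evaluate the Gibbs weights."""
    bg_vals = np.array([0.0, 5.0, 10.0])
    pres_vals = np.array([10.0])
    model = MaxEnt(df(pres_vals), df(bg_vals), feature_classes=("linear",),
                   add_presence_to_background=False)
    # hand evaluation: scaled features are [0, .5, 1]; with lam=1,
    # Z = e^0 + e^.5 + e^1, q(pres) = e^1/Z, gain = log q + log 3
    lam = np.array([1.0])
    from niche_shift.maxent import MaxEntResults
    res = MaxEntResults(model, lam, model._betas(), [0.0], [], True)
    z = np.exp(0) + np.exp(0.5) + np.exp(1.0)
    expected_gain = np.log(np.exp(1.0) / z) + np.log(3)
    assert res.gain == pytest.approx(expected_gain, abs=1e-12)


# ---------------------------------------------------------------------------
# Prediction links
# ---------------------------------------------------------------------------

def test_links_preserve_ranking_and_bounds(fitted_small):
    stack, truth, train, test, res = fitted_small
    vals = res.model.background.sample(200, random_state=0)
    raw = res.predict_values(vals, link="raw")
    logi = res.predict_values(vals, link="logistic")
    clog = res.predict_values(vals, link="cloglog")
    for p in (logi, clog):
        assert p.min() >= 0.0 and p.max() <= 1.0
        # identical ranking under monotone links
        assert (np.argsort(np.argsort(raw)) == np.argsort(np.argsort(p))).all()


def test_predict_propagates_nodata(fitted_small):
    stack, truth, train, test, res = fitted_small
    import copy
    layers = [copy.deepcopy(l) for l in stack.layers]
    layers[0].values[5, 5] = np.nan
    hole_stack = ns.RasterStack(layers)
    suit = res.predict(hole_stack)
    assert np.isnan(suit.values[5, 5])
    assert np.isfinite(suit.values[0, 0])


def test_predict_missing_variable_raises(fitted_small):
    stack, truth, train, test, res = fitted_small
    partial = ns.RasterStack(stack.layers[:3])
    with pytest.raises(ValueError, match="missing model variables"):
        res.predict(partial)


def test_predict_from_saved_round_trip(fitted_small):
    stack, truth, train, test, res = fitted_small
    direct = res.predict(stack)
    revived = predict_from_saved(res.to_dict(), stack)
    np.testing.assert_allclose(revived.values, direct.values, atol=1e-12)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_enumerable_examples():
    assert auc([3, 4], [1, 2]) == 1.0
    assert auc([1, 1, 1], [1, 1]) == 0.5
    # presence {0.9, 0.4}, background {0.5, 0.1}: 3 wins of 4 pairs
    assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    pres = rng.normal(1, 1, 50)
    bg = rng.normal(0, 1, 200)
    base = auc(pres, bg)
    for f in (np.exp, np.tanh, lambda v: 3 * v - 7):
        assert auc(f(pres), f(bg)) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

def occ_of_size(n):
    return OccurrenceSet(records=[
        OccurrenceRecord("sp", GeoPoint(100 + 0.01 * i, 20 + 0.01 * i))
        for i in range(n)])


def test_split_counts_and_determinism():
    train, test = split(occ_of_size(374), SplitConfig(seed=4))
    assert (len(train), len(test)) == (281, 93)
    train2, test2 = split(occ_of_size(374), SplitConfig(seed=4))
    assert [r.location for r in train2.records] == [r.location for r in train.records]
    t4, s4 = split(occ_of_size(4), SplitConfig(seed=0))
    assert (len(t4), len(s4)) == (3, 1)
    with pytest.raises(ValueError, match="at least 4"):
        split(occ_of_size(3), SplitConfig())


def test_split_partition_is_disjoint_union():
    occ = occ_of_size(41)
    train, test = split(occ, SplitConfig(seed=9))
    all_pts = {(r.location.lon_deg, r.location.lat_deg) for r in occ.records}
    tr = {(r.location.lon_deg, r.location.lat_deg) for r in train.records}
    te = {(r.location.lon_deg, r.location.lat_deg) for r in test.records}
    assert tr | te == all_pts and not (tr & te)


# ---------------------------------------------------------------------------
# Importance, jackknife, response curves
# ---------------------------------------------------------------------------

def test_single_variable_importance_is_total():
    rng = np.random.default_rng(3)
    pres = df(rng.normal(4, 0.5, 50))
    bg = df(rng.normal(0, 2, 300))
    res = MaxEnt(pres, bg).fit()
    assert res.contribution_rates()["x"] == pytest.approx(100.0)
    assert res.permutation_importance(seed=0)["x"] == pytest.approx(100.0)


def test_uninformative_variable_gets_zero_contribution():
    rng = np.random.default_rng(4)
    x = rng.normal(3, 1, 80)
    pres = pd.DataFrame({"x": x, "noise": np.full(80, 1.0)})
    bgx = rng.normal(0, 2, 400)
    bg = pd.DataFrame({"x": bgx, "noise": np.full(400, 1.0)})
    res = MaxEnt(pres, bg).fit()
    # constant variable contributes no features at all
    assert res.contribution_rates()["noise"] == 0.0
    assert res.permutation_importance(seed=0)["noise"] == 0.0


def test_importance_vectors_sum_to_100(fitted_small):
    stack, truth, train, test, res = fitted_small
    imp = res.importance(seed=1)
    assert imp["contribution_pct"].sum() == pytest.approx(100.0, abs=0.5)
    assert imp["permutation_pct"].sum() == pytest.approx(100.0, abs=0.5)
    assert (imp >= 0).all().all()


def test_jackknife_single_variable_equals_full_gain():
    rng = np.random.default_rng(5)
    pres = df(rng.normal(4, 0.5, 40))
    bg = df(rng.normal(0, 2, 200))
    res = MaxEnt(pres, bg, add_presence_to_background=False).fit()
    jk = res.jackknife()
    assert jk.loc["x", "gain_only"] == pytest.approx(res.gain, rel=1e-6)
    assert np.isnan(jk.loc["x", "gain_without"])


def test_jackknife_causal_beats_noise():
    rng = np.random.default_rng(6)
    n_pres, n_bg = 60, 400
    causal_pres = rng.normal(4, 0.5, n_pres)
    causal_bg = rng.normal(0, 2, n_bg)
    pres = pd.DataFrame({"causal": causal_pres, "noise": rng.normal(0, 1, n_pres)})
    bg = pd.DataFrame({"causal": causal_bg, "noise": rng.normal(0, 1, n_bg)})
    res = MaxEnt(pres, bg).fit()
    jk = res.jackknife()
    assert jk.loc["causal", "gain_only"] > jk.loc["noise", "gain_only"]


def test_response_curve_shapes():
    rng = np.random.default_rng(7)
    pres = df(rng.normal(4, 0.5, 30))
    bg = df(rng.normal(0, 2, 200))
    res = MaxEnt(pres, bg, feature_classes=("linear",)).fit()
    curve = res.response_curve("x", n_points=50)
    assert len(curve) == 50
    assert ((curve["p"] >= 0) & (curve["p"] <= 1)).all()
    # single positive-weight linear feature -> nondecreasing response
    assert res.params[0] > 0
    assert (np.diff(curve["p"]) >= -1e-12).all()
    # closed form: p = link(exp(lam * z) / Z) on the sweep
    fs = res.model.features
    z = fs.transform(curve[["value"]].to_numpy())
    expected = res._apply_link(np.exp(z @ res.params - res._log_z), "cloglog")
    np.testing.assert_allclose(curve["p"], expected, atol=1e-12)


def test_response_curve_flat_for_uniform_model():
    pres = df([5.0, 5.0, 5.0])
    bg = df(np.linspace(0, 10, 20))
    res = MaxEnt(pres, bg, feature_classes=("linear",), beta_multiplier=1e6,
                 add_presence_to_background=False).fit()
    assert res.params[0] == 0.0
    curve = res.response_curve("x")
    assert curve["p"].std() == pytest.approx(0.0, abs=1e-12)


def test_summary_mentions_key_quantities(fitted_small):
    *_, res = fitted_small
    text = res.summary()
    for token in ("presences", "training gain", "entropy", "AUC", "converged"):
        assert token in text
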