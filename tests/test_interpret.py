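"""Partial dependence, permutation importance and Friedman's H against
exhaustive oracles and analytic stub predictors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import harborhab as hh
from harborhab.interpret import GridSpec
from test_model import make_records


def _background(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "x": rng.uniform(-1, 1, n),
        "z": rng.uniform(-1, 1, n),
        "w": rng.uniform(-1, 1, n),
    })


def test_pdp_equals_bruteforce_average():
    """10-row background x 3-point grid == the exhaustive 30-prediction mean."""
    rec = make_records(200, seed=1)
    model = hh.fit_weighted_rf(rec, hh.ModelConfig(n_trees=30), seed=0)
    bg = rec.iloc[:10]
    grid = [5.0, 50.0, 95.0]
    pdp = hh.partial_dependence(model, bg, ["sav_pct"],
                                GridSpec(values={"sav_pct": grid}))
    for v, yhat in zip(pdp.values["sav_pct"], pdp.values["yhat"]):
        preds = []
        for _, row in bg.iterrows():
            mod = row.to_frame().T
            mod["sav_pct"] = v
            preds.append(model.predict_prob(mod)[0])
        assert yhat == pytest.approx(np.mean(preds), abs=1e-12)


def test_pdp_flat_for_uninformative_predictor():
    rec = make_records(1500, signal=False, seed=2)
    rec["present"] = (rec["depth_m"] > 12).astype(int)  # sav carries nothing
    model = hh.fit_weighted_rf(
        rec, hh.ModelConfig(n_trees=200, min_samples_leaf=10), seed=0)
    pdp = hh.partial_dependence(model, rec.iloc[:200], ["sav_pct"])
    yhat = pdp.values["yhat"]
    assert (np.abs(yhat - yhat.mean()) < 0.02).all()


def test_pdp_categorical_grid_covers_levels():
    rec = make_records(200, seed=3)
    model = hh.fit_weighted_rf(rec, hh.ModelConfig(n_trees=30), seed=0)
    pdp = hh.partial_dependence(model, rec.iloc[:30], ["season"])
    assert set(pdp.values["season"]) == {"winter", "spring", "summer", "fall"}
    assert pdp.values["yhat"].between(0, 1).all()


def test_pdp_unknown_variable_and_empty_background():
    rec = make_records(50, seed=4)
    model = hh.fit_weighted_rf(rec, hh.ModelConfig(n_trees=10), seed=0)
    with pytest.raises(hh.ConfigurationError):
        hh.partial_dependence(model, rec, ["no_such_var"])
    with pytest.raises(hh.ConfigurationError):
        hh.partial_dependence(model, rec.iloc[0:0], ["sav_pct"])


def test_pdp_at_means_profile_variant():
    rec = make_records(100, seed=5)
    model = hh.fit_weighted_rf(rec, hh.ModelConfig(n_trees=20), seed=0)
    pdp = hh.partial_dependence(model, rec, ["sav_pct"], GridSpec(at_means=True))
    assert pdp.background_n == 1


def test_pdp_marginal_average_identity_for_additive_predictor():
    """For an additive prediction function the background-marginal average
    of the one-way curve equals the mean model prediction exactly."""
    bg = _background(60)

    def f(df):
        return 0.4 + 0.2 * np.asarray(df["x"]) + 0.1 * np.asarray(df["z"]) ** 2

    pdp = hh.partial_dependence(f, bg, ["x"], GridSpec(values={"x": bg["x"].to_numpy()}))
    assert pdp.values["yhat"].mean() == pytest.approx(f(bg).mean(), abs=1e-12)


def test_pdp_marginal_average_is_product_measure_mean():
    """Fubini form: averaging the one-way curve over the background's own
    values equals the double mean over the product distribution, for any
    predictor (here a random forest)."""
    rec = make_records(30, seed=6)
    model = hh.fit_weighted_rf(rec, hh.ModelConfig(n_trees=20), seed=0)
    pdp = hh.partial_dependence(model, rec, ["sav_pct"],
                                GridSpec(values={"sav_pct": rec["sav_pct"].to_numpy()}))
    double = []
    for v in rec["sav_pct"]:
        mod = rec.copy()
        mod["sav_pct"] = v
        double.append(model.predict_prob(mod).mean())
    assert pdp.values["yhat"].mean() == pytest.approx(np.mean(double), abs=1e-12)


def test_h_additive_vs_multiplicative_stubs():
    bg = _background(120)
    additive = lambda df: 0.5 + 0.2 * np.asarray(df["x"]) + 0.2 * np.asarray(df["z"])  # noqa
    mult = lambda df: 0.5 + 0.45 * np.asarray(df["x"]) * np.asarray(df["z"])  # noqa
    h_add = hh.friedman_h(additive, bg, "x", "z", sample_n=100, seed=0).h
    h_mul = hh.friedman_h(mult, bg, "x", "z", sample_n=100, seed=0).h
    assert h_add < 0.05
    assert h_mul > 0.5


def test_h_matches_literal_double_loop():
    bg = _background(18, seed=3)

    def f(df):
        return (0.4 + 0.3 * np.asarray(df["x"]) * np.asarray(df["z"])
                + 0.25 * np.asarray(df["x"]) + 0.2 * np.asarray(df["z"])
                + 0.1 * np.asarray(df["w"]))

    got = hh.friedman_h(f, bg, "x", "z", sample_n=len(bg), seed=0).h

    m = len(bg)

    def pd_vals(cols):
        out = np.empty(m)
        for i in range(m):
            tmp = bg.copy()
            for c in cols:
                tmp[c] = bg[c].iloc[i]
            out[i] = f(tmp).mean()
        return out - out.mean()

    pj, pk, pjk = pd_vals(["x"]), pd_vals(["z"]), pd_vals(["x", "z"])
    expected = np.sqrt(((pjk - pj - pk) ** 2).sum() / (pjk ** 2).sum())
    assert got == pytest.approx(expected, abs=1e-10)


def test_h_invariant_to_additive_terms_in_other_variables():
    bg = _background(80, seed=4)
    f1 = lambda df: 0.5 + 0.3 * np.asarray(df["x"]) * np.asarray(df["z"])  # noqa
    f2 = lambda df: f1(df) + 0.4 * np.sin(3 * np.asarray(df["w"]))  # noqa
    h1 = hh.friedman_h(f1, bg, "x", "z", sample_n=60, seed=1).h
    h2 = hh.friedman_h(f2, bg, "x", "z", sample_n=60, seed=1).h
    assert h1 == pytest.approx(h2, abs=1e-10)


def test_h_constant_surface_reported_missing():
    bg = _background(30)
    const = lambda df: np.full(len(df), 0.3)  # noqa
    assert np.isnan(hh.friedman_h(const, bg, "x", "z", sample_n=20, seed=0).h)


def test_mda_ranks_informative_predictor_first():
    rec = make_records(2400, seed=7)  # presence driven by SAV only
    train = rec.iloc[:400]
    ev = rec.iloc[400:].reset_index(drop=True)
    model = hh.fit_weighted_rf(train, hh.ModelConfig(n_trees=150), seed=0)
    imp = hh.mda_importance(model, ev, n_permutations=5, seed=0)
    assert imp[0].variable == "sav_pct"
    noise = {r.variable: r.mda for r in imp if r.variable != "sav_pct"}
    assert all(abs(v) < 2 for v in noise.values())


def test_destroying_all_predictors_reaches_chance_accuracy():
    rec = make_records(1500, seed=8)
    train, ev = rec.iloc[:500], rec.iloc[500:].reset_index(drop=True)
    model = hh.fit_weighted_rf(train, hh.ModelConfig(n_trees=100), seed=0)
    rng = np.random.default_rng(0)
    perm = ev.copy()
    for c in model.predictors:
        perm[c] = rng.permutation(perm[c].to_numpy())
    pred = (model.predict_prob(perm) >= 0.5).astype(int)
    y = ev["present"].to_numpy()
    acc = (pred == y).mean()
    q, p = pred.mean(), y.mean()
    chance = q * p + (1 - q) * (1 - p)
    assert acc == pytest.approx(chance, abs=0.04)


def _const_pdp(value, species_vals):
    vals = pd.DataFrame({
        "season": np.repeat(["winter", "spring", "summer", "fall"], 3),
        "sav_pct": np.tile([0.0, 50.0, 100.0], 4),
    })
    vals["yhat"] = value
    return hh.PartialDependence(variables=("season", "sav_pct"), values=vals,
                                background_n=10)


def test_community_hsi_means_and_invariances():
    a = {"sav_pct": _const_pdp(0.2, None)}
    b = {"sav_pct": _const_pdp(0.4, None)}
    out = hh.community_hsi({"sp1": a, "sp2": b})
    assert np.allclose(out["mean_yhat"], 0.3)
    assert (out["n_species"] == 2).all()
    # identical inputs -> identity; order invariance
    same = hh.community_hsi({"sp1": a, "sp2": a})
    assert np.allclose(same["mean_yhat"], 0.2)
    swapped = hh.community_hsi({"sp2": b, "sp1": a})
    assert np.allclose(out["mean_yhat"], swapped["mean_yhat"])


def test_community_hsi_excludes_exposure():
    vals = pd.DataFrame({"season": ["winter"] * 2, "exposure_m": [0.0, 1.0],
                         "yhat": [0.1, 0.2]})
    pdp = hh.PartialDependence(("season", "exposure_m"), vals, 5)
    out = hh.community_hsi({"sp": {"exposure_m": pdp}})
    assert out.empty


def test_pdp_recovers_true_sav_response(clean_study, clean_presence):
    """Monotone SAV preference: rank agreement between the fitted SAV
    partial dependence and the generator's true response curve."""
    from harborhab.synthetic import true_response

    rec = clean_presence[clean_presence["species"] == "largemouth_bass"].reset_index(drop=True)
    train, tune, test = hh.split_data(rec, hh.SplitSpec(seed=2))
    model = hh.fit_weighted_rf(train, hh.ModelConfig(n_trees=200, presence_weight=5.0),
                               seed=2)
    bg = train.sample(300, random_state=2)  # background spanning many nodes
    pdp = hh.partial_dependence(model, bg, ["sav_pct"])
    truth = true_response(clean_study.system.preferences, "largemouth_bass",
                          "sav_pct", pdp.values["sav_pct"], clean_study.nodes)
    rho = stats.spearmanr(pdp.values["yhat"], truth).statistic
    assert rho >= 0.9
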