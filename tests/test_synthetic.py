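"""Generator contracts: determinism, bounds, detection-process guarantees,
occupancy statistics and the closed-form true response curves."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from conftest import SMALL_CFG

import harborhab as hh
from harborhab.presence import SEASONS
from harborhab.synthetic import (PiecewiseResponse, SpeciesPreference,
                                 _choice_probs, true_response)


def test_default_config_echo():
    study = hh.simulate_study(seed=1)
    assert study.nodes["node_id"].nunique() == 36
    assert study.nodes["region"].nunique() == 6
    span = study.deployments["end"].max() - study.deployments["start"].min()
    assert span >= pd.Timedelta(days=700)  # deployments cover the 2-year study
    assert (study.tags.groupby("species").size() == 15).all()


def test_same_seed_identical_outputs(small_study):
    again = hh.simulate_study(hh.SimConfig(**SMALL_CFG), seed=11)
    assert small_study.nodes.equals(again.nodes)
    assert small_study.deployments.equals(again.deployments)
    assert small_study.tags.equals(again.tags)
    assert small_study.detections.equals(again.detections)
    assert small_study.truth.occupancy.equals(again.truth.occupancy)
    assert small_study.truth.false_detection_ids == again.truth.false_detection_ids


def test_covariates_within_configured_ranges(small_study):
    nodes = small_study.nodes
    assert nodes["depth_m"].between(1, 25).all()
    assert nodes["sav_pct"].between(0, 100).all()
    assert nodes["exposure_m"].between(100, 10_000).all()
    assert np.isfinite(nodes[["depth_m", "sav_pct", "exposure_m"]]).all().all()


def test_invalid_configs_rejected():
    with pytest.raises(hh.ConfigurationError):
        hh.SimConfig(n_nodes=1).validate()
    with pytest.raises(hh.ConfigurationError):
        hh.SimConfig(species=()).validate()


def test_deployments_span_at_least_one_year(small_study):
    dep = small_study.deployments
    assert (dep["start"] < dep["end"]).all()
    per_node = dep.groupby("node_id").agg(start=("start", "min"), end=("end", "max"))
    assert ((per_node["end"] - per_node["start"]) >= pd.Timedelta(days=364)).all()


def test_detections_inside_deployment_windows(small_study):
    det = small_study.detections.merge(small_study.deployments, on="receiver_id")
    ok = (det["timestamp"] >= det["start"]) & (
        det["timestamp"] < det["end"] + pd.Timedelta(days=1))
    assert ok.groupby(det["det_id"]).any().all()


def test_min_delay_respected_for_true_detections(small_study):
    det = small_study.detections
    genuine = det[~det["det_id"].isin(small_study.truth.false_detection_ids)]
    gaps = (genuine.sort_values(["tag_id", "receiver_id", "timestamp"])
            .groupby(["tag_id", "receiver_id"])["timestamp"].diff().dropna())
    assert gaps.min() >= pd.Timedelta(seconds=45)


def test_contaminant_bookkeeping_matches_config(small_study):
    truth = small_study.truth
    assert len(truth.false_detection_ids) == 30
    assert truth.false_detection_ids <= set(small_study.detections["det_id"])
    assert len(truth.dead_tag_onsets) == 2  # one per species
    assert set(truth.dead_tag_onsets) <= set(small_study.tags["tag_id"])


def _toy_system(pref, n_nodes=8, seed=3, n_per_species=5):
    cfg = hh.SimConfig(n_nodes=n_nodes, n_days=365, species=(pref.species,),
                       n_per_species=n_per_species, n_spurious=0,
                       dead_tags_per_species=0, absent_prob=0.0)
    system = hh.simulate_system(cfg, seed)
    system.preferences = {pref.species: pref}
    return system


def _flat_pref(species="sp", beta0=-2.0):
    z = PiecewiseResponse((0.0, 1.0), (0.0, 0.0))
    return SpeciesPreference(species, beta0=beta0,
                             f_sav=PiecewiseResponse((0, 100), (0, 0)),
                             f_depth=PiecewiseResponse((1, 25), (0, 0)),
                             f_exposure=PiecewiseResponse((100, 10000), (0, 0))), z


def test_occupancy_frequencies_match_softmax():
    """Monte-Carlo day-choice frequencies agree with the analytic softmax,
    and a strong SAV preference concentrates days on high-SAV nodes."""
    pref = SpeciesPreference(
        "sp", beta0=-2.0,
        f_sav=PiecewiseResponse((0, 50, 50.001, 100), (0, 0, 4, 4)),
        f_depth=PiecewiseResponse((1, 25), (0, 0)),
        f_exposure=PiecewiseResponse((100, 10000), (0, 0)))
    system = _toy_system(pref, n_per_species=28)  # ~10,000 tracked days
    truth = hh.simulate_occupancy(system, seed=5)
    counts = truth.occupancy.groupby("node_id").size()
    end = system.config.end_ts
    n_days_total = (end - system.tags["release_date"]).dt.days.sum()
    p = truth.species_node_probs.query("season == 'summer'").set_index("node_id")["p"]
    high = system.nodes.loc[system.nodes["sav_pct"] > 50, "node_id"]
    low = system.nodes.loc[system.nodes["sav_pct"] <= 50, "node_id"]
    assert counts.reindex(high).sum() > counts.reindex(low, fill_value=0).sum()
    freq = counts / n_days_total
    # seasons are symmetric here, so the summer softmax is the overall law
    assert np.allclose(freq.reindex(p.index, fill_value=0), p, atol=0.02)


def test_flat_preference_is_uniform_within_sampling_error():
    pref, _ = _flat_pref()
    system = _toy_system(pref, n_per_species=12)
    truth = hh.simulate_occupancy(system, seed=5)
    counts = truth.occupancy.groupby("node_id").size().reindex(
        system.nodes["node_id"], fill_value=0)
    expected = counts.mean()
    assert (np.abs(counts - expected) / expected < 0.15).all()


def test_absent_probability_one_gives_no_detectable_days():
    pref, _ = _flat_pref()
    system = _toy_system(pref)
    system.config = replace(system.config, absent_prob=1.0)
    truth = hh.simulate_occupancy(system, seed=5)
    assert truth.occupancy.empty


def test_zero_contaminants_means_every_detection_is_true(clean_study):
    assert clean_study.truth.false_detection_ids == set()
    assert clean_study.truth.dead_tag_onsets == {}
    # every detection maps to a realized presence day of its tag at that node
    det = clean_study.detections.copy()
    det["date"] = det["timestamp"].dt.normalize()
    det = det.merge(clean_study.deployments[["receiver_id", "node_id"]], on="receiver_id")
    occ = clean_study.truth.occupancy
    idx = pd.MultiIndex.from_frame(occ[["tag_id", "date", "node_id"]])
    assert pd.MultiIndex.from_frame(det[["tag_id", "date", "node_id"]]).isin(idx).all()


def test_dead_tag_construction(small_study):
    det = small_study.detections
    for tag, onset in small_study.truth.dead_tag_onsets.items():
        after = det[(det["tag_id"] == tag) & (det["timestamp"] >= onset)
                    & ~det["det_id"].isin(small_study.truth.false_detection_ids)]
        assert after["receiver_id"].nunique() == 1
        assert (after["timestamp"].max() - onset) > pd.Timedelta(days=14)


def test_true_response_closed_form():
    """At sav=0 (with f_sav(0)=0 and no season terms) the curve equals
    inverse-logit(beta0 + f_depth(mean depth) + f_exposure(mean exposure))."""
    pref = SpeciesPreference(
        "sp", beta0=-1.5,
        f_sav=PiecewiseResponse((0, 100), (0.0, 3.0)),
        f_depth=PiecewiseResponse((1, 25), (0.5, -0.5)),
        f_exposure=PiecewiseResponse((100, 10000), (0.2, -0.2)))
    system = _toy_system(pref)
    nodes = system.nodes
    prefs = {"sp": pref}
    got = true_response(prefs, "sp", "sav_pct", [0.0], nodes)[0]
    expected = 1 / (1 + np.exp(-(pref.beta0
                                 + pref.f_depth(nodes["depth_m"].mean())
                                 + pref.f_exposure(nodes["exposure_m"].mean()))))
    assert got == pytest.approx(expected, abs=1e-12)
    # monotone response -> monotone curve; flat response -> constant curve
    grid = np.linspace(0, 100, 15)
    curve = true_response(prefs, "sp", "sav_pct", grid, nodes)
    assert (np.diff(curve) > 0).all()
    flat, _ = _flat_pref()
    const = true_response({"sp": flat}, "sp", "sav_pct", grid, nodes)
    assert np.ptp(const) < 1e-12


def test_choice_probs_sum_to_one(small_study):
    p = _choice_probs(small_study.system.preferences["walleye"],
                      small_study.nodes, "spring", absent_prob=0.1)
    assert p.sum() == pytest.approx(1.0)
    assert (p >= 0).all()
    for sp in ("largemouth_bass", "walleye"):
        for season in SEASONS:
            sub = small_study.truth.species_node_probs.query(
                "species == @sp and season == @season")["p"]
            assert sub.sum() < 1.0
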