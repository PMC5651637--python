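"""Simulation engine: selection, conversion, scenario runs."""

import numpy as np
import pandas as pd
import pytest

from modeshift import simulate
from modeshift.features import MODES
from modeshift.scenario import Scenario, ShiftPlan
from modeshift.simulate import (apply_conversion, apply_repetition,
                                run_complementary, run_scenario,
                                select_and_assign)


def _null_plan():
    return ShiftPlan({}, {}, {}, 0)


def test_null_plan_assigns_nothing(survey_integrated, likelihoods):
    _, trips = survey_integrated
    cands = trips[trips["mode"] == "private_motorized"]
    out = select_and_assign(cands, likelihoods, _null_plan(),
                            np.random.default_rng(0))
    assert out.isna().all()


def test_single_candidate_near_certain_assignment(survey_integrated,
                                                  likelihoods):
    _, trips = survey_integrated
    cand = trips[trips["mode"] == "private_motorized"].head(1)
    plan = ShiftPlan({"public_transport": 1, "walking": 1, "bicycle": 1},
                     {"public_transport": 0.996, "walking": 0.002,
                      "bicycle": 0.002},
                     {"public_transport": 1, "walking": 1, "bicycle": 1}, 3)
    rng = np.random.default_rng(12)
    hits = sum(select_and_assign(cand, likelihoods, plan, rng).iloc[0]
               == "public_transport" for _ in range(1000))
    assert hits >= 990


def test_conversion_contracts(survey_integrated, duration_model,
                              tmvpa_model):
    _, trips = survey_integrated
    trip = trips[trips["mode"] == "private_motorized"].iloc[0]
    for new_mode in ("bicycle", "walking", "public_transport"):
        conv = apply_conversion(trip, new_mode, duration_model, tmvpa_model)
        assert conv["mode"] == new_mode
        assert conv["duration_min"] >= 1.0
        assert conv["speed_m_min"] == pytest.approx(
            conv["straight_line_distance_m"] / conv["duration_min"])
        assert 0.0 <= conv["tmvpa_min"] <= conv["duration_min"]
        if new_mode == "bicycle":
            assert conv["tmvpa_min"] == conv["duration_min"]


def test_conversion_to_same_mode_rejected(survey_integrated, duration_model,
                                          tmvpa_model):
    _, trips = survey_integrated
    trip = trips[trips["mode"] == "walking"].iloc[0]
    with pytest.raises(simulate.SimulationError, match="already"):
        apply_conversion(trip, "walking", duration_model, tmvpa_model)


def _small_scenario(reps=20, mult=1, seed=5):
    return Scenario(name="t", multiplier=mult, n_repetitions=reps, seed=seed)


def test_null_scenario_reproduces_baseline(survey_integrated, likelihoods,
                                           duration_model, tmvpa_model):
    persons, trips = survey_integrated
    sc = Scenario(destination_increases={"public_transport": 0.0,
                                         "walking": 0.0, "bicycle": 0.0},
                  n_repetitions=3, seed=1)
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model, sc)
    for i in range(3):
        assert len(run.repetitions[i].converted) == 0
        pd.testing.assert_frame_equal(run.rep_decomposition(i),
                                      run.baseline_decomp)


def test_same_master_seed_gives_identical_runs(survey_integrated,
                                               likelihoods, duration_model,
                                               tmvpa_model):
    _, trips = survey_integrated
    a = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                     _small_scenario(reps=5))
    b = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                     _small_scenario(reps=5))
    for ra, rb in zip(a.repetitions, b.repetitions):
        pd.testing.assert_frame_equal(ra.converted, rb.converted)


def test_trip_count_conserved_and_unselected_trips_immutable(
        survey_integrated, likelihoods, duration_model, tmvpa_model):
    _, trips = survey_integrated
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                       _small_scenario(reps=5))
    for rep in run.repetitions:
        post = apply_repetition(trips, rep)
        assert len(post) == len(trips)
        assert post["mode"].value_counts().sum() == len(trips)
        untouched = ~trips["trip_id"].isin(rep.converted["trip_id"])
        pd.testing.assert_frame_equal(post.loc[untouched],
                                      trips.loc[untouched],
                                      check_dtype=False, rtol=0, atol=0)


def test_multiplier_doubles_expected_conversions(survey_integrated,
                                                 likelihoods, duration_model,
                                                 tmvpa_model):
    _, trips = survey_integrated
    r1 = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                      _small_scenario(reps=40, mult=1, seed=2))
    r2 = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                      _small_scenario(reps=40, mult=2, seed=3))
    n1 = np.mean([len(r.converted) for r in r1.repetitions])
    n2 = np.mean([len(r.converted) for r in r2.repetitions])
    assert n2 / n1 == pytest.approx(2.0, rel=0.25)


def test_converted_counts_match_plan_expectation(survey_integrated,
                                                 likelihoods, duration_model,
                                                 tmvpa_model):
    _, trips = survey_integrated
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                       _small_scenario(reps=60, seed=8))
    plan = run.plan
    reps = len(run.repetitions)
    for mode, expected in plan.conversions.items():
        mean_count = np.mean([r.counts_by_destination()[mode]
                              for r in run.repetitions])
        frac = plan.selection_fraction[mode]
        n_cand = plan.candidate_count[mode]
        se = np.sqrt(n_cand * frac * (1 - frac) / reps)
        assert abs(mean_count - expected) <= 3 * se + 1


def test_complementary_candidates_exclude_destination(survey_integrated,
                                                      likelihoods,
                                                      duration_model,
                                                      tmvpa_model):
    _, trips = survey_integrated
    run = run_complementary(trips, likelihoods, duration_model, tmvpa_model,
                            "public_transport", 0.118, n_repetitions=10,
                            seed=4)
    for rep in run.repetitions:
        assert (rep.converted["old_mode"] != "public_transport").all()
        assert (rep.converted["new_mode"] == "public_transport").all()


def test_complementary_zero_increase_is_baseline(survey_integrated,
                                                 likelihoods, duration_model,
                                                 tmvpa_model):
    _, trips = survey_integrated
    run = run_complementary(trips, likelihoods, duration_model, tmvpa_model,
                            "walking", 0.0, n_repetitions=2, seed=1)
    assert all(len(r.converted) == 0 for r in run.repetitions)


def test_mode_counts_shift_in_expected_direction(survey_integrated,
                                                 likelihoods, duration_model,
                                                 tmvpa_model):
    _, trips = survey_integrated
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                       _small_scenario(reps=10, seed=9))
    before = trips["mode"].value_counts()
    post = apply_repetition(trips, run.repetitions[0])
    after = post["mode"].value_counts()
    assert after["private_motorized"] < before["private_motorized"]
    assert after["public_transport"] >= before["public_transport"]
    assert after.sum() == before.sum()
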