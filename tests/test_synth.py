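"""Generator: determinism, schema invariants, gradients, accelerometer."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from modeshift import synth
from modeshift.synth import (GeneratorConfig, GeneratorError, MvpaMechanism,
                             MVPA_CUTPOINT, count_mvpa_minutes,
                             emulate_accelerometer_minutes,
                             ground_truth_tmvpa)


def test_persons_deterministic_under_fixed_seed():
    cfg = GeneratorConfig(n_persons_survey=1000, seed=7)
    a = synth.generate_persons(cfg)
    b = synth.generate_persons(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_trips_deterministic_and_csv_identical(tmp_path):
    cfg = GeneratorConfig(n_persons_survey=200, n_persons_donor=20, seed=3)
    p1 = synth.write_datasets(cfg, tmp_path / "a")
    p2 = synth.write_datasets(cfg, tmp_path / "b")
    for key in ("survey", "donor"):
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_education_paris_gradient_matches_configured_shares():
    cfg = GeneratorConfig(n_persons_survey=20_000, seed=1)
    persons = synth.generate_persons(cfg)
    shares = persons.groupby("education")["residence_zone"].apply(
        lambda z: (z == "paris").mean())
    assert abs(shares["E3"] - 0.25) < 0.03
    assert abs(shares["E1"] - 0.06) < 0.03
    assert shares["E3"] > shares["E1"]


def test_invalid_configs_rejected():
    with pytest.raises(GeneratorError, match="person counts"):
        GeneratorConfig(n_persons_survey=0).validate()
    with pytest.raises(GeneratorError, match="sum to 1"):
        GeneratorConfig(mode_composition={
            "walking": 0.5, "bicycle": 0.5,
            "public_transport": 0.5, "private_motorized": 0.5}).validate()
    cfg = GeneratorConfig()
    with pytest.raises(GeneratorError):
        synth.generate_persons(cfg, n=0)


def test_trip_invariants_and_composition(small_survey, small_cfg):
    _, trips = small_survey
    assert (trips["duration_min"] >= 1).all()
    np.testing.assert_allclose(
        trips["speed_m_min"],
        trips["straight_line_distance_m"] / trips["duration_min"])
    rush = (((trips["departure_hour"] >= 8) & (trips["departure_hour"] < 11))
            | ((trips["departure_hour"] >= 16)
               & (trips["departure_hour"] < 19)))
    assert (trips["rush_hour"].astype(bool) == rush).all()
    freq = trips["mode"].value_counts(normalize=True)
    for mode, share in small_cfg.mode_composition.items():
        assert abs(freq.get(mode, 0.0) - share) < 0.04


def test_trip_count_scales_with_persons_and_rate():
    cfg = GeneratorConfig(n_persons_survey=2000, seed=5)
    persons, trips = synth.generate_survey(cfg)
    expected = 2000 * cfg.trips_per_day_survey
    assert abs(len(trips) - expected) < 4 * np.sqrt(expected)


def test_degenerate_composition_all_walking():
    cfg = GeneratorConfig(
        n_persons_survey=50, seed=2,
        mode_composition={"walking": 1.0, "bicycle": 0.0,
                          "public_transport": 0.0, "private_motorized": 0.0})
    _, trips = synth.generate_survey(cfg)
    assert (trips["mode"] == "walking").all()


def test_empty_person_collection_rejected():
    cfg = GeneratorConfig(n_persons_survey=10, seed=1)
    with pytest.raises(GeneratorError, match="empty"):
        synth.generate_trips(pd.DataFrame(), cfg)


def test_durations_and_distances_are_mode_dependent(small_survey):
    _, trips = small_survey
    med = trips.groupby("mode")["straight_line_distance_m"].median()
    assert med["walking"] < med["public_transport"] < med["private_motorized"]


def test_schema_parity_between_survey_and_donor(small_survey, small_donor):
    _, survey = small_survey
    _, donor = small_donor
    assert list(donor.columns) == list(survey.columns) + ["tmvpa_min"]


def test_tmvpa_bounds_hold_for_all_generated_trips(small_donor):
    _, donor = small_donor
    assert (donor["tmvpa_min"] >= 0).all()
    assert (donor["tmvpa_min"] <= donor["duration_min"]).all()


def _trip_row(mode="walking", duration=23, dist_pt=300.0):
    row = {"mode": mode, "duration_min": duration,
           "departure_dist_pt": dist_pt, "arrival_dist_pt": dist_pt}
    return pd.Series(row)


def test_bicycle_ground_truth_is_exact_duration():
    cfg = GeneratorConfig()
    rng = np.random.default_rng(0)
    assert ground_truth_tmvpa(_trip_row("bicycle", 23), cfg, rng) == 23.0


def test_ground_truth_clipped_to_duration():
    cfg = GeneratorConfig()
    rng = np.random.default_rng(0)
    for mode in ("walking", "public_transport", "private_motorized"):
        for _ in range(20):
            v = ground_truth_tmvpa(_trip_row(mode, 5), cfg, rng)
            assert 0.0 <= v <= 5.0


def test_zero_mechanism_yields_zero():
    mech = MvpaMechanism(pm_fraction=0.0, noise_sd=0.0)
    cfg = dataclasses.replace(GeneratorConfig(), mvpa=mech)
    rng = np.random.default_rng(0)
    assert ground_truth_tmvpa(
        _trip_row("private_motorized", 30), cfg, rng) == 0.0


def test_cutpoint_is_strictly_greater_than():
    assert count_mvpa_minutes([2690, 2691, 3000]) == 2
    assert count_mvpa_minutes([0, 0, 0]) == 0


def test_accelerometer_series_realizes_ground_truth():
    cfg = GeneratorConfig(seed=9)
    for mode, dur in [("walking", 18), ("public_transport", 40),
                      ("private_motorized", 25), ("bicycle", 12)]:
        # identical rng state for the mechanism draw and the emulation
        rng1 = np.random.default_rng(123)
        rng2 = np.random.default_rng(123)
        k = ground_truth_tmvpa(_trip_row(mode, dur), cfg, rng1)
        series, count = emulate_accelerometer_minutes(
            _trip_row(mode, dur), cfg, rng2)
        assert len(series) == dur
        assert count == k
        assert count == np.sum(np.asarray(series) > MVPA_CUTPOINT)


def test_accelerometer_rejects_zero_duration():
    cfg = GeneratorConfig()
    with pytest.raises(GeneratorError, match="at least 1 minute"):
        emulate_accelerometer_minutes(_trip_row("walking", 0), cfg,
                                      np.random.default_rng(0))
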