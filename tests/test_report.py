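"""Summary tables: additivity, intervals, strata oracles, inequality."""

import numpy as np
import pandas as pd
import pytest

from modeshift import report
from modeshift.features import MODES
from modeshift.report import (ReportError, inequality_delta,
                              summarize_baseline, summarize_gains)
from modeshift.scenario import Scenario
from modeshift.simulate import run_scenario


def _decomp(values: dict[int, list[float]]) -> pd.DataFrame:
    d = pd.DataFrame.from_dict(values, orient="index", columns=MODES)
    d.index.name = "person_id"
    d["total"] = d[MODES].sum(axis=1)
    return d


def _persons(education: dict[int, str]) -> pd.DataFrame:
    return pd.DataFrame({"person_id": list(education),
                         "education": list(education.values())})


def test_all_modes_equals_sum_of_mode_columns():
    decomp = _decomp({1: [5, 0, 3, 1], 2: [2, 1, 0, 0], 3: [0, 0, 0, 0]})
    persons = _persons({1: "E1", 2: "E2", 3: "E3"})
    table = summarize_baseline(decomp, persons)
    np.testing.assert_allclose(table.mean["all_modes"],
                               table.mean[MODES].sum(axis=1), atol=1e-9)


def test_identical_persons_give_zero_width_interval():
    decomp = _decomp({1: [5, 0, 3, 1], 2: [5, 0, 3, 1]})
    persons = _persons({1: "E1", 2: "E1"})
    # strata with no members are not meaningful here; use E1-only oracle
    with pytest.raises(ReportError):
        summarize_baseline(decomp, persons)  # E2/E3 empty


def test_baseline_interval_zero_width_for_identical_values():
    decomp = _decomp({1: [5, 0, 3, 1], 2: [5, 0, 3, 1], 3: [5, 0, 3, 1]})
    persons = _persons({1: "E1", 2: "E2", 3: "E3"})
    t = summarize_baseline(decomp, persons)
    assert np.allclose(t.lo.to_numpy(dtype=float),
                       t.hi.to_numpy(dtype=float))


def test_stratum_means_match_group_by_oracle(survey_integrated):
    persons, trips = survey_integrated
    decomp = trips.groupby("person_id").apply(
        lambda g: pd.Series({m: g.loc[g["mode"] == m, "tmvpa_min"].sum()
                             for m in MODES}), include_groups=False)
    decomp = decomp.reindex(persons["person_id"], fill_value=0.0)
    decomp["total"] = decomp[MODES].sum(axis=1)
    table = summarize_baseline(decomp, persons)
    edu = persons.set_index("person_id")["education"]
    for e in ("E1", "E2", "E3"):
        oracle = decomp.loc[edu.reindex(decomp.index) == e, "total"].mean()
        assert table.mean.loc[e, "all_modes"] == pytest.approx(oracle,
                                                               abs=1e-12)
    assert table.mean.loc["total", "all_modes"] == pytest.approx(
        decomp["total"].mean(), abs=1e-12)


def test_missing_education_rejected():
    decomp = _decomp({1: [1, 0, 0, 0], 2: [1, 0, 0, 0]})
    persons = pd.DataFrame({"person_id": [1, 2],
                            "education": ["E1", None]})
    with pytest.raises(ReportError, match="education"):
        summarize_baseline(decomp, persons)


def test_gains_zero_under_null_scenario(survey_integrated, likelihoods,
                                        duration_model, tmvpa_model):
    persons, trips = survey_integrated
    sc = Scenario(destination_increases={"public_transport": 0.0,
                                         "walking": 0.0, "bicycle": 0.0},
                  n_repetitions=3, seed=1)
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model, sc,
                       person_ids=persons["person_id"])
    gains = summarize_gains(run, persons)
    assert np.allclose(gains.mean.to_numpy(dtype=float), 0.0, atol=1e-12)


def test_gains_additive_across_modes(survey_integrated, likelihoods,
                                     duration_model, tmvpa_model):
    persons, trips = survey_integrated
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                       Scenario(n_repetitions=10, seed=2),
                       person_ids=persons["person_id"])
    gains = summarize_gains(run, persons)
    np.testing.assert_allclose(gains.mean["all_modes"],
                               gains.mean[MODES].sum(axis=1), atol=1e-9)


def test_gains_intervals_contain_means(survey_integrated, likelihoods,
                                       duration_model, tmvpa_model):
    persons, trips = survey_integrated
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                       Scenario(n_repetitions=30, seed=3),
                       person_ids=persons["person_id"])
    gains = summarize_gains(run, persons)
    assert (gains.lo.to_numpy(dtype=float)
            <= gains.mean.to_numpy(dtype=float) + 1e-12).all()
    assert (gains.mean.to_numpy(dtype=float)
            <= gains.hi.to_numpy(dtype=float) + 1e-12).all()


def test_gains_match_direct_per_rep_oracle(survey_integrated, likelihoods,
                                           duration_model, tmvpa_model):
    """The incremental stratum aggregation must equal recomputing each
    repetition's decomposition from scratch."""
    persons, trips = survey_integrated
    run = run_scenario(trips, likelihoods, duration_model, tmvpa_model,
                       Scenario(n_repetitions=5, seed=4),
                       person_ids=persons["person_id"])
    gains = summarize_gains(run, persons)
    edu = persons.set_index("person_id")["education"]
    base = run.baseline_decomp
    oracle = np.zeros(len(run.repetitions))
    for i in range(len(run.repetitions)):
        d = run.rep_decomposition(i)
        oracle[i] = d["total"].mean() - base["total"].mean()
    assert gains.mean.loc["total", "all_modes"] == pytest.approx(
        oracle.mean(), abs=1e-9)
    # one stratum as well
    e3 = edu.reindex(base.index) == "E3"
    oracle_e3 = np.mean([
        run.rep_decomposition(i).loc[e3.to_numpy(), "total"].mean()
        - base.loc[e3.to_numpy(), "total"].mean()
        for i in range(len(run.repetitions))])
    assert gains.mean.loc["E3", "all_modes"] == pytest.approx(oracle_e3,
                                                              abs=1e-9)


def test_inequality_delta_trivial_cases():
    idx = ["total", "E1", "E2", "E3"]
    cols = ["all_modes"] + MODES
    flat = pd.DataFrame(1.0, index=idx, columns=cols)
    base = report.SummaryTable(flat, flat, flat)
    gains = report.SummaryTable(flat * 0.0, flat * 0.0, flat * 0.0)
    d = inequality_delta(base, gains)
    assert d.baseline_gap == 0.0 and d.gain_gap == 0.0 and not d.amplified

    g2 = flat * 0.0
    g2.loc["E3", "all_modes"] = 0.5
    g2.loc["E1", "all_modes"] = 0.2
    d2 = inequality_delta(base, report.SummaryTable(g2, g2, g2))
    assert d2.gain_gap == pytest.approx(0.3)
    assert d2.amplified
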