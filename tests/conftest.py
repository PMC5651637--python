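"""Shared fixtures: a small synthetic survey/donor pair and fitted models.

Session-scoped so the forests are fitted once; sizes are kept small
(hundreds of persons) — large-sample behavior is exercised in the
acceptance suite.
"""

from __future__ import annotations

import pytest

from modeshift import integrate, likelihood, simulate, synth


@pytest.fixture(scope="session")
def small_cfg() -> synth.GeneratorConfig:
    return synth.GeneratorConfig(n_persons_survey=700, n_persons_donor=60,
                                 seed=7)


@pytest.fixture(scope="session")
def small_survey(small_cfg):
    persons, trips = synth.generate_survey(small_cfg)
    return persons, trips


@pytest.fixture(scope="session")
def small_donor(small_cfg):
    persons, trips = synth.generate_donor(small_cfg)
    return persons, trips


@pytest.fixture(scope="session")
def tmvpa_model(small_donor):
    _, donor = small_donor
    return integrate.fit_tmvpa_model(donor, n_estimators=150, random_state=1)


@pytest.fixture(scope="session")
def survey_integrated(small_survey, tmvpa_model):
    persons, trips = small_survey
    trips = trips.copy()
    trips["tmvpa_min"] = integrate.predict_tmvpa(tmvpa_model, trips)
    return persons, trips


@pytest.fixture(scope="session")
def mode_model(survey_integrated):
    _, trips = survey_integrated
    return likelihood.fit_mode_model(trips, n_estimators=250,
                                     random_state=2)


@pytest.fixture(scope="session")
def likelihoods(mode_model, survey_integrated):
    _, trips = survey_integrated
    return likelihood.extract_oob_likelihoods(mode_model, trips)


@pytest.fixture(scope="session")
def duration_model(survey_integrated):
    _, trips = survey_integrated
    return simulate.fit_duration_model(trips, n_estimators=80,
                                       random_state=3)
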