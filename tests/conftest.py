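import numpy as np
import pytest

import foodsec as fs


@pytest.fixture(scope="session")
def small_survey() -> fs.SurveyDataset:
    """4 regions x 2 years x 150 households, full baskets."""
    cfg = fs.ScenarioConfig(n_regions=4, years=(2014, 2015),
                            households_per_stratum=150, seed=11)
    return fs.generate_survey(cfg)


@pytest.fixture(scope="session")
def scored(small_survey):
    return fs.score_households(small_survey.consumption,
                               small_survey.composition,
                               small_survey.members,
                               small_survey.ae_table)


@pytest.fixture(scope="session")
def hdds_frame(small_survey):
    return fs.hdds_scores(small_survey.consumption,
                          small_survey.households["household_id"])


@pytest.fixture(scope="session")
def model_matrix(small_survey, scored, hdds_frame):
    return fs.build_model_matrix(small_survey.households, small_survey.members,
                                 scored, hdds_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
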