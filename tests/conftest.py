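"""Shared fixtures: one synthetic world, generated once per session."""

import pandas as pd
import pytest

from damburden.synthetic import (
    default_ground_truth,
    generate_examination_survey,
    generate_interview_survey,
    generate_population,
)


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def exam_survey(truth) -> pd.DataFrame:
    """Examination survey at the recovery-test size."""
    return generate_examination_survey(truth, 20_000, seed=101)


@pytest.fixture(scope="session")
def interview_survey(truth) -> pd.DataFrame:
    return generate_interview_survey(truth, 50_000, seed=202)


@pytest.fixture(scope="session")
def small_exam(truth) -> pd.DataFrame:
    """Cheaper survey for structural tests that do not need precision."""
    return generate_examination_survey(truth, 3_000, seed=11)


@pytest.fixture(scope="session")
def small_interview(truth) -> pd.DataFrame:
    return generate_interview_survey(truth, 6_000, seed=12)


@pytest.fixture(scope="session")
def population(truth) -> pd.DataFrame:
    return generate_population(truth)
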