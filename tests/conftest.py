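import logging

import pytest

import postopsat as pos

# the cutpoint clamp for cells targeting a Likert mean of exactly 5 is
# expected and would otherwise flood the test logs
logging.getLogger("postopsat.synthetic").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    return pos.default_config(seed=1824)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One study-calibrated cohort shared across the suite (4018 records)."""
    return pos.generate_cohort(default_config)


@pytest.fixture(scope="session")
def retained_cohort(default_cohort):
    retained, _, _ = pos.apply_exclusion(default_cohort)
    return retained


def make_record(**overrides) -> pos.QuestionnaireRecord:
    """A fully answered operated respondent; keyword overrides per field."""
    base = dict(
        year=2021,
        ward="urology",
        age=50.0,
        gender="female",
        residence="rural",
        education="secondary",
        q1_surgery="yes",
        q2_postop_care=4,
        q3_overall=5,
        infection="no",
        complication="no",
        protocol="standard",
        innovation="no",
        pain=2,
    )
    base.update(overrides)
    return pos.QuestionnaireRecord(**base)
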