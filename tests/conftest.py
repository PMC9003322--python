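"""Shared fixtures: the default truth and reusable synthetic cohorts.

Expensive cohorts (scale 20 for calibration checks, the attrition cohort
for bookkeeping checks) are session-scoped so every module shares one
generation.
"""

import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from mmdnet import (  # noqa: E402
    apply_missingness,
    assemble_analysis_table,
    default_truth,
    generate_cohort,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def attrition_cohort(truth):
    """Scale-1 cohort at blood-draw totals with the configured missingness."""
    cohort = generate_cohort(truth, 1.0, seed=7, attrition=True)
    cohort.blood_table = apply_missingness(cohort.blood_table, truth, seed=8)
    return cohort


@pytest.fixture(scope="session")
def analysis_table(attrition_cohort):
    table, dropped = assemble_analysis_table(attrition_cohort)
    return table


@pytest.fixture(scope="session")
def scale20_cohort(truth):
    return generate_cohort(truth, 20.0, seed=1)


@pytest.fixture(scope="session")
def scale20_table(scale20_cohort):
    table, _ = assemble_analysis_table(scale20_cohort)
    return table
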