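import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

import sleresponse as sr


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient generated cohort with follow-ups and ground truth."""
    cohort, truth = sr.generate_cohort(sr.GeneratorConfig(n_patients=300, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def labelled_mcr(small_cohort):
    cohort, _ = small_cohort
    pairs = sr.build_inception_cohort(cohort)
    return sr.label_outcomes(pairs, "mcr")
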