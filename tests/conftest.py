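import pytest

from hifuseg.synthetic import (AcquisitionProtocol, CohortDesign,
                               LesionSettings, generate_cohort)


@pytest.fixture(scope="session")
def small_protocol():
    """Scaled-down acquisition grid for fast unit tests."""
    return AcquisitionProtocol(shape=(32, 32, 6))


@pytest.fixture(scope="session")
def small_cohort(small_protocol):
    """A small but complete longitudinal cohort with raw noisy series."""
    design = CohortDesign(n_treated=4, n_treated_72h=2, n_control=2)
    lesions = LesionSettings(fractions_1h=(0.15, 0.3, 0.2, 0.35))
    return generate_cohort(design, small_protocol, lesions=lesions, seed=11)
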