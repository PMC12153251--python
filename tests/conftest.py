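import pytest

from futilitykit import DesignSpec, LookSchedule


@pytest.fixture
def design_85():
    return DesignSpec(alpha_one_sided=0.025, power=0.85)


@pytest.fixture
def design_90():
    return DesignSpec(alpha_one_sided=0.025, power=0.90)


@pytest.fixture
def four_looks():
    return LookSchedule.equally_spaced(4)


@pytest.fixture
def lume_schedule():
    """Interim looks at 10%..70% of events plus the final analysis."""
    return LookSchedule([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 1.0])
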