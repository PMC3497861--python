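import pytest

from lungbench import VentilatorSettings, build_point_system


@pytest.fixture
def pattern_20():
    """1000 ml at 20/min, I:E = 1/2 (the high-minute-ventilation bench pattern)."""
    return VentilatorSettings(tidal_volume=1.0, rate=20.0, ie_ratio=0.5)


@pytest.fixture
def pattern_6():
    """500 ml at 12/min, I:E = 1/2 (the low-minute-ventilation bench pattern)."""
    return VentilatorSettings(tidal_volume=0.5, rate=12.0, ie_ratio=0.5)


@pytest.fixture
def make_system():
    """Factory for grid-point lung systems (fresh instance per call)."""
    return build_point_system
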