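import pytest

from gravitropism import wheat_calibration


@pytest.fixture(scope="session")
def wheat():
    """Calibrated wheat-coleoptile parameter set."""
    return wheat_calibration()
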