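import pytest

from baitline import synthetic_field as sf


@pytest.fixture(scope="session")
def small_operation():
    """One complete synthetic operation on a 60-ha block (fast, shared)."""
    config = sf.SimConfig(area_ha=60.0)
    return config, sf.run_operation(config, seed=7)
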