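import numpy as np
import pytest

from rosettrack import Environment, GenotypeSpec, GrowthParams


@pytest.fixture(scope="session")
def chamber_env():
    """Three weeks of the growth-chamber photoperiod (8 h light)."""
    return Environment.constant_photoperiod(504)


@pytest.fixture(scope="session")
def default_params():
    return GrowthParams()


@pytest.fixture(scope="session")
def small_scene():
    """A small no-jitter rosette sequence used by several suites."""
    from rosettrack import render_sequence

    spec = GenotypeSpec(seed=42, n_days=13, canvas=(640, 640),
                        phyllotaxy_jitter_sd_deg=0.0,
                        rotation_jitter_sd_deg=0.0)
    return render_sequence(spec)
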