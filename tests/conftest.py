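import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eitpose import io as eio
from eitpose import sim

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def roi():
    return eio.default_roi_mask()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, cardiac-free healthy configuration for exact checks."""
    return sim.SimConfig(
        seed=0, injury_severity=0.0, noise_sd=0.0, cardiac_amplitude=0.0
    )


def render_breathing(model, config, duration=30.0, vent=None, **kw):
    vent = vent or sim.VentSettings()
    seg = sim.Segment(model, vent, sim.SUPINE, duration, kind="breathing")
    return sim.render_frames([seg], config, **kw)


@pytest.fixture(scope="session")
def quick_sequence(quiet_config, roi):
    """A short noise-free healthy render shared by read-only tests."""
    model = sim.build_lung_model(quiet_config, roi)
    return render_breathing(model, quiet_config, duration=20.0)
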