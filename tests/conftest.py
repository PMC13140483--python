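import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def windkessel_beat():
    """One noise-free windkessel pressure/flow cycle at 1 kHz."""
    import hemopulse as hp

    params = hp.WindkesselParams(
        zc=0.1, r_peripheral=1.0, compliance=1.5, heart_rate=60,
        stroke_volume=70, sampling_rate=1000, n_beats=3, noise_sd=0.0,
    )
    pressure, flow = hp.simulate_windkessel(params)
    n = pressure.meta["samples_per_beat"]
    beat = hp.EnsembleBeat(pressure.values[:n], 1000.0, units="mmHg")
    fb = hp.FlowBeat(flow.values[:n], 1000.0, diastolic_diameter=6.0,
                     cross_sectional_area=float(np.pi * 0.09))
    return params, beat, fb
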