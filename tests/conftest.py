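import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def uniform_trace():
    """Factory for uniformly sampled traces: f(values_fn, duration, dt)."""
    from lucisync.traces import BioluminescenceTrace

    def make(values, duration=120.0, dt=1 / 6, zt0_offset=0.0):
        t = np.arange(0.0, duration + 1e-9, dt)
        vals = values(t) if callable(values) else np.asarray(values, dtype=float)
        return BioluminescenceTrace(t, vals, zt0_offset)

    return make


@pytest.fixture(scope="session")
def gestation_sims():
    """Full simulated in utero study (6 circadian + 1 arrhythmic dams)."""
    from lucisync.synth import gestation_study
    return gestation_study(seed=0)


@pytest.fixture(scope="session")
def gestation_report(gestation_sims):
    from lucisync.pipeline import AnalysisConfig, run_inutero
    stacks = {d: s.stack for d, s in gestation_sims.items()}
    return run_inutero(stacks, AnalysisConfig(gaussian_sigma=0.0, seed=0))
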