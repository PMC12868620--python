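import numpy as np
import pytest

from electroperm.synthetic import GeneratorConfig
from electroperm.traces import FluorescenceTrace


@pytest.fixture
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=42)


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    """All stochastic knobs at zero: generators emit exact model output."""
    return GeneratorConfig(
        seed=0,
        trace_noise_sd=0.0,
        replicate_cv=0.0,
        swell_cv=0.0,
        swell_trace_noise=0.0,
        cell_area_cv=0.0,
        map_cv=0.0,
        spheroid_modulus_cv=0.0,
        deflection_noise_m=0.0,
        correlation_noise_scale=0.0,
    )


def make_uptake_trace(
    amplitude: float = 100.0,
    tau: float = 130.0,
    t0: float = 10.0,
    dt: float = 3.0,
    t_end: float = 180.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **meta,
) -> FluorescenceTrace:
    """Noise-optional saturating-exponential trace on a uniform grid."""
    times = np.arange(0.0, t_end + dt / 2, dt)
    values = np.full_like(times, baseline)
    post = times >= t0
    values[post] += amplitude * -np.expm1(-(times[post] - t0) / tau)
    if noise_sd > 0:
        values = values + (rng or np.random.default_rng(0)).normal(0, noise_sd, times.shape)
    return FluorescenceTrace(times=times, values=values, exposure_time=t0, meta=meta)
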