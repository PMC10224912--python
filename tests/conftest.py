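import pytest

import lightpatch as lp


@pytest.fixture(scope="session")
def device():
    return lp.default_device()


@pytest.fixture(scope="session")
def small_spec():
    return lp.EmissionSpec(n_rays=20_000, seed=42)


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels(device):
    """Trigger numba compilation once so per-test timings stay honest."""
    spec = lp.EmissionSpec(n_rays=64, seed=0)
    bundle = lp.sample_emission(spec, (0.0, 0.0, -device.gap.d))
    lp.simulate_device(device, spec)
    del bundle
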