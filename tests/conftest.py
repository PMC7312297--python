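import numpy as np
import pytest

from epibarrier.synthetic import StackSpec, flat_surface, generate_confocal_stack


@pytest.fixture(scope="session")
def flat_stack_rho2():
    """Noise-free stack with a flat surface and membrane enrichment 2."""
    spec = StackSpec(
        nx=32, ny=32, nz=40, surface_um=flat_surface(32, 32, 1.0),
        enrichment=2.0, noise_sd=0.0,
    )
    return generate_confocal_stack(spec)


@pytest.fixture(scope="session")
def noisy_stack_suite():
    """Small suite of seeded stacks with undulating surfaces and noise."""
    out = []
    for seed in (0, 1, 2):
        spec = StackSpec(nx=48, ny=48, nz=40, enrichment=1.5, noise_sd=10.0, seed=seed)
        out.append(generate_confocal_stack(spec))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
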