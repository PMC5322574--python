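import numpy as np
import pytest

from renalseg import PhantomSpec, VoxelGrid, generate_cohort

# 32^3 lattice with the same physical extent as the default grid: keeps the
# default kidney geometry valid while making pipeline tests cheap.
SMALL_DIMS = (32, 32, 32)
SMALL_SPACING = (1.28, 1.28, 1.8)


def small_spec(**overrides) -> PhantomSpec:
    kwargs = dict(dims=SMALL_DIMS, spacing=SMALL_SPACING)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def unit_grid8() -> VoxelGrid:
    return VoxelGrid(dims=(8, 8, 8), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """Three small synthetic subjects at default difficulty."""
    return generate_cohort(small_spec(), 3, master_seed=5)


@pytest.fixture(scope="session")
def easy_cohort():
    """Degenerate, noise/bias/deformation-free cohort: trivially separable."""
    spec = small_spec(noise_sd=0.0, bias_amplitude=0.0, deformation_mm=0.0, distractor_count=0)
    return generate_cohort(spec, 3, master_seed=5)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
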