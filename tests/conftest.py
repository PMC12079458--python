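import pytest

from aggrekin.simulate import (
    GrowthModel,
    ImagingModel,
    simulate_aggregate,
    benchmark_field_of_view,
)


@pytest.fixture(scope="session")
def benchmark_fov():
    """One benchmark field of view (three archetypes + touching pair)."""
    return benchmark_field_of_view(seed=1)


@pytest.fixture(scope="session")
def isotropic_acquisition():
    model = GrowthModel("isotropic", rx=4000.0)
    imaging = ImagingModel(seed=7, n_frames=180, binding_rate_per_area=5e-6)
    return simulate_aggregate(model, imaging, origin=(20_000.0, 20_000.0))
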