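import numpy as np
import pytest

from ctrkit.phantom import PhantomGeometry, PopulationSpec, generate_population
from ctrkit.segmentation import TrainConfig, UNetConfig, build_model, train


@pytest.fixture(scope="session")
def small_geometry() -> PhantomGeometry:
    return PhantomGeometry(image_size=64)


@pytest.fixture(scope="session")
def small_population(small_geometry):
    spec = PopulationSpec(n_normal=10, n_cardiomegaly=10, seed=123)
    return generate_population(spec, small_geometry)


@pytest.fixture(scope="session")
def benchmark_split(small_geometry):
    """100 training + 30 held-out phantoms for the segmentation benchmark."""
    spec = PopulationSpec(n_normal=65, n_cardiomegaly=65, seed=11)
    cases = generate_population(spec, small_geometry)
    return cases[:100], cases[100:130]

@pytest.fixture(scope="session")
def trained_model(benchmark_split):
    """Reduced-preset network trained once per session on the benchmark split."""
    train_cases, _ = benchmark_split
    model = build_model(UNetConfig(input_size=64, encoder_stages=3, base_channels=8, seed=0))
    history = train(model, train_cases, TrainConfig(epochs=10, seed=0))
    assert np.isfinite(history).all()
    return model
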