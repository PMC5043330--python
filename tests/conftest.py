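import numpy as np
import pytest

from rdhybrid import (
    CompartmentGrid,
    ReactionDiffusionModel,
    ReactionSpec,
    SpeciesSpec,
    SystemState,
    build_example,
)


@pytest.fixture(scope="session")
def example1_small():
    """Scaled example-I morphogen model (K=20) for fast structural tests."""
    return build_example("example1", K=20, D_M=40.0)


@pytest.fixture()
def two_compartment_diffusion():
    model = ReactionDiffusionModel(
        species=[SpeciesSpec("X", diffusion_coefficient=10.0, lambda_scale=100.0)],
        grid=CompartmentGrid(extent=(2,), spacing=1.0),
        name="two-compartment",
    )
    initial = SystemState(np.array([[200], [0]], dtype=np.int64))
    return model, initial


@pytest.fixture()
def birth_death_model():
    model = ReactionDiffusionModel(
        species=[SpeciesSpec("X", 0.0, lambda_scale=1e3)],
        grid=CompartmentGrid(extent=(1,), spacing=1.0),
        reactions=[
            ReactionSpec({}, {"X": 1}, 1e-2, name="birth"),
            ReactionSpec({"X": 1}, {}, 1e-1, name="death"),
        ],
        name="birth-death",
    )
    initial = SystemState(np.array([[100]], dtype=np.int64))
    return model, initial
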