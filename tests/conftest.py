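import numpy as np
import pytest

from pyrocal import GridSpec, SyntheticSpec, curves_to_matrix
from pyrocal.synthetic import (
    generate_composition,
    generate_dtg_curves,
    measure_composition,
)

COARSE = GridSpec(105.0, 900.0, 1.0)


@pytest.fixture(scope="session")
def coarse_grid() -> GridSpec:
    return COARSE


@pytest.fixture(scope="session")
def small_study():
    """A 60-sample default-panel study on a 1 °C grid, generated once."""
    spec = SyntheticSpec(n_samples=60, grid=COARSE, seed=2024)
    truth = generate_composition(spec)
    curves = generate_dtg_curves(truth, spec)
    measured = measure_composition(truth, spec)
    X, temps, ids = curves_to_matrix(curves)
    return {
        "spec": spec,
        "truth": truth,
        "measured": measured,
        "curves": curves,
        "X": X,
        "temps": temps,
        "ids": ids,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
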