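import numpy as np
import pandas as pd
import pytest

from venomtherm import synthdata
from venomtherm.containers import BandMatrix


@pytest.fixture
def default_band_sim():
    """Default study-design band matrix plus its truth table."""
    spec = synthdata.BandSimSpec(seed=11)
    matrix, truth = synthdata.simulate_band_matrix(spec)
    return spec, matrix, truth


@pytest.fixture
def small_matrix():
    """A small hand-controllable matrix: 12 individuals x 4 bands."""
    rng = np.random.default_rng(5)
    idx = pd.Index([f"i{k}" for k in range(12)], name="individual_id")
    meta = pd.DataFrame(
        {
            "line": "ISm",
            "temperature": np.repeat([20.0, 25.0, 30.0], 4),
            "replicate": ["r1", "r1", "r2", "r2"] * 3,
        },
        index=idx,
    )
    vals = rng.uniform(10, 100, size=(12, 4))
    bands = [f"band_{b}" for b in range(4)]
    return BandMatrix(pd.DataFrame(vals, index=idx, columns=bands), meta)


def make_matrix(values, temperatures, replicates):
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"i{k}" for k in range(len(values))], name="individual_id")
    meta = pd.DataFrame(
        {"line": "ISm", "temperature": temperatures, "replicate": replicates},
        index=idx,
    )
    bands = [f"band_{b}" for b in range(values.shape[1])]
    return BandMatrix(pd.DataFrame(values, index=idx, columns=bands), meta)
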