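import numpy as np
import pytest

from methkit.calls import MethylationDataset
from methkit.simulate import (SimulationConfig, TOY_CPG_POSITIONS,
                              TOY_PATTERN, simulate_experiment)

#: the 4-clone x 5-site demonstration matrix: clones 1-2 methylated at
#: sites 1-2 only, clone 3 at sites 3-4, clone 4 at sites 3-5
TOY_MATRIX = np.array(TOY_PATTERN, dtype=float)


@pytest.fixture(scope="session")
def toy_dataset() -> MethylationDataset:
    """The demonstration dataset built directly from its description."""
    return MethylationDataset(
        clone_ids=[f"clone{i}" for i in range(1, 5)],
        cpg_positions=list(TOY_CPG_POSITIONS),
        calls=TOY_MATRIX.copy(),
        spans=[(1, 100)] * 4,
        reference_id="toy",
    )


@pytest.fixture(scope="session")
def toy_experiment():
    """Noise-free simulated experiment with the demonstration geometry."""
    return simulate_experiment(SimulationConfig(seed=42))
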