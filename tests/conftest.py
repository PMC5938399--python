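import numpy as np
import pytest

from projquant import (
    MorphologyBuilder,
    SyntheticCohortSpec,
    default_region_model,
    generate_cohort,
)
from projquant.morphology import AXON, BASAL_DENDRITE, ROOT_PARENT, SOMA


@pytest.fixture(scope="session")
def model():
    return default_region_model()


@pytest.fixture(scope="session")
def cohort(model):
    """Planted 6 S2p + 9 M1p cohort reused across the suite (seed fixed)."""
    return generate_cohort(SyntheticCohortSpec(rng_seed=1), model)


def random_tree(
    n_nodes: int = 200,
    seed: int = 0,
    span_mm: float = 0.4,
    neuron_id: str = "random",
):
    """A random valid reconstruction: soma root plus mixed axon/dendrite tree."""
    rng = np.random.default_rng(seed)
    b = MorphologyBuilder(neuron_id)
    b.add_node(ROOT_PARENT, SOMA, (-3.0, -1.6, 0.3), radius_um=6.0)
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        node_type = AXON if rng.random() < 0.6 else BASAL_DENDRITE
        if parent == 0:
            pos = np.array([-3.0, -1.6, 0.3])
        else:
            pos = b._xyz[parent]
        step = rng.normal(0.0, span_mm / 10.0, size=3)
        new = np.array(pos) + step
        new[2] = abs(new[2])  # stay below the pia
        b.add_node(parent, node_type, new, radius_um=float(rng.uniform(0.3, 2)))
    return b.build()
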