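import numpy as np
import pytest

import mranet as m


def well_conditioned_R(n: int, seed: int) -> m.GlobalResponseMatrix:
    """Random dense matrix shifted to be comfortably invertible."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, n)) + 2.0 * np.sqrt(n) * np.eye(n)
    return m.GlobalResponseMatrix(values, [f"M{i}" for i in range(n)])


@pytest.fixture
def small_dataset() -> m.PerturbationDataset:
    """Tiny hand-written positive-abundance dataset (3 modules)."""
    return m.PerturbationDataset(
        ["g1", "g2", "g3"],
        basal=[1.0, 2.0, 4.0],
        perturbed=[[3.0, 1.0, 1.0], [2.0, 0.0, 2.0], [4.0, 4.0, 2.0]],
    )


@pytest.fixture
def small_network() -> m.GroundTruthNetwork:
    return m.generate_topology(5, 5, 1.5, seed=7)


@pytest.fixture
def reference_from(small_network):
    truth = small_network.edge_frame()
    pairs = {}
    for row in truth.itertuples():
        a, b = sorted((row.regulator, row.target))
        pairs[(a, b)] = 1.0
    return m.ReferenceNetwork(pairs, list(small_network.module_ids))


def ground_truth_reference(net: m.GroundTruthNetwork) -> m.ReferenceNetwork:
    pairs = {}
    for row in net.edge_frame().itertuples():
        a, b = sorted((row.regulator, row.target))
        pairs[(a, b)] = 1.0
    return m.ReferenceNetwork(pairs, list(net.module_ids))
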