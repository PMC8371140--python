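import numpy as np
import pytest

from organoidbench import de, reference
from organoidbench.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One seeded run of the full default generator, shared across tests."""
    cfg = SimulationConfig(seed=11)
    design, truth, bulk, cells, labels = simulate_study(cfg)
    return cfg, design, truth, bulk, cells, labels


@pytest.fixture(scope="session")
def normalized_bulk(default_study):
    _, _, _, bulk, _, _ = default_study
    return de.normalized_frame(bulk)


@pytest.fixture(scope="session")
def normalized_cells(default_study):
    _, _, _, _, cells, _ = default_study
    return reference.normalize_cells(cells)


@pytest.fixture(scope="session")
def planted_signature(default_study, normalized_cells):
    """Signature built from the true cell-type labels and planted markers."""
    _, _, truth, _, _, labels = default_study
    return reference.build_signature(
        normalized_cells,
        np.asarray(labels),
        {t: list(g) for t, g in truth.marker_genes.items()},
        type_order=tuple(truth.marker_genes),
    )
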