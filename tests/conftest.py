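import numpy as np
import pytest

import sdcorr as s


def box_mask(occ, spacing=50.0, origin=(0.0, 0.0, 0.0)):
    """Small VoxelMask helper from a 3D 0/1 array."""
    return s.VoxelMask(np.asarray(origin, float), np.full(3, spacing),
                       np.asarray(occ, bool))


@pytest.fixture(scope="session")
def small_dataset():
    """600-cell planted-structure dataset (seed 1) shared across tests."""
    cfg = s.SyntheticConfig.small(rng_seed=1)
    cells, injections, ontology, truth = s.generate_dataset(cfg)
    return cfg, cells, injections, ontology, truth


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    cfg, cells, injections, ontology, truth = small_dataset
    result = s.run_pipeline(cells, injections, ontology,
                            s.AnalysisConfig(rng_seed=1))
    return result, truth, ontology
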