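import numpy as np
import pytest

from erpmicro.inverse import build_grid, leadfield
from erpmicro.montage import gen_montage, standard_montage_110
from erpmicro.synth import gen_erp_dataset, gen_templates, make_ground_truth


@pytest.fixture(scope="session")
def montage110():
    return standard_montage_110()


@pytest.fixture(scope="session")
def montage128():
    return gen_montage(128, seed=7)


@pytest.fixture(scope="session")
def grid300():
    return build_grid(300)


@pytest.fixture(scope="session")
def lf300(montage110, grid300):
    return leadfield(montage110, grid300)


@pytest.fixture(scope="session")
def templates3(montage110, grid300):
    maps, dipoles = gen_templates(3, montage110, grid300, seed=3)
    return maps, dipoles


@pytest.fixture(scope="session")
def two_condition_truth(templates3):
    """Shared map 0 flanking condition-specific maps 1 / 2, SNR 5."""
    maps, dipoles = templates3
    return make_ground_truth(
        maps, dipoles,
        condition_sequences=[[0, 1, 0], [0, 2, 0]],
        noise_sd=1.0, gfp_amplitude=5.0,
    )


@pytest.fixture(scope="session")
def two_condition_dataset(two_condition_truth):
    erps, effects = gen_erp_dataset(two_condition_truth, n_subjects=15, seed=11)
    return erps, effects


def match_templates(found: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Map each recovered template to its best-correlated ground-truth index."""
    sim = np.abs(found @ truth.T)
    return np.argmax(sim, axis=1)
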