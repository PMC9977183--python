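import numpy as np
import pytest

from morphollr import procrustes, synthetic
from morphollr.io import assemble_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study: 25 species (8 intraspecific),
    10 landmarks, full ground truth."""
    configs, taxa, tree, truth, means, log_cs = synthetic.generate_study(
        n_species=25,
        n_intraspecific=8,
        specimens_range=(27, 32),
        background_range=(3, 8),
        p_landmarks=10,
        seed=2024,
    )
    study = assemble_study(configs, taxa, tree, min_n=27)
    return {
        "configs": configs,
        "taxa": taxa,
        "tree": tree,
        "truth": truth,
        "means_true": means,
        "log_cs_true": log_cs,
        "study": study,
    }


@pytest.fixture(scope="session")
def small_gpa(small_study):
    return procrustes.gpa(small_study["configs"])


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_psd(rng: np.random.Generator, k: int, scale: float = 1.0) -> np.ndarray:
    A = rng.standard_normal((k, k + 2))
    return scale * A @ A.T / (k + 2)
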