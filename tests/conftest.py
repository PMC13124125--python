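import numpy as np
import pytest

from dlam.pipeline import FeatureConfig, build_dataset
from dlam.synthetic_data import StudyConfig, generate_study, worked_micro_example, write_study


@pytest.fixture(scope="session")
def micro():
    """The fixed 3-protein / 2-domain worked example."""
    return worked_micro_example()


@pytest.fixture(scope="session")
def small_study():
    """A 300-protein study with planted signal, generated once per session."""
    return generate_study(StudyConfig(n_proteins=300, n_domains=80, seed=11))


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    write_study(small_study, d)
    return d


@pytest.fixture(scope="session")
def small_dataset(small_study_dir):
    """Assembled dataset for the session study (fast autoencoder settings)."""
    dataset, artifacts = build_dataset(
        small_study_dir, FeatureConfig(sae_epochs=150, seed=11)
    )
    return dataset, artifacts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
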