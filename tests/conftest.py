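"""Shared fixtures: seeded libraries, calibrations and study bundles."""

import numpy as np
import pytest

from cofactorscope.similarity import calibrate_null
from cofactorscope.study import CofactorStudy
from cofactorscope.synthetic import SyntheticConfig, generate_pwm_library, simulate_study


@pytest.fixture(scope="session")
def library60():
    return generate_pwm_library(60, seed=1)


@pytest.fixture(scope="session")
def calib60(library60):
    return calibrate_null(library60, n_null=2000, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A three-line study small enough for cheap unit tests."""
    return SyntheticConfig(
        n_cell_lines=3,
        library_size=20,
        motifs_per_line=8,
        n_true_cofactors=4,
        n_modules_per_line=10,
        module_size_range=(2, 4),
        n_genes=120,
        n_go_terms=12,
        n_decoy_proteins=10,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_calib(small_bundle):
    return calibrate_null(small_bundle.known_library, n_null=1000, seed=2)


@pytest.fixture(scope="session")
def default_study():
    """The default eight-line study conditions at seed 7."""
    return CofactorStudy.simulate(seed=7)


@pytest.fixture(scope="session")
def default_results(default_study):
    return default_study.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
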