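import numpy as np
import pytest

from triodistort.simulate import PlantedRegion, make_fixture
from triodistort.trio_io import load_pedigree


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """A small synthetic trio cohort: clean data, one planted SA region."""
    out = tmp_path_factory.mktemp("fixture")
    vcf, ped, truth = make_fixture(
        out, n_trios=250, n_sons=98, n_sites=24, n_x_sites=40,
        planted=[PlantedRegion(8, 13, model="M2", eps_m=0.15, eps_f=-0.15)],
        seed=20240901,
    )
    return vcf, ped, truth


@pytest.fixture(scope="session")
def trio_set(fixture_paths):
    return load_pedigree(fixture_paths[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
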