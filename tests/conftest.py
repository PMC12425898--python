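import numpy as np
import pytest

import qwa


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down stand: 4 trees, 35 rings, 6–8 files of ~20 cells."""
    return qwa.SyntheticParams(
        seed=11,
        n_trees=4,
        start_year=1985,
        end_year=2019,
        cells_per_file=20.0,
        files_per_ring=(6, 8),
        n_cores_rw=5,
    )


@pytest.fixture(scope="session")
def small_climate(small_params):
    return qwa.gen_climate(small_params)


@pytest.fixture(scope="session")
def small_cells(small_params, small_climate):
    return qwa.gen_anatomy(small_climate, small_params)


@pytest.fixture(scope="session")
def small_matrix(small_cells):
    return qwa.build_sector_matrix(small_cells, min_files=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
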