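import numpy as np
import pytest

import mtimpute as mt


@pytest.fixture(scope="session")
def small_cohort():
    """Paper-like preset cohort at unit-test scale (300 cells/biopsy)."""
    table, truth = mt.generate_cohort(mt.preset_paperlike(42, cells_per_biopsy=300))
    return table, truth


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def scaled_table(small_table):
    scaler = mt.fit_scaler(small_table, fit_scope="global")
    return mt.apply_scaler(small_table, scaler)


@pytest.fixture(scope="session")
def medium_cohort():
    """Preset cohort big enough for model-quality checks (800 cells/biopsy)."""
    table, truth = mt.generate_cohort(mt.preset_paperlike(7, cells_per_biopsy=800))
    return table, truth


@pytest.fixture(scope="session")
def prepared_fold(medium_cohort):
    """One across-patient fold of the medium cohort, scaled + featurized at
    radius 0, full training set (no subsample)."""
    from mtimpute.benchmark import _prepare_split

    table, _ = medium_cohort
    split = mt.make_splits(table)[0]
    rng = np.random.default_rng(0)
    return split, _prepare_split(table, split, 0.0, rng, 1.0, "train_only")
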