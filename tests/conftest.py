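import dataclasses

import numpy as np
import pandas as pd
import pytest

import scenmep as sm


@pytest.fixture(scope="session")
def archetypes():
    return sm.builtin_archetypes()


@pytest.fixture(scope="session")
def archetypes_by_key(archetypes):
    return {a.key: a for a in archetypes}


@pytest.fixture(scope="session")
def noiseless_archetypes(archetypes):
    return [dataclasses.replace(a, cell_sigma=0.0) for a in archetypes]


@pytest.fixture(scope="session")
def small_scenith_table(archetypes_by_key):
    """Noisy table for two archetypes, small wells — fast unit-test input."""
    archs = [archetypes_by_key[("ctrl", "mono_0h")],
             archetypes_by_key[("ctrl", "mDC")]]
    return sm.generate_scenith_dataset(
        archs, n_cells_per_well=300, donor_model=sm.DonorModel(2, 0.1),
        seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_event_table(rng, n=500, markers=("CD14", "HLA-DR", "CD86")):
    """Minimal valid SCENITH table with random marker intensities."""
    frame = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "donor_id": "D1",
        "condition": "ctrl",
        "stage": "iDC",
        "inhibitor": "C",
        "puromycin": rng.lognormal(6, 0.4, n),
        "viable": True,
    })
    for m in markers:
        frame[m] = rng.lognormal(4, 0.8, n)
    return frame
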