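import numpy as np
import pytest

from gourdcore import (
    GenotypeMatrix,
    Marker,
    PanelSimConfig,
    simulate_structured_panel,
)


def matrix_from_codes(codes, accession_ids=None, markers=None, chroms=None):
    """Small-matrix builder: codes is a list of rows over {0,1,2,-1}."""
    calls = np.asarray(codes, dtype=np.int8)
    n, L = calls.shape
    if accession_ids is None:
        accession_ids = [f"a{i + 1}" for i in range(n)]
    if markers is None:
        if chroms is None:
            chroms = ["1"] * L
        markers = [
            Marker(f"M{j + 1}", chroms[j], j + 1, "A", "T") for j in range(L)
        ]
    return GenotypeMatrix(accession_ids, markers, calls)


@pytest.fixture(scope="session")
def study_panels():
    """Five replicate structured panels at the study conditions
    (206 accessions x 93 markers, two subpopulations, fst 0.1)."""
    return {
        seed: simulate_structured_panel(PanelSimConfig(seed=seed))
        for seed in range(1, 6)
    }


@pytest.fixture()
def small_random_matrix():
    rng = np.random.default_rng(42)
    calls = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8),
        size=(5, 8),
        p=[0.4, 0.1, 0.4, 0.1],
    )
    return matrix_from_codes(calls)
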