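import numpy as np
import pytest

from poolcomp import simdata
from poolcomp.barcodes import BarcodeCatalog, ReadTemplate, Segment


@pytest.fixture(scope="session")
def small_pool():
    """30 wild strains + 6 reference barcodes at 9:1 mass."""
    return simdata.make_pool(
        30,
        fitness_spec={"name": "uniform", "low": -0.05, "high": 0.1},
        n_reference=6,
        reference_mass=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def neutral_pool():
    """All-neutral pool: frequencies are constant under selection."""
    return simdata.make_pool(
        20,
        fitness_spec={"name": "constant", "value": 0.0},
        n_reference=6,
        reference_mass=0.1,
        seed=12,
    )


@pytest.fixture()
def template():
    """Merged-read layout: const - idxF - const - barcode - const - idxR."""
    return ReadTemplate([
        Segment("const", "ACGTAC", tolerance=1),
        Segment("index_f", length=6),
        Segment("const", "GGATCCA", tolerance=1),
        Segment("barcode", length=20),
        Segment("const", "TTGAGC", tolerance=1),
        Segment("index_r", length=6),
    ])


@pytest.fixture()
def catalog(small_pool):
    return BarcodeCatalog.from_pool(small_pool)
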