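import numpy as np
import pytest
from hypothesis import settings

import tuberpop as tp

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_panel():
    """3 tetraploids + 1 diploid at 4 loci, one missing call."""
    dosage = np.array(
        [
            [0.0, 2.0, 4.0, 1.0],
            [1.0, 2.0, 4.0, np.nan],
            [0.0, 3.0, 4.0, 0.0],
            [1.0, 1.0, 2.0, 0.0],
        ]
    )
    return tp.GenotypePanel(
        sample_ids=["a", "b", "c", "d"],
        locus_ids=["L1", "L2", "L3", "L4"],
        dosage=dosage,
        ploidy=np.array([4, 4, 4, 2]),
        group=["g1", "g1", "g2", "g2"],
    )


@pytest.fixture
def five_pop_panel():
    """Well-separated Balding-Nichols panel with ground truth."""
    return tp.simulate_panel(tp.SimConfig(K=5, n_per_pop=30, L=300, fst=0.25, seed=7))


@pytest.fixture
def toy_pedigree():
    """Two founders, full sibs S1/S2, and their (inbred) offspring X."""
    return tp.Pedigree(
        {
            "A": (None, None),
            "B": (None, None),
            "S1": ("A", "B"),
            "S2": ("A", "B"),
            "X": ("S1", "S2"),
        }
    )
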