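import numpy as np
import pytest

from samredox.data_model import Snapshot, default_scenarios
from samredox.synthetic import build_sam, default_params


@pytest.fixture(scope="session")
def small_params():
    """A 2x2-ligand alkane ensemble small enough for every unit test."""
    return default_params("alkane", n_frames=20, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_params):
    return build_sam(small_params)


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios(0, 1)


@pytest.fixture
def toy_snapshot():
    """Two 3-atom 'nucleobase' triangles plus one gold atom, hand-built."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # gold
            [0.0, 0.0, 3.0],
            [1.0, 0.0, 3.0],
            [0.0, 1.0, 3.0],
            [5.0, 0.0, 3.0],
            [6.0, 0.0, 3.0],
            [5.0, 1.0, 3.0],
        ]
    )
    return Snapshot(
        system_id="toy",
        state="neutral",
        frame_index=0,
        elements=["Au", "C", "N", "C", "C", "N", "C"],
        coords=coords,
        ligand_ids=np.array([-1, 0, 0, 0, 1, 1, 1]),
        moieties=["gold"] + ["nucleobase"] * 6,
    )
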