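import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import pulsepore as pp


def periodic_component_count(occupied: np.ndarray) -> int:
    """Independent oracle for periodic 4-connected component counting.

    The component count of a periodic grid is invariant under cyclic
    rolls; for components smaller than half the box some roll moves every
    component off the grid edges, where a plain (non-periodic) flood fill
    counts them correctly.  The minimum plain count over half-box rolls
    is therefore the periodic count.
    """
    nx, ny = occupied.shape
    counts = []
    for dx in (0, nx // 2):
        for dy in (0, ny // 2):
            rolled = np.roll(occupied, (dx, dy), axis=(0, 1))
            _, n = ndimage.label(
                rolled, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]
            )
            counts.append(n)
    return min(counts)


@pytest.fixture(scope="session")
def reference_table() -> pp.SampleTable:
    """The packaged 12-sample PEF table (8 train / 4 test)."""
    return pp.load_reference_table()


@pytest.fixture(scope="session")
def reference_model(reference_table) -> pp.PLSModel:
    """One-component PLS fit on the 8 training rows."""
    return pp.fit_table(reference_table, n_components=1)


@pytest.fixture()
def linear_table() -> pp.SampleTable:
    """A noiseless table whose response is exactly linear in the predictors."""
    rng = np.random.default_rng(42)
    n = 12
    yp = rng.uniform(5, 95, n)
    pi = rng.uniform(5, 95, n)
    fusion = 1.0 + 0.05 * yp + 0.15 * pi
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "pulse_width_ns": 200.0,
            "field_strength_kv_cm": 1.0,
            "yp_rate": yp,
            "pi_rate": pi,
            "fusion_rate": fusion,
            "role": ["train"] * 8 + ["test"] * 4,
        }
    )
    return pp.SampleTable(df)


@pytest.fixture(scope="session")
def bilayer_no_pore():
    frame, truth = pp.make_bilayer_frame(pp.BilayerSpec(seed=11))
    return frame, truth


@pytest.fixture(scope="session")
def bilayer_one_pore():
    spec = pp.BilayerSpec(pores=[((4.0, 4.0), 1.0)], seed=12)
    frame, truth = pp.make_bilayer_frame(spec)
    return frame, truth
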