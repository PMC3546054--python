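import numpy as np
import pytest

import nucloc as nl


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return nl.AnalysisParams()


@pytest.fixture
def small_mixed_scenario():
    """A small mixed-archetype population, noise-free, short record."""
    return nl.SimScenario(
        n_cells=9, archetype_weights=(0.2, 0.4, 0.4), seed=2, duration=600.0
    )


def random_region(rng, cell_id="c", size_range=(130, 260), frame_shape=(64, 64)):
    """A random connected-ish blob region: a disc plus random interior jitter."""
    h, w = frame_shape
    radius = int(rng.integers(7, 9))
    cr = int(rng.integers(radius, h - radius))
    cc = int(rng.integers(radius, w - radius))
    rows, cols = [], []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                rows.append(cr + dr)
                cols.append(cc + dc)
    return nl.CellRegion(cell_id, np.array(rows), np.array(cols))
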