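import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mxscreen.design import CompoundLibrary, PenaltyState, design_screen

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


@pytest.fixture(scope="session")
def lib80():
    return CompoundLibrary([f"C{i:03d}" for i in range(1, 81)])


@pytest.fixture(scope="session")
def lib6():
    return CompoundLibrary(list("ABCDEF"))


@pytest.fixture(scope="session")
def design80(lib80):
    """A full-scale design shared by analysis/simulation tests (fast settings)."""
    return design_screen(lib80, 10, restarts=5, trials=300, seed=20240917)


def make_state(library: CompoundLibrary, penalties=None, seed: int = 0) -> PenaltyState:
    """PenaltyState with optionally overridden penalty values."""
    state = PenaltyState(library, np.random.default_rng(seed))
    if penalties is not None:
        penalties = np.asarray(penalties, dtype=float)
        state.penalties[:] = penalties
        state._square[state._ii, state._jj] = penalties
        state._square[state._jj, state._ii] = penalties
    return state


@pytest.fixture
def simple_readings():
    """Two strata with known vehicle levels for normalization tests."""
    rows = []
    for plate, cell, veh in [("P1", "MV4-11", 1000.0), ("P1", "CMK", 500.0)]:
        rows.append(
            {"plate_id": plate, "well_id": 1, "cell_line": cell, "time_h": 72.0,
             "rfu": 2.0 * veh, "role": "treatment"}
        )
        for k, v in enumerate([0.9 * veh, 1.1 * veh]):
            rows.append(
                {"plate_id": plate, "well_id": 9000 + k, "cell_line": cell,
                 "time_h": 72.0, "rfu": v, "role": "vehicle"}
            )
    return pd.DataFrame(rows)
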