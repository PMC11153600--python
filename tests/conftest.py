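import numpy as np
import pandas as pd
import pytest

from palmcount import LocalizationTable, TableMeta

#: quality-field values that pass every filter inequality
PASSING_QUALITY = {
    "sigma [nm]": 150.0,
    "intensity [photon]": 200.0,
    "offset [photon]": 2.0,
    "bkgstd [photon]": 1.0,
    "uncertainty [nm]": 25.0,
}


def make_table(frames, x, y, meta=None, **overrides) -> LocalizationTable:
    """Localization table with filter-passing quality fields by default."""
    frames = np.asarray(frames, dtype=int)
    n = frames.size
    cols = {
        "frame": frames,
        "x [nm]": np.asarray(x, float),
        "y [nm]": np.asarray(y, float),
    }
    for col, value in PASSING_QUALITY.items():
        cols[col] = np.broadcast_to(
            np.asarray(overrides.get(col, value), float), (n,)
        ).copy()
    return LocalizationTable(pd.DataFrame(cols), meta=meta or TableMeta())


def random_table(
    rng: np.random.Generator,
    n: int,
    n_frames: int = 60,
    extent_nm: float = 400.0,
) -> LocalizationTable:
    """Random table dense enough in space/time to exercise merge chaining."""
    return make_table(
        rng.integers(1, n_frames + 1, n),
        rng.uniform(0, extent_nm, n),
        rng.uniform(0, extent_nm, n),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260901)
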