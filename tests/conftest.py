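import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import mlclust as m


@pytest.fixture()
def two_block_est():
    """The 4x4 worked fixture: perfect 2+2 blocks, within 1, between 0."""
    return m.generate_two_block_est(2, 2, 1.0, 0.0)


@pytest.fixture()
def toy_cohort_csv(tmp_path):
    """Three subjects, 6-monthly visits; subject C has only a baseline
    visit and must be dropped by the inclusion rule."""
    rows = []
    for sid, months, adas in (("A", [0, 6, 12], [10, 11, 12]),
                              ("B", [0, 6], [20, 19]),
                              ("C", [0], [15])):
        for mo, v in zip(months, adas):
            rows.append({"subject_id": sid, "month": mo, "diagnosis": "MCI",
                         "cohort": "study-1", "sex": "F",
                         "ADAS13": v, "MMSE": 28.0})
    path = tmp_path / "toy.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_synthetic():
    """A 140-subject cohort from the default study conditions (shared
    across tests; treat as read-only)."""
    cfg = m.default_config(n_rapid=60, n_slow=45, n_unclustered=35, seed=11)
    return m.generate(cfg)


@pytest.fixture(scope="session")
def two_group_synthetic():
    """A two-group cohort without the diffuse remainder."""
    cfg = m.default_config(n_rapid=70, n_slow=55, n_unclustered=0, seed=5)
    return m.generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
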