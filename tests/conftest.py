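from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fcgraph import (NetworkPartition, RoiTimeSeries, StudyDesign,
                     SyntheticConfig, default_partition, simulate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_partition():
    """16-ROI partition: 2 ROIs per system."""
    return default_partition(16)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    cfg = SyntheticConfig(n_per_group=(5, 4), n_frames=120, n_runs=2,
                          roi_count=24, seed=77)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_design():
    """10-subject design with both behavior scales filled."""
    rng = np.random.default_rng(3)
    n = 10
    frame = pd.DataFrame({
        "subject": [f"sub-{i:02d}" for i in range(n)],
        "group": ["I"] * 6 + ["NI"] * 4,
        "age": rng.uniform(7, 12, n).round(1),
        "scanner": (rng.random(n) < 0.5).astype(float),
        "inattention_t1": rng.uniform(10, 25, n),
        "inattention_t2": rng.uniform(8, 22, n),
        "internalizing_t1": rng.uniform(2, 20, n),
        "internalizing_t2": rng.uniform(2, 18, n),
    })
    return StudyDesign(frame)


def make_ts(data: np.ndarray, tr: float = 2.0, **kw) -> RoiTimeSeries:
    return RoiTimeSeries(np.asarray(data, float), tr=tr, **kw)
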