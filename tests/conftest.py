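import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from brainstates import CohortManifest, ScanSeries, generate_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """K=3, R=4 ground truth with well-separated means."""
    return generate_params(R=4, K=3, separation=5.0, seed=7, dwell_mean=4.0, max_dwell=20)


@pytest.fixture
def toy_scan(rng):
    return ScanSeries(
        participant_id="p0", scan_id="s0", group="control",
        matrix=rng.normal(size=(30, 3)), region_names=("a", "b", "c"),
    )


@pytest.fixture
def toy_manifest(tmp_path, rng):
    """Four scans (2 participants x 2) written to disk with a manifest."""
    rows = []
    for pid, group in (("p0", "mindfulness"), ("p1", "control")):
        for sid in ("s0", "s1"):
            path = tmp_path / f"{pid}_{sid}.csv"
            pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"]).to_csv(
                path, index=False)
            rows.append({"participant_id": pid, "scan_id": sid, "group": group,
                         "stress_score": 2.0, "avg_drinks": 1.5, "path": str(path)})
    mpath = tmp_path / "manifest.csv"
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath
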