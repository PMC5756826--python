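import numpy as np
import pandas as pd
import pytest

from killscan.telemetry import Trajectory


def make_traj(t_hours, x, y, animal_id="b1", start="2014-06-01T00:00:00",
              sex=None, age_class=None):
    """Trajectory from hour offsets and planar coordinates."""
    t0 = np.datetime64(start, "s")
    t = t0 + (np.asarray(t_hours, dtype=float) * 3600).astype("timedelta64[s]")
    n = len(t)
    return Trajectory(
        animal_id=animal_id,
        fix_ids=np.array([f"{animal_id}-{i}" for i in range(n)], dtype=object),
        t=t,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        sex=sex,
        age_class=age_class,
    )


@pytest.fixture
def simple_traj():
    """20 tight fixes (hours 0-19) then 10 far-flung ones (hours 20-29)."""
    rng = np.random.default_rng(7)
    x = np.concatenate([rng.uniform(0, 5, 20), np.arange(10) * 500.0 + 2000])
    y = np.concatenate([rng.uniform(0, 5, 20), np.arange(10) * 500.0])
    return make_traj(np.arange(30), x, y)


@pytest.fixture
def fixes_csv(tmp_path):
    path = tmp_path / "fixes.csv"
    pd.DataFrame(
        {
            "animal_id": ["a", "a", "b"],
            "timestamp": [
                "2014-06-01T02:00:00Z",
                "2014-06-01T01:00:00Z",
                "2014-06-01T01:00:00Z",
            ],
            "x": [10.0, 0.0, 5.0],
            "y": [0.0, 0.0, 5.0],
        }
    ).to_csv(path, index=False)
    return path
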