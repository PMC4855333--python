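import warnings

import numpy as np
import pandas as pd
import pytest

from fptmigrate.simulator import SimConfig, simulate_path


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Edge-of-grid / all-missing warnings are exercised explicitly elsewhere."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_track_df(times, xs, ys, quality=None):
    times = pd.to_datetime(times)
    xs = np.broadcast_to(np.asarray(xs, dtype=float), (len(times),))
    ys = np.broadcast_to(np.asarray(ys, dtype=float), (len(times),))
    cols = {"timestamp": times, "x": xs, "y": ys}
    if quality is not None:
        cols["quality"] = [str(q) for q in quality]
    return pd.DataFrame(cols)


# fixture seeds give paths whose first break is well represented in the FPT
# profile (a slow break walk can fail to wander far enough for any backward
# circle crossing, leaving the first break with almost no defined FPT; that
# legitimate edge case is exercised separately)
@pytest.fixture(scope="session")
def sim_2lb():
    return simulate_path(SimConfig(path_type="2LB", seed=3))


@pytest.fixture(scope="session")
def sim_1lb():
    return simulate_path(SimConfig(path_type="1LB", seed=12))
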