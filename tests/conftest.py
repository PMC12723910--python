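import numpy as np
import pandas as pd
import pytest

import forensnp as f


@pytest.fixture(scope="session")
def small_panel():
    return f.build_panel(200, 20, seed=11)


@pytest.fixture(scope="session")
def truth_small(small_panel):
    truth = f.simulate_individuals(small_panel, 5, seed=12)
    return f.add_replicates(truth, truth.sample_ids[0], 1)


@pytest.fixture(scope="session")
def deep_noiseless(small_panel, truth_small):
    """Deep, error-free reads: the caller must recover truth exactly."""
    cfg = f.SimulationConfig(mean_depth=100.0, depth_dispersion=20.0,
                             site_efficiency_sd=0.0, error_rate=0.0,
                             mean_quality=36.0, quality_sd=1.0, seed=13)
    return f.simulate_reads(truth_small, small_panel, cfg)


def make_callset(panel, calls, sample_id="s"):
    """Build a CallSet from a marker_id -> call mapping (rest no_call)."""
    frame = pd.DataFrame(
        {"call": "no_call", "no_call_reason": "low_depth"},
        index=pd.Index(panel.marker_ids, name="marker_id"),
    )
    for mid, call in calls.items():
        frame.loc[mid, ["call", "no_call_reason"]] = [call, "none"]
    return f.CallSet(sample_id=sample_id, panel=panel, calls=frame)


def callset_from_arrays(panel, call_array, sample_id="s"):
    call_array = np.asarray(call_array, dtype=object)
    reason = np.where(call_array == "no_call", "low_depth", "none")
    frame = pd.DataFrame(
        {"call": call_array, "no_call_reason": reason},
        index=pd.Index(panel.marker_ids, name="marker_id"),
    )
    return f.CallSet(sample_id=sample_id, panel=panel, calls=frame)
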