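import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from apisim import AgentParams, build_protocol, simulate_cohort, trial_metrics_table
from apisim.arena import ChamberSpec

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def chamber():
    return ChamberSpec()


def cohort_metrics(protocol, n, seed, params=None):
    """Simulate a cohort and return (traces, events, records, tidy per-trial table)."""
    params = params or AgentParams()
    traces, events, records = simulate_cohort(protocol, n, params, seed)
    tm = pd.concat(
        [trial_metrics_table(tr, events, protocol) for tr in traces],
        ignore_index=True,
    )
    return traces, events, records, tm


@pytest.fixture(scope="session")
def bg_reinforced():
    """Small reinforced blue-λ+/green-λ− cohort, shared across tests."""
    proto = build_protocol("I", "BG", reinforced=True)
    return proto, *cohort_metrics(proto, 12, seed=101)


@pytest.fixture(scope="session")
def bg_unreinforced():
    proto = build_protocol("I", "BG", reinforced=False)
    return proto, *cohort_metrics(proto, 12, seed=102)


def make_trace(positions, chamber=None, fs=16.0, bee_id="hand"):
    """Hand-built trace at the nominal sample rate from a position list."""
    from apisim.io import PositionTrace

    chamber = chamber or ChamberSpec()
    positions = np.asarray(positions, dtype=float)
    return PositionTrace(
        bee_id=bee_id,
        times_s=np.arange(len(positions)) / fs,
        positions_cm=positions,
        chamber=chamber,
    )
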