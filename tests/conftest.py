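import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gtcsdetect as g
from gtcsdetect.reference import NON_SEIZURE, SEIZURE

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rdne_model():
    """Daily-activity reference built from the simulated 135-block
    (1,215-s) collection schedule."""
    trace, _ = g.simulate_day(g.reference_collection_schedule(seed=11))
    feats = g.per_second_features(trace)
    return g.build_reference(feats, NON_SEIZURE)


@pytest.fixture(scope="session")
def rde_model():
    """Seizure reference from the tonic-clonic phases of three simulated
    seizures (one per source dog in the emulated collection protocol)."""
    rows = []
    for seed in (21, 22, 23):
        trace, _ = g.simulate_gtcs(tonic_s=5, clonic_s=25, seed=seed)
        rows.append(g.per_second_features(trace))
    import pandas as pd

    return g.build_reference(pd.concat(rows, ignore_index=True), SEIZURE)


@pytest.fixture(scope="session")
def activity_day():
    """A 600-s seizure-free activity recording with labels."""
    sched = g.day_schedule_with_seizures(total_s=600.0, seed=31)
    return g.simulate_day(sched)


@pytest.fixture(scope="session")
def seizure_day():
    """A 900-s recording with one 30-s seizure embedded at t=300 s."""
    sched = g.day_schedule_with_seizures(
        total_s=900.0, seizure_starts_s=(300.0,), seed=41
    )
    return g.simulate_day(sched)
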