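import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import saccsync as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return sc.build_layout(6, 7.0)


@pytest.fixture(scope="session")
def small_schedule():
    """30 inducer trials at 600-ms SOA (20 steps each)."""
    return sc.make_schedule(30, "all", 600, seed=11)


def simulate_labeled(phenotype_name, n_trials=200, soa=600, seed=0, **overrides):
    """Simulate a session and run it through the predictive pipeline."""
    schedule = sc.make_schedule(n_trials, "all", soa, seed=seed)
    phen = sc.get_phenotype(phenotype_name, **overrides)
    events = sc.sample_session(schedule, phen, seed=seed + 1)
    return sc.InducerEffectModel.from_events(events, "predictive").data


@pytest.fixture(scope="session")
def boundary3_labeled():
    return simulate_labeled("BOUNDARY_DELAY_3", seed=101)


def make_event_row(
    step=5,
    target_landmark=1,
    direction="ccw",
    latency_ms=0.0,
    assigned=None,
    soa_ms=600.0,
    trial_id=0,
    onset_ms=None,
):
    """One synthetic event-table row for hand-built filter fixtures."""
    if assigned is None:
        assigned = target_landmark
    if onset_ms is None:
        onset_ms = 2000.0 + step * soa_ms + latency_ms
    return {
        "trial_id": trial_id,
        "step": step,
        "target_landmark": target_landmark,
        "direction": direction,
        "soa_ms": soa_ms,
        "inducer_loc": np.nan,
        "onset_ms": onset_ms,
        "landing_x_deg": 0.0,
        "landing_y_deg": 0.0,
        "latency_ms": latency_ms,
        "assigned_landmark": np.nan if assigned is np.nan else float(assigned),
        "isi_ms": soa_ms,
    }


@pytest.fixture
def events_frame_factory():
    def _make(rows):
        return pd.DataFrame(rows)

    return _make
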