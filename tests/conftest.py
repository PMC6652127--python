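import warnings

import numpy as np
import pandas as pd
import pytest

from rehabsense.cohort import (
    CohortConfig,
    ProtocolSchedule,
    Segment,
    default_beacon_layout,
    draw_patient_params,
    generate_cohort,
    make_protocol_schedule,
    simulate_accelerometer,
    simulate_rssi,
)
from rehabsense.config import PipelineConfig
from rehabsense.pipeline import run_pipeline, train_activity_model
from rehabsense.signal import analyze_stream

warnings.filterwarnings("ignore", message="The least populated class")


@pytest.fixture(scope="session")
def layout():
    return default_beacon_layout()


@pytest.fixture(scope="session")
def full_wear_config():
    """Study conditions with the dropout process switched off, so one
    patient-day covers the whole 9 am - 6 pm protocol."""
    return CohortConfig(n_community=1, n_hospital=0, seed=7,
                        p_remove_early=0.0, p_midday_gap=0.0)


@pytest.fixture(scope="session")
def sim_day(full_wear_config, layout):
    """One fully worn community patient-day: schedule, streams and analysed
    windows, shared across modules."""
    rng = np.random.default_rng(21)
    params = draw_patient_params(full_wear_config, "community", rng)
    sched = make_protocol_schedule(full_wear_config, "community", rng, "P001", 1, params=params)
    accel = simulate_accelerometer(sched, full_wear_config, np.random.default_rng(22))
    rssi = simulate_rssi(sched, layout, full_wear_config, np.random.default_rng(23))
    windows = analyze_stream(accel)
    return {
        "config": full_wear_config,
        "params": params,
        "schedule": sched,
        "accel": accel,
        "rssi": rssi,
        "windows": windows,
    }


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(n_community=3, n_hospital=2, n_days=2, seed=11)


@pytest.fixture(scope="session")
def activity_model(pipeline_config):
    return train_activity_model(pipeline_config)


@pytest.fixture(scope="session")
def e2e_result(pipeline_config):
    """A small cohort through every pipeline stage."""
    return run_pipeline(pipeline_config)


def make_manual_schedule(segments, wear_mask=None, patient_id="PX", day=1):
    """Hand-built schedule helper for targeted signal tests."""
    if wear_mask is None:
        start = min(s[0] for s in segments)
        end = max(s[1] for s in segments)
        wear_mask = [(start, end)]
    segs = [Segment(*s) for s in segments]
    return ProtocolSchedule(patient_id=patient_id, day_index=day,
                            segments=segs, wear_mask=wear_mask)
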