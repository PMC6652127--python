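import logging

import numpy as np
import pytest

from rehabsense.cohort import (
    DAY_END_S,
    DAY_START_S,
    DEFAULT_GROUP_EFFECT_MAP,
    CohortConfig,
    default_beacon_layout,
    draw_patient_params,
    generate_cohort,
    make_protocol_schedule,
    path_loss_rssi,
    simulate_accelerometer,
    simulate_feature_cohort,
    simulate_rssi,
    window_ground_truth,
)
from rehabsense.signal import analyze_stream, compute_signal_magnitude
from rehabsense.stats import cohens_d_from_samples
from tests.conftest import make_manual_schedule


def test_full_wear_schedule_spans_540_minutes(full_wear_config):
    sched = make_protocol_schedule(
        full_wear_config, "community", np.random.default_rng(3)
    )
    assert sched.worn_seconds / 60.0 == pytest.approx(540.0)


def test_hospital_default_laying_fraction_parameter():
    """The hospital-group laying-time parameter mirrors the study population
    (60.99% of uptime)."""
    mean_c, mean_h, _ = DEFAULT_GROUP_EFFECT_MAP["time_pct_laying"]
    assert mean_h == pytest.approx(60.99)
    assert mean_c == pytest.approx(46.83)


def test_schedule_is_deterministic_given_seed(full_wear_config):
    a = make_protocol_schedule(full_wear_config, "hospital", np.random.default_rng(9))
    b = make_protocol_schedule(full_wear_config, "hospital", np.random.default_rng(9))
    assert a.wear_mask == b.wear_mask
    assert [vars(s) for s in a.segments] == [vars(s) for s in b.segments]


def test_unknown_group_label_rejected(full_wear_config):
    with pytest.raises(ValueError, match="group label"):
        make_protocol_schedule(full_wear_config, "icu", np.random.default_rng(0))


def test_schedule_invariants(full_wear_config):
    rng = np.random.default_rng(17)
    for outcome in ("community", "hospital"):
        sched = make_protocol_schedule(full_wear_config, outcome, rng)
        rooms = default_beacon_layout().rooms
        therapy = [s for s in sched.segments if rooms[s.location_id] == "therapy"]
        starts = [s.start_s for s in therapy]
        # exactly one contiguous therapy block, duration near an hour
        assert therapy
        dur = sum(s.duration_s for s in therapy) / 60.0
        assert 40.0 <= dur <= 80.0
        assert max(np.diff([s.start_s for s in therapy])) if len(therapy) > 1 else True
        for a, b in zip(therapy[:-1], therapy[1:]):
            assert b.start_s == pytest.approx(a.end_s)
        for s in sched.segments:
            assert DAY_START_S <= s.start_s < s.end_s <= DAY_END_S
            if s.motion == "walk":
                assert s.posture == "stand"


def test_idle_lay_segment_windows_below_threshold(full_wear_config):
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 600, "resident_bed1", "lay", "idle",
          full_wear_config.idle_mad_cms2)]
    )
    acc = simulate_accelerometer(sched, full_wear_config, np.random.default_rng(4))
    wt = analyze_stream(acc)
    assert len(wt) > 0
    assert np.all(wt.mad_ms2 < 0.02)


def test_static_segment_without_noise_has_unit_magnitude():
    cfg = CohortConfig(n_community=1, n_hospital=0, seed=1,
                       sensor_noise_g=0.0, idle_mad_cms2=0.0)
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 60, "resident_bed1", "lay", "idle", 0.0)]
    )
    acc = simulate_accelerometer(sched, cfg, np.random.default_rng(4))
    sm = compute_signal_magnitude(acc.ax, acc.ay, acc.az)
    assert np.allclose(sm, 1.0, atol=1e-12)


def test_walking_segment_has_gait_band_spectral_peak(full_wear_config):
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 600, "resident_bed1", "stand", "walk", 450.0)]
    )
    acc = simulate_accelerometer(sched, full_wear_config, np.random.default_rng(12))
    wt = analyze_stream(acc)
    # independent FFT oracle on a mid-day window
    w = wt.sm_filtered_ms2[len(wt) // 2]
    spec = np.abs(np.fft.rfft(w)) ** 2
    freqs = np.fft.rfftfreq(160, d=1 / 16.0)
    peak = freqs[1:][np.argmax(spec[1:])]
    assert 1.5 <= peak <= 2.5


def test_rssi_line_of_sight_anchor(full_wear_config, layout):
    """At 1 ft line of sight with zero noise every reception is ~-66 dBm."""
    assert path_loss_rssi(0.3048) == pytest.approx(-66.0)
    from dataclasses import replace

    cfg = replace(full_wear_config, rssi_noise_sd=1e-12,
                  position_jitter_m=(0.3048, 0.3048))
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 60, "bike", "sit", "idle", 0.5)]
    )
    stream = simulate_rssi(sched, layout, cfg, np.random.default_rng(2))
    own = stream.rssi_dbm[stream.beacon_id == "b_bike"]
    assert own.size > 0
    assert np.allclose(own, -66.0, atol=1e-6)


def test_rssi_guards(full_wear_config, layout):
    with pytest.raises(ValueError):
        CohortConfig(n_community=1, n_hospital=0, advert_interval=0.0)
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 60, "broom_closet", "sit", "idle", 0.5)]
    )
    with pytest.raises(ValueError, match="broom_closet"):
        simulate_rssi(sched, layout, full_wear_config, np.random.default_rng(0))


def test_rssi_deterministic_given_seed(full_wear_config, layout):
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 120, "bike", "sit", "idle", 0.5)]
    )
    a = simulate_rssi(sched, layout, full_wear_config, np.random.default_rng(6))
    b = simulate_rssi(sched, layout, full_wear_config, np.random.default_rng(6))
    assert np.array_equal(a.t, b.t)
    assert np.array_equal(a.beacon_id, b.beacon_id)
    assert np.array_equal(a.rssi_dbm, b.rssi_dbm)


def test_occupied_beacon_has_highest_mean_rssi(full_wear_config, layout):
    sched = make_manual_schedule(
        [(DAY_START_S, DAY_START_S + 300, "strip", "stand", "active", 100.0)]
    )
    stream = simulate_rssi(sched, layout, full_wear_config, np.random.default_rng(8))
    import pandas as pd

    means = pd.Series(stream.rssi_dbm).groupby(stream.beacon_id).mean()
    assert means.idxmax() == "b_strip"


def test_cohort_counts_and_candidate_days():
    cohort = generate_cohort(CohortConfig(n_community=5, n_hospital=4, seed=3))
    assert len(cohort.patient_ids()) == 9
    assert set(cohort.metadata["outcome"]) == {"community", "hospital"}
    days = cohort.metadata.groupby("patient_id")["day"].nunique()
    assert (days >= 3).all()


def test_study_scale_cohort_metadata():
    cohort = generate_cohort(CohortConfig(n_community=145, n_hospital=9, seed=2))
    assert len(cohort.patient_ids()) == 154
    assert (cohort.metadata["outcome"] == "community").sum() == 145 * 3


def test_empty_cohort_warns(caplog):
    with caplog.at_level(logging.WARNING):
        cohort = generate_cohort(CohortConfig(n_community=0, n_hospital=0, seed=1))
    assert len(cohort.patient_ids()) == 0
    assert "empty cohort" in caplog.text


def test_walking_occupies_under_one_percent_of_community_uptime(full_wear_config):
    """Realism floor: this population spends a negligible share of the day
    walking."""
    rng = np.random.default_rng(31)
    params = draw_patient_params(full_wear_config, "community", rng)
    walk, total = 0.0, 0.0
    for _ in range(10):
        sched = make_protocol_schedule(
            full_wear_config, "community", rng, params=params
        )
        walk += sum(s.duration_s for s in sched.segments if s.motion == "walk")
        total += sched.worn_seconds
    assert walk / total < 0.01


def test_ground_truth_recoverable_for_arbitrary_window_starts(sim_day):
    starts = np.array([DAY_START_S + 13.7, DAY_START_S + 2000.2, DAY_END_S - 20.0])
    gt = window_ground_truth(sim_day["schedule"], starts)
    assert len(gt) == 3
    assert gt["posture"].notna().all()
    assert gt["room"].isin(["resident", "therapy"]).all()


def test_programmed_intensity_effect_recovered_in_one_cohort():
    """A single study-size cohort recovers the programmed resident-room
    effect (d = 1.25) within sampling error at n_H = 9."""
    df = simulate_feature_cohort(CohortConfig(seed=5))
    d = cohens_d_from_samples(
        df.loc[df.outcome == "community", "ei_resident_room"],
        df.loc[df.outcome == "hospital", "ei_resident_room"],
    )
    assert d == pytest.approx(1.25, abs=0.35)


def test_feature_cohort_deterministic():
    cfg = CohortConfig(n_community=20, n_hospital=5, seed=9)
    a = simulate_feature_cohort(cfg)
    b = simulate_feature_cohort(cfg)
    assert a.equals(b)


def test_accel_stream_deterministic_and_within_wear_mask(full_wear_config):
    cohort = generate_cohort(CohortConfig(n_community=1, n_hospital=0, seed=13))
    a = cohort.accel("P001", 1)
    b = cohort.accel("P001", 1)
    assert np.array_equal(a.t, b.t) and np.array_equal(a.az, b.az)
    sched = cohort.schedule("P001", 1)
    for ts in (a.t[0], a.t[-1]):
        assert any(w0 - 1e-9 <= ts <= w1 + 1e-9 for w0, w1 in sched.wear_mask)
    inside = np.zeros(a.t.size, dtype=bool)
    for w0, w1 in sched.wear_mask:
        inside |= (a.t >= w0 - 1e-9) & (a.t < w1 + 1e-9)
    assert inside.all()
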