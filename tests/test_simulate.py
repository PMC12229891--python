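"""Generator-level checks: task structure, determinism, ground truth."""

import numpy as np
import pytest

from placeref.circular import arc_distance, forward_distance, wrap
from placeref.config import SimConfig
from placeref.simulate import simulate_behavior_full, simulate_calcium, simulate_vm


def test_reward_events_at_configured_location(small_cfg, small_session):
    session, _ = small_session
    pre = session.reward_positions[: small_cfg.n_laps_pre]
    post = session.reward_positions[small_cfg.n_laps_pre :]
    assert np.all(pre == small_cfg.reward_pre_cm)
    assert np.all(post == small_cfg.reward_post_cm)
    assert len(session.reward_times) == small_cfg.n_laps_pre + small_cfg.n_laps_post
    # the recorded position trace actually sits at the reward when it fires
    frames = session.reward_frames()
    d = arc_distance(session.position[frames], session.reward_positions, 180.0)
    assert np.max(d) < 180.0 / 50  # within one spatial bin


def test_mean_stop_duration_near_target(small_session, small_cfg):
    _, schedule = small_session
    mean_stop = schedule.stop_durations.mean()
    assert abs(mean_stop - 6.8) / 6.8 < 0.10


def test_velocity_profile_dips_and_cruises(small_session):
    session, schedule = small_session
    # stationary after each reward for roughly the scheduled duration
    for k in (3, 10, 40):
        t0, t1 = schedule.stop_times[k], schedule.stop_times[k] + schedule.stop_durations[k]
        a, b = np.searchsorted(session.time, [t0 + 0.05, t1 - 0.05])
        assert np.all(session.velocity[a:b] < 1.0)


def test_same_seed_identical_traces(small_cfg, small_session, small_calcium):
    session, _ = small_session
    s2, sched2 = simulate_behavior_full(small_cfg)
    assert np.array_equal(session.position, s2.position)
    assert np.array_equal(session.velocity, s2.velocity)
    assert np.array_equal(session.lick_times, s2.lick_times)
    raw2, truth2 = simulate_calcium(small_cfg, s2, sched2)
    assert np.array_equal(small_calcium[0], raw2)
    assert small_calcium[1].category == truth2.category


def test_lick_probability_rises_before_reward(small_session):
    session, _ = small_session
    from placeref.behavior import bin_behavior

    _, _, lick_prob = bin_behavior(session)
    # reward bins: 50 cm -> bin 13, 140 cm -> bin 38 (3.6-cm bins); each
    # reward site is active for only half the laps, capping probability at 0.5
    assert lick_prob[11:15].max() > 0.4
    assert lick_prob[36:40].max() > 0.4
    assert lick_prob[9] < lick_prob[12]  # ramps up approaching the reward
    assert lick_prob[20:33].max() < 0.05  # silent mid-track


def test_pure_space_and_pure_goal_truth_shifts():
    base = dict(n_laps_pre=8, n_laps_post=8, n_cells=6, seed=4)
    cfg = SimConfig(**base, fractions={"space": 1.0})
    s, sched = simulate_behavior_full(cfg)
    _, truth = simulate_calcium(cfg, s, sched)
    assert np.allclose(truth.shift_cm, 0.0)
    cfg = SimConfig(**base, fractions={"goal": 1.0})
    _, truth = simulate_calcium(cfg, s, sched)
    assert np.all((np.array(truth.shift_cm) >= 75.0) & (np.array(truth.shift_cm) <= 90.0))


def test_intermediate_shift_range():
    cfg = SimConfig(
        n_laps_pre=8, n_laps_post=8, n_cells=30, seed=6, fractions={"intermediate": 1.0}
    )
    s, sched = simulate_behavior_full(cfg)
    _, truth = simulate_calcium(cfg, s, sched)
    shifts = np.array(truth.shift_cm)
    assert np.all((shifts >= 16.0) & (shifts <= 74.0))


def test_noise_free_dff_zero_outside_fields():
    """Energy check: without noise or drift, activity exists only in the
    decay tail downstream of each cell's anchor."""
    cfg = SimConfig(
        n_laps_pre=6, n_laps_post=6, n_cells=4, seed=8, noise_sd=0.0, drift_amp=0.0,
        reliability=1.0, fractions={"space": 1.0},
    )
    s, sched = simulate_behavior_full(cfg)
    raw, truth = simulate_calcium(cfg, s, sched)
    from placeref.dff import dff

    for c in range(4):
        d = dff(raw[c])
        downstream = forward_distance(truth.pf_pre_cm[c], s.position, 180.0)
        outside = downstream > 60.0  # anchor + decay tail at cruise speed
        # the exponential tail truncates at ~e^-8 of the transient amplitude
        assert np.abs(d[outside]).max() < 2e-3


def test_btsp_injection_creates_abrupt_persistent_field():
    cfg = SimConfig(
        n_laps_pre=6, n_laps_post=30, n_cells=1, seed=9, fractions={"space": 1.0},
        btsp_injection=[(0, 16, 90.0)], noise_sd=0.0, drift_amp=0.0,
    )
    s, sched = simulate_behavior_full(cfg)
    raw, truth = simulate_calcium(cfg, s, sched)
    assert truth.btsp_events == [(0, 16, 90.0)]
    from placeref.dff import dff
    from placeref import placecells as pc

    d = dff(raw[0])
    bf = pc.frame_binning(s, pc.condition_laps(s, "post"))
    lm = np.nan_to_num(pc.lap_max_maps(d[bf.frames], bf))
    event_bin = int(90.0 / bf.bin_cm)
    win = lm[:, event_bin : event_bin + 3].max(axis=1)
    rel_lap = 16 - 6
    assert np.all(win[:rel_lap] < 0.1)  # nothing there before the event
    assert win[rel_lap] > 2.0  # large induction transient
    assert np.all(win[rel_lap + 1 : rel_lap + 6] > 0.3)  # persistent field


def test_vm_components_move_with_reward_switch():
    base = dict(
        belt_length_cm=184.0, n_bins=184, reward_pre_cm=184.0, reward_post_cm=92.0,
        n_laps_pre=5, n_laps_post=5, frame_rate_hz=2000.0, n_cells=1,
        vm_noise_sd_mv=0.0, vm_trial_offset_sd_mv=0.0, vm_spike_rate_hz=0.0,
        fractions={"goal": 1.0},
    )
    s, sched = simulate_behavior_full(SimConfig(**base, seed=10))
    for weights, expect_shift in [((1.0, 0.0), 92.0), ((0.0, 1.0), 0.0)]:
        cfg = SimConfig(**base, seed=10, vm_weights=[weights])
        vm_raw, truth = simulate_vm(cfg, s, sched)
        # peak belt position of the subthreshold trace, pre vs late post
        pre = s.lap_index < 5
        post = s.lap_index == 9  # past the transition lap
        peak_pre = s.position[pre][np.argmax(vm_raw.vm[pre])]
        peak_post = s.position[post][np.argmax(vm_raw.vm[post])]
        assert arc_distance(peak_pre, truth.pf_pre_cm[0], 184.0) < 4.0
        assert arc_distance(
            forward_distance(peak_pre, peak_post, 184.0), expect_shift, 184.0
        ) < 8.0


def test_vm_ramp_amplitude_and_plateau_construction():
    cfg = SimConfig(
        belt_length_cm=184.0, n_bins=184, reward_pre_cm=184.0, reward_post_cm=92.0,
        n_laps_pre=4, n_laps_post=4, frame_rate_hz=2000.0, n_cells=1,
        vm_noise_sd_mv=0.0, vm_trial_offset_sd_mv=0.0, vm_spike_rate_hz=0.0,
        vm_weights=[(1.0, 1.0)], plateau_schedule=[(2, 3.0, 150.0)],
        fractions={"goal": 1.0}, seed=11,
    )
    s, sched = simulate_behavior_full(cfg)
    vm_raw, truth = simulate_vm(cfg, s, sched)
    # combined ramp peak ~9 mV above the -65 mV resting level
    no_plateau = vm_raw.vm < -35.0
    assert np.nanmax(vm_raw.vm[no_plateau]) == pytest.approx(-65.0 + 9.0, abs=0.5)
    # exactly one supra(-35 mV) segment lasting 150 ms
    above = vm_raw.vm > -35.0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(int), [0]])))
    segs = list(zip(edges[::2], edges[1::2]))
    assert len(segs) == 1
    dur_ms = (segs[0][1] - segs[0][0]) / 2000.0 * 1000.0
    assert dur_ms == pytest.approx(150.0, abs=1.0)


def test_vm_negative_weights_rejected():
    cfg = SimConfig(n_laps_pre=2, n_laps_post=2, n_cells=1, seed=1)
    s, sched = simulate_behavior_full(cfg)
    cfg.vm_weights = [(-1.0, 1.0)]  # bypass construction-time validation
    from placeref.config import InvalidConfigError

    with pytest.raises(InvalidConfigError):
        simulate_vm(cfg, s, sched)
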