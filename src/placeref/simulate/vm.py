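"""Synthetic intracellular membrane potential for one recorded cell.

The subthreshold potential is a resting level plus two smooth unimodal
ramps: a *space* component anchored to a fixed belt position and a
*goal* component anchored to a fixed arc-distance from each lap's
running start. Before the reward switch both components coincide at the
cell's place field; after the switch the goal component follows the
running start (a 92-cm rotation on the 184-cm belt) while the space
component stays put. Component amplitudes are scaled so the combined
pre-switch ramp peaks near 9 mV regardless of the weight ratio, and the
true goal/space index is (w_goal - w_space)/(w_goal + w_space).

Spikes are emitted stochastically at a rate that rises steeply with the
underlying depolarization; each inserted waveform initiates from a
stereotyped threshold (-50 mV plus the trial's recording offset) so
that threshold-based trial baseline correction can recover the offset.
Scheduled plateau potentials are square depolarizations to -30 mV.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from ..circular import arc_distance, forward_distance, wrap
from ..config import InvalidConfigError, SimConfig
from ..session import BehaviorSession, GroundTruth, VmRaw
from .treadmill import LapSchedule, simulate_behavior_full

RAMP_SIGMA_CM = 12.0
PLATEAU_LEVEL_MV = -30.0
SPIKE_PEAK_MV = 20.0
_SOFT_THRESHOLD_MV = -54.0
_REFRACTORY_S = 0.010


def _bump(delta_cm: np.ndarray, belt_length: float) -> np.ndarray:
    d = arc_distance(delta_cm, 0.0, belt_length)
    return np.exp(-0.5 * (d / RAMP_SIGMA_CM) ** 2)


def simulate_vm(
    config: SimConfig,
    behavior: BehaviorSession,
    schedule: LapSchedule | None = None,
):
    """Simulate one cell's V_m trace aligned to behavior; returns (VmRaw, GroundTruth)."""
    if schedule is None:
        _, schedule = simulate_behavior_full(config)
    weights = config.vm_weights[0] if config.vm_weights else (1.0, 1.0)
    w_goal, w_space = float(weights[0]), float(weights[1])
    if w_goal < 0 or w_space < 0:
        raise InvalidConfigError("vm weights must be nonnegative")
    if w_goal + w_space <= 0:
        raise InvalidConfigError("at least one vm weight must be positive")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    L = config.belt_length_cm
    fs = config.frame_rate_hz
    dt = 1.0 / fs
    n = behavior.n_frames
    n_laps = config.n_laps_pre + config.n_laps_post

    # place the pre-switch field mid-lap so the +-30 cm analysis windows
    # stay clear of the stationary period
    start_pre = wrap(
        np.median(wrap(schedule.start_positions_unwrapped[1 : config.n_laps_pre], L)), L
    )
    p0 = wrap(start_pre + rng.uniform(40.0, 110.0), L)
    goal_offset = float(forward_distance(start_pre, p0, L))

    x_unwrapped = behavior.lap_index * L + behavior.position
    k = np.clip(
        np.searchsorted(schedule.start_times, behavior.time, side="right") - 1, 0, n_laps - 1
    )
    dist_from_start = x_unwrapped - schedule.start_positions_unwrapped[k]

    scale = config.vm_ramp_peak_mv / (w_goal + w_space)
    vm_bio = config.vm_resting_mv + scale * (
        w_space * _bump(behavior.position - p0, L)
        + w_goal * _bump(dist_from_start - goal_offset, L)
    )
    if config.vm_noise_sd_mv > 0:
        noise = gaussian_filter1d(rng.standard_normal(n), sigma=0.005 * fs)
        vm_bio = vm_bio + config.vm_noise_sd_mv * noise / max(noise.std(), 1e-12)

    offsets = (
        config.vm_trial_offset_sd_mv * rng.standard_normal(n_laps)
        if config.vm_trial_offset_sd_mv > 0
        else np.zeros(n_laps)
    )
    lap_of_frame = np.clip(behavior.lap_index, 0, n_laps - 1)
    vm = vm_bio + offsets[lap_of_frame]

    # --- spikes -----------------------------------------------------------
    rate = config.vm_spike_rate_hz * expit((vm_bio - _SOFT_THRESHOLD_MV) / 1.5)
    candidates = np.flatnonzero(rng.random(n) < rate * dt)
    spike_onsets = []
    last = -np.inf
    refractory = int(round(_REFRACTORY_S * fs))
    for i in candidates:
        if i - last >= refractory:
            spike_onsets.append(int(i))
            last = i
    n_up = max(int(round(0.0003 * fs)), 2)
    n_down = max(int(round(0.0010 * fs)), 2)
    max_approach = max(int(round(0.0020 * fs)), 2)
    spike_times = []
    for i in spike_onsets:
        theta = config.vm_spike_threshold_mv + offsets[lap_of_frame[i]]
        v0 = min(vm[i], theta - 0.5)
        # depolarize to threshold at under 15 mV/ms so that spike
        # initiation is always read off at the stereotyped threshold
        n_approach = int(np.clip(np.ceil((theta - v0) * fs / 15000.0) + 1, 2, max_approach))
        wave_len = n_approach + n_up + n_down
        if i + wave_len + 1 >= n:
            continue
        seg = np.concatenate(
            [
                np.linspace(v0, theta, n_approach, endpoint=False),
                np.linspace(theta, SPIKE_PEAK_MV, n_up, endpoint=False),
                np.linspace(SPIKE_PEAK_MV, vm[i + wave_len], n_down, endpoint=False),
            ]
        )
        vm[i : i + wave_len] = seg
        spike_times.append(behavior.time[i + n_approach])

    # --- scheduled plateau potentials ------------------------------------
    plateau_events = []
    truth_plateaus = []
    for entry in config.plateau_schedule:
        if len(entry) == 4:
            _cell, trial, t_in_trial, dur_ms = entry
        else:
            trial, t_in_trial, dur_ms = entry
        lap_frames = np.flatnonzero(behavior.lap_index == int(trial))
        if lap_frames.size == 0:
            raise InvalidConfigError(f"plateau trial {trial} outside session")
        t0 = behavior.time[lap_frames[0]] + float(t_in_trial)
        i0 = int(np.searchsorted(behavior.time, t0))
        i1 = i0 + int(round(float(dur_ms) / 1000.0 * fs))
        vm[i0 : min(i1, n)] = PLATEAU_LEVEL_MV
        plateau_events.append((t0, float(dur_ms)))
        truth_plateaus.append((0, int(trial), t0, float(dur_ms)))

    index = (w_goal - w_space) / (w_goal + w_space)
    truth = GroundTruth(
        category=["goal" if w_goal > w_space else ("space" if w_space > w_goal else "intermediate")],
        pf_pre_cm=[float(p0)],
        pf_post_cm=[float(wrap(p0 + (L / 2.0 if w_goal >= w_space else 0.0), L))],
        onset_lap=[0],
        shift_cm=[
            float(L / 2.0) if w_goal > w_space else (0.0 if w_space > w_goal else float("nan"))
        ],
        vm_weights=[(w_goal, w_space)],
        vm_index=[index],
        plateau_times=truth_plateaus,
        running_start_times=list(schedule.start_times),
        running_start_positions=list(wrap(schedule.start_positions_unwrapped, L)),
    )
    return VmRaw(vm=vm, spike_times=np.array(spike_times), plateau_events=plateau_events), truth
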