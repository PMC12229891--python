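"""Treadmill behavior generator.

Emulates a head-fixed mouse running laps on a circular belt for a water
reward at a fixed location: anticipatory slowing and licking over the
~20 cm before the reward, a post-reward stop a few cm past the delivery
site, a ~6.8-s stationary consumption period, then a running start and
a cruise at a lap-specific speed. After ``n_laps_pre`` laps the reward
moves to the post-switch location.

Kinematics are piecewise constant-acceleration, so position and
velocity are evaluated analytically at the frame times; the resulting
traces are exactly reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import InvalidConfigError, SimConfig
from ..session import BehaviorSession

_ACCEL = 20.0  # cm/s^2 at running starts
_DECEL_DIST = 20.0  # cm of anticipatory slowing before the reward
_V_REWARD = 3.0  # cm/s when crossing the reward site
_MIN_CRUISE = 6.0  # cm/s floor on lap cruise speed


@dataclass
class LapSchedule:
    """Generator-side ground truth of the lap structure."""

    reward_positions: np.ndarray  # per lap, cm
    reward_times: np.ndarray  # per lap, s
    stop_times: np.ndarray  # per lap: time the animal comes to rest
    stop_positions: np.ndarray  # cm (belt)
    start_times: np.ndarray  # per lap: running start that begins lap k's run
    start_positions_unwrapped: np.ndarray  # cumulative cm at that start
    stop_durations: np.ndarray
    cruise_speeds: np.ndarray
    extra_stop_times: list = field(default_factory=list)  # (time, position)


class _SegmentTrack:
    """Accumulates constant-acceleration segments and samples them."""

    def __init__(self) -> None:
        self.t0 = [0.0]
        self.x0 = [0.0]
        self.v0 = []
        self.a = []

    @property
    def t_end(self) -> float:
        return self.t0[-1]

    @property
    def x_end(self) -> float:
        return self.x0[-1]

    def add(self, duration: float, v_start: float, v_end: float) -> None:
        if duration <= 0:
            return
        a = (v_end - v_start) / duration
        self.v0.append(v_start)
        self.a.append(a)
        self.t0.append(self.t0[-1] + duration)
        self.x0.append(self.x0[-1] + v_start * duration + 0.5 * a * duration**2)

    def add_distance(self, dist: float, v_start: float, v_end: float) -> None:
        """Segment covering ``dist`` cm with linear velocity change."""
        if dist <= 0:
            return
        self.add(2.0 * dist / (v_start + v_end), v_start, v_end)

    def add_stationary(self, duration: float) -> None:
        self.add(duration, 0.0, 0.0)

    def sample(self, times: np.ndarray):
        t0 = np.asarray(self.t0[:-1])
        seg = np.clip(np.searchsorted(t0, times, side="right") - 1, 0, len(self.v0) - 1)
        tau = times - t0[seg]
        v0 = np.asarray(self.v0)[seg]
        a = np.asarray(self.a)[seg]
        x = np.asarray(self.x0[:-1])[seg] + v0 * tau + 0.5 * a * tau**2
        v = v0 + a * tau
        return x, np.maximum(v, 0.0)


def simulate_behavior_full(config: SimConfig):
    """Simulate treadmill behavior; returns (BehaviorSession, LapSchedule)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    L = config.belt_length_cm
    n_laps = config.n_laps_pre + config.n_laps_post
    reward_pos = np.array(
        [
            np.mod(config.reward_pre_cm if k < config.n_laps_pre else config.reward_post_cm, L)
            for k in range(n_laps)
        ]
    )
    cruise = np.maximum(
        config.cruise_speed_cm_s * (1.0 + config.speed_jitter * rng.standard_normal(n_laps)),
        _MIN_CRUISE,
    )
    stop_dur = np.maximum(
        rng.normal(config.mean_stop_duration_s, config.stop_duration_sd_s, n_laps), 1.0
    )
    stop_dist = np.clip(rng.normal(3.0, 0.8, n_laps), 1.0, 6.0)
    # scheduled mid-track stops, as unwrapped positions consumed by
    # whichever run covers them
    extra_stops = sorted(
        (int(lap) * L + float(np.mod(pos, L)), float(dur))
        for lap, pos, dur in config.extra_stops
    )

    track = _SegmentTrack()
    reward_times = np.empty(n_laps)
    stop_times = np.empty(n_laps)
    start_times = np.empty(n_laps)
    start_x = np.empty(n_laps)
    extra_stop_events = []

    for k in range(n_laps):
        # running start that begins lap k's run
        start_times[k] = track.t_end
        start_x[k] = track.x_end
        v_k = cruise[k]
        if k > 0:
            track.add(v_k / _ACCEL, 0.0, v_k)
        # unwrapped position at which lap k's reward is crossed: the lap-k
        # origin crossing plus the reward offset
        x_reward = k * L + reward_pos[k]
        # mid-lap scheduled stops (non-rewarded), in traversal order
        for x_stop, dur in extra_stops:
            if not track.x_end < x_stop < x_reward - _DECEL_DIST - 10.0:
                continue
            run = x_stop - track.x_end
            track.add_distance(max(run - 8.0, 0.0), v_k, v_k)
            track.add_distance(min(8.0, run), v_k, 0.0)
            extra_stop_events.append((track.t_end, np.mod(x_stop, L)))
            track.add_stationary(dur)
            track.add(v_k / _ACCEL, 0.0, v_k)
        d_decel = _DECEL_DIST
        d_cruise = x_reward - track.x_end - d_decel
        if d_cruise < 0:  # reward too close (e.g. delivered at the lap origin)
            d_decel = max(x_reward - track.x_end, 0.0)
            d_cruise = 0.0
        track.add_distance(d_cruise, v_k, v_k)
        track.add_distance(d_decel, v_k, _V_REWARD)
        reward_times[k] = track.t_end
        track.add_distance(stop_dist[k], _V_REWARD, 0.0)
        stop_times[k] = track.t_end
        track.add_stationary(stop_dur[k])
    # closing run: finish the final belt lap (stopping just short of the
    # origin) so the last lap's spatial map is complete
    v_k = cruise[-1]
    track.add(v_k / _ACCEL, 0.0, v_k)
    closing = np.mod(-track.x_end, L) - 0.5
    if closing > 0:
        track.add_distance(closing, v_k, v_k)

    dt = 1.0 / config.frame_rate_hz
    times = np.arange(0.0, track.t_end, dt)
    x, v = track.sample(times)
    position = np.mod(x, L)
    lap_index = np.floor(x / L).astype(int)

    lick_times = _licks(rng, cruise, reward_times, stop_times, stop_dur)
    session = BehaviorSession(
        time=times,
        position=position,
        velocity=v,
        lick_times=lick_times,
        reward_times=reward_times,
        reward_positions=reward_pos.astype(float),
        lap_index=lap_index,
        belt_length_cm=L,
        reward_switch_lap=config.n_laps_pre,
    )
    sched = LapSchedule(
        reward_positions=reward_pos.astype(float),
        reward_times=reward_times,
        stop_times=stop_times,
        stop_positions=np.mod(
            np.array([reward_pos[k] + stop_dist[k] for k in range(n_laps)]), L
        ),
        start_times=start_times,
        start_positions_unwrapped=start_x,
        stop_durations=stop_dur,
        cruise_speeds=cruise,
        extra_stop_times=extra_stop_events,
    )
    return session, sched


def simulate_behavior(config: SimConfig) -> BehaviorSession:
    """Simulate treadmill behavior for one reward-switch session."""
    return simulate_behavior_full(config)[0]


def _licks(rng, cruise, reward_times, stop_times, stop_dur) -> np.ndarray:
    """Anticipatory licks ramping up before the reward plus consumption licks."""
    licks = []
    for k, (t_r, t_stop) in enumerate(zip(reward_times, stop_times)):
        # anticipatory: rate increasing linearly over the deceleration window
        span = 2.0 * _DECEL_DIST / (cruise[k] + _V_REWARD)
        n = rng.poisson(0.5 * 8.0 * span)
        if n:
            licks.append(t_r - span * (1.0 - np.sqrt(rng.random(n))))
        # consumption: ~6 Hz during the first 2 s of the stationary period
        dur = min(2.0, stop_dur[k])
        n = rng.poisson(6.0 * dur)
        if n:
            licks.append(t_stop + dur * rng.random(n))
    if not licks:
        return np.empty(0)
    return np.sort(np.concatenate(licks))
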