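"""Behavioral analysis: spatial maps, post-reward and non-rewarded running starts.

The running start — the end of the post-reward stationary period — is
the origin of the goal-referenced frame, so its detection is specified
tightly: the stop is the first sub-1 cm/s frame within 5 s or 50 cm of
the reward (falling back to sub-5 cm/s, then to the minimum-speed
frame); movement bouts travelling under 8 cm during the stationary
window are zeroed; and the end of the stationary period is read off a
binarized (>1 cm/s) speed trace smoothed with a centered 1-s moving
average, thresholded at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .circular import arc_distance
from .session import BehaviorSession

VELOCITY_FLOOR_CM_S = 5.0  # frames slower than this are discarded from maps
STOP_SPEED_CM_S = 1.0
STOP_SEARCH_S = 5.0
STOP_SEARCH_CM = 50.0
MIN_STATIONARY_S = 0.5
BOUT_CM = 8.0
POST_STOP_WINDOW_CM = 18.0  # stationary window extends this far past the stop
RESAMPLE_DT_S = 0.15


class NoRewardError(ValueError):
    """Raised when a lap has no reward event."""


@dataclass
class RunningStart:
    lap: int
    stop_time: float
    stop_position: float
    start_time: float
    start_position: float
    fallback: bool  # True if the deterministic fallback rule was used


def bin_behavior(session: BehaviorSession, n_bins: int = 50):
    """Per-bin velocity map, lick-count map and lick-probability map.

    Velocity uses only frames faster than 5 cm/s; unoccupied bins are
    NaN rather than zero. Lick probability is the fraction of laps with
    at least one lick in the bin.
    """
    if session.n_laps < 1:
        raise ValueError("need at least one complete lap")
    L = session.belt_length_cm
    bin_of = lambda pos: np.minimum((pos / L * n_bins).astype(int), n_bins - 1)

    fast = session.velocity >= VELOCITY_FLOOR_CM_S
    bins = bin_of(session.position[fast])
    occ = np.bincount(bins, minlength=n_bins).astype(float)
    vsum = np.bincount(bins, weights=session.velocity[fast], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        velocity_map = np.where(occ > 0, vsum / occ, np.nan)

    lick_frames = session.lick_frames()
    lick_frames = lick_frames[lick_frames < session.n_frames]
    lick_bins = bin_of(session.position[lick_frames])
    lick_laps = session.lap_index[lick_frames]
    lick_count = np.bincount(lick_bins, minlength=n_bins).astype(float)

    n_laps = session.n_laps
    hit = np.zeros((n_laps, n_bins), dtype=bool)
    hit[lick_laps, lick_bins] = True
    lick_prob = hit.mean(axis=0)
    return velocity_map, lick_count, lick_prob


def find_running_start(session: BehaviorSession, lap: int) -> RunningStart:
    """Locate the post-reward stop and the running start that ends it."""
    reward = session.lap_reward(lap)
    if reward is None:
        raise NoRewardError(f"lap {lap} has no reward event")
    t_reward, _ = reward
    fr = session.frame_rate
    i_reward = int(np.searchsorted(session.time, t_reward))
    n = session.n_frames
    # bounded analysis window: the stationary period plus the running
    # start resolve well within 40 s of the reward
    horizon = min(i_reward + int(round(40.0 * fr)) + 1, n)
    v = session.velocity[:horizon]
    t = session.time[:horizon]
    n = horizon

    # cumulative travel from the reward
    Lb = session.belt_length_cm
    dx = np.diff(session.position[i_reward:horizon])
    dx = np.where(dx < -Lb / 2, dx + Lb, dx)  # unwrap belt resets
    travel = np.concatenate([[0.0], np.cumsum(np.abs(dx))])

    lim = i_reward + travel.size
    within = np.flatnonzero(
        (t[i_reward:lim] - t_reward <= STOP_SEARCH_S) & (travel <= STOP_SEARCH_CM)
    )
    search = i_reward + within
    sub1 = search[v[search] < STOP_SPEED_CM_S]
    if sub1.size:
        i_stop = int(sub1[0])
    else:
        sub5 = search[v[search] < VELOCITY_FLOOR_CM_S]
        i_stop = int(sub5[0]) if sub5.size else int(search[np.argmin(v[search])])

    # analysis window: reward to 18 cm of travel past the stop
    stop_travel = travel[i_stop - i_reward]
    past = np.flatnonzero(travel > stop_travel + POST_STOP_WINDOW_CM)
    i_end = i_reward + (int(past[0]) if past.size else travel.size - 1)
    i_end = min(max(i_end, i_stop + int(round(2 * fr))), n - 1)

    moving = (v[i_reward : i_end + 1] > STOP_SPEED_CM_S).astype(float)
    # zero out small (<8 cm) running bouts inside the stationary window
    idx = np.flatnonzero(np.diff(np.concatenate([[0.0], moving, [0.0]])))
    for a, b in zip(idx[::2], idx[1::2]):
        seg = slice(i_reward + a, i_reward + b)
        seg_travel = (
            travel[min(b, travel.size - 1)] - travel[a] if a < travel.size else BOUT_CM
        )
        if seg_travel < BOUT_CM and i_reward + a > i_stop:
            moving[a:b] = 0.0

    w = max(int(round(fr)) | 1, 3)
    smoothed = uniform_filter1d(moving, size=w, mode="nearest")
    rel_stop = i_stop - i_reward
    after = np.flatnonzero(smoothed[rel_stop:] > 0.5)
    fallback = False
    if after.size:
        i_start = i_stop + int(after[0])
    else:  # unresolvable within the window: take the latest sub-1 cm/s frame
        fallback = True
        still = np.flatnonzero(v[i_stop : i_end + 1] < STOP_SPEED_CM_S)
        i_start = i_stop + (int(still[-1]) + 1 if still.size else 0)
    i_start = min(i_start, n - 1)

    # a stationary period shorter than 0.5 s does not qualify; keep the
    # detected frame but flag it so callers can audit the lap
    if t[i_start] - t[i_stop] < MIN_STATIONARY_S:
        fallback = True
    return RunningStart(
        lap=lap,
        stop_time=float(t[i_stop]),
        stop_position=float(session.position[i_stop]),
        start_time=float(t[i_start]),
        start_position=float(session.position[i_start]),
        fallback=fallback,
    )


def running_start_table(session: BehaviorSession, laps=None) -> pd.DataFrame:
    """Rewarded running starts for each requested lap (default: all laps)."""
    if laps is None:
        laps = range(session.n_laps)
    rows = []
    for lap in laps:
        try:
            rs = find_running_start(session, lap)
        except NoRewardError:
            continue
        rows.append(
            {
                "lap": rs.lap,
                "stop_time": rs.stop_time,
                "stop_position": rs.stop_position,
                "start_time": rs.start_time,
                "start_position": rs.start_position,
                "fallback": rs.fallback,
            }
        )
    return pd.DataFrame(rows)


def find_nonrewarded_starts(session: BehaviorSession):
    """Running starts after mid-track (non-rewarded) stops, pre-switch laps only.

    The velocity trace is resampled at ~6.7 Hz; stationary periods are
    sub-1 cm/s stretches lasting at least 1 s. The first post-reward
    start of each lap and any start within 10 cm of the previous reward
    are excluded.
    """
    pre = session.lap_index < session.reward_switch_lap
    if not np.any(pre):
        return []
    t_end = session.time[pre][-1]
    t_rs = np.arange(session.time[0], t_end, RESAMPLE_DT_S)
    v_rs = np.interp(t_rs, session.time, session.velocity)
    pos_rs = np.interp(t_rs, session.time, np.unwrap(session.position, period=session.belt_length_cm))
    pos_rs = np.mod(pos_rs, session.belt_length_cm)

    still = (v_rs < STOP_SPEED_CM_S).astype(int)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], still, [0]])))
    min_pts = int(np.ceil(1.0 / RESAMPLE_DT_S))
    starts = []
    for a, b in zip(edges[::2], edges[1::2]):  # [a, b) is a stationary run
        if b - a < min_pts or b >= t_rs.size:
            continue
        t_start = t_rs[b]
        pos = pos_rs[b]
        i_prev = int(np.searchsorted(session.reward_times, t_start)) - 1
        if i_prev >= 0:
            t_prev = session.reward_times[i_prev]
            prev_pos = session.reward_positions[i_prev]
            if arc_distance(pos, prev_pos, session.belt_length_cm) < 10.0:
                continue
            # the first stationary period after a reward is the rewarded stop
            if t_rs[a] - t_prev >= 0 and not np.any(
                (t_rs[edges[::2]] > t_prev) & (t_rs[edges[::2]] < t_rs[a])
            ):
                continue
        starts.append((float(t_start), float(pos)))
    return starts
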