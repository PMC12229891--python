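"""Space-versus-time coding analysis for goal-referenced cells.

Each analysis lap runs from the post-reward running onset to the next
lap's post-reward stop. The lap's dF/F is binned two ways: 50 bins over
the lap's own travelled *distance* (space map) and 50 bins over a fixed
*duration* equal to the session-median full-lap time (time map; longer
laps are truncated, shorter laps leave trailing bins missing). Sorting
laps into speed terciles dissociates the two codes: a spatially locked
cell keeps its space-map peak across terciles while its time-map peak
scales with 1/speed, and vice versa for a temporally locked cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import BehaviorSession

N_BINS = 50
MAX_PEAK_DISTANCE_CM = 90.0  # cells peaking farther from the onset are excluded
PEAK_DISCREPANCY_CM = 18.0  # slow-vs-fast space-peak mismatch that excludes a cell


@dataclass
class SpaceTimeMaps:
    space: np.ndarray  # (n_laps, 50), dF/F mean per distance bin
    time: np.ndarray  # (n_laps, 50), dF/F mean per duration bin
    lap_distance_cm: np.ndarray
    lap_duration_s: np.ndarray
    fixed_duration_s: float
    lap_ids: np.ndarray


def build_spacetime_maps(
    dff_trace: np.ndarray,
    session: BehaviorSession,
    starts: pd.DataFrame,
    max_laps: int = 100,
) -> SpaceTimeMaps:
    """Space and time maps for one cell over the pre-switch laps."""
    starts = starts.sort_values("lap").reset_index(drop=True)
    n_laps_avail = min(len(starts) - 1, session.reward_switch_lap, max_laps)
    if n_laps_avail < 1:
        raise ValueError("need at least two running starts to segment a lap")
    x = np.unwrap(session.position, period=session.belt_length_cm)
    t = session.time

    spans = []
    for j in range(n_laps_avail):
        t0 = starts.loc[j, "start_time"]
        t1 = starts.loc[j + 1, "stop_time"]
        if not np.isfinite(t0) or not np.isfinite(t1) or t1 <= t0:
            continue
        spans.append((j, t0, t1))
    durations = np.array([t1 - t0 for _, t0, t1 in spans])
    fixed_t = float(np.median(durations))

    space = np.full((len(spans), N_BINS), np.nan)
    time = np.full((len(spans), N_BINS), np.nan)
    dist = np.empty(len(spans))
    for row, (j, t0, t1) in enumerate(spans):
        a, b = np.searchsorted(t, [t0, t1])
        b = min(b, t.size)
        travel = x[a:b] - x[a]
        total = travel[-1] if b > a else 0.0
        dist[row] = total
        vals = dff_trace[a:b]
        if total > 0:
            sbins = np.minimum((travel / total * N_BINS).astype(int), N_BINS - 1)
            space[row] = _bin_mean(vals, sbins)
        rel_t = t[a:b] - t0
        inside = rel_t < fixed_t
        tbins = np.minimum((rel_t[inside] / fixed_t * N_BINS).astype(int), N_BINS - 1)
        time[row] = _bin_mean(vals[inside], tbins)
    return SpaceTimeMaps(
        space=space,
        time=time,
        lap_distance_cm=dist,
        lap_duration_s=durations,
        fixed_duration_s=fixed_t,
        lap_ids=np.array([j for j, _, _ in spans]),
    )


def _bin_mean(values, bins):
    cnt = np.bincount(bins, minlength=N_BINS).astype(float)
    s = np.bincount(bins, weights=values, minlength=N_BINS)
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, s / cnt, np.nan)


def lap_speeds_to_peak(
    session: BehaviorSession,
    starts: pd.DataFrame,
    pf_peak_distance_cm: float,
    lap_ids: np.ndarray,
) -> np.ndarray:
    """Mean running speed from each lap's start to the field peak."""
    starts = starts.sort_values("lap").set_index("lap")
    x = np.unwrap(session.position, period=session.belt_length_cm)
    t = session.time
    speeds = np.full(lap_ids.size, np.nan)
    for row, j in enumerate(lap_ids):
        t0 = starts.loc[j, "start_time"]
        a = int(np.searchsorted(t, t0))
        travel = x[a:] - x[a]
        hit = np.searchsorted(travel, pf_peak_distance_cm)
        if hit >= travel.size:
            continue
        dt = t[a + hit] - t0
        if dt > 0:
            speeds[row] = pf_peak_distance_cm / dt
    return speeds


def speed_terciles(speeds: np.ndarray):
    """Lap indices split into slow/medium/fast thirds by speed."""
    ok = np.flatnonzero(np.isfinite(speeds))
    if ok.size < 3:
        raise ValueError("need at least 3 laps with defined speed")
    order = ok[np.argsort(speeds[ok])]
    thirds = np.array_split(order, 3)
    return {"slow": thirds[0], "medium": thirds[1], "fast": thirds[2]}


def tercile_peaks(maps: SpaceTimeMaps, groups: dict):
    """Peak bins of tercile-averaged space and time maps.

    Returns a DataFrame with one row per tercile: space_peak_bin,
    space_peak_cm (peak fraction x median lap distance), time_peak_bin,
    time_peak_s.
    """
    import warnings

    rows = []
    med_dist = float(np.median(maps.lap_distance_cm))
    for name in ("slow", "medium", "fast"):
        laps = groups[name]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN trailing bins
            sp = np.nanmean(maps.space[laps], axis=0)
            tm = np.nanmean(maps.time[laps], axis=0)
        sbin = int(np.nanargmax(np.nan_to_num(sp)))
        tbin = int(np.nanargmax(np.nan_to_num(tm)))
        rows.append(
            {
                "tercile": name,
                "space_peak_bin": sbin,
                "space_peak_cm": (sbin + 0.5) / N_BINS * med_dist,
                "time_peak_bin": tbin,
                "time_peak_s": (tbin + 0.5) / N_BINS * maps.fixed_duration_s,
            }
        )
    return pd.DataFrame(rows)


def cell_passes_exclusions(peaks: pd.DataFrame, pf_peak_distance_cm: float) -> bool:
    """Exclusion rules: field peak within 90 cm of the running onset and
    slow-vs-fast space-peak discrepancy under 18 cm."""
    if pf_peak_distance_cm > MAX_PEAK_DISTANCE_CM:
        return False
    slow = peaks.loc[peaks["tercile"] == "slow", "space_peak_cm"].iloc[0]
    fast = peaks.loc[peaks["tercile"] == "fast", "space_peak_cm"].iloc[0]
    return abs(slow - fast) <= PEAK_DISCREPANCY_CM
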