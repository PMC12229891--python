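"""Intracellular V_m analysis: spike stripping, trial baseline correction,
spatial binning in space- and goal-referenced frames, plateau detection,
and decomposition of the reward-switch dV_m into goal- and space-
referenced synaptic components.

The decomposition logic: averaging trials in belt coordinates (space
frame) cancels the space-referenced input between conditions, so
dV_m = post - pre isolates the *goal* component, which appears 92 cm
(half the 184-cm belt) past the original field; its signed area within
+-30 cm of that point is Area_Goal. Re-zeroing each trial at its
running start (goal frame) instead cancels the goal-referenced input,
and the *space* component appears 92 cm away in that frame, giving
Area_Space. The goal/space index is
(Area_Goal - Area_Space)/(Area_Goal + Area_Space).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .behavior import running_start_table
from .circular import circular_com, forward_distance, wrap
from .session import BehaviorSession, VmRaw

SLOPE_THRESHOLD_MV_PER_MS = 20.0
EXCISE_BEFORE_MS = 1.0
EXCISE_AFTER_MS = 4.0
BASELINE_TARGET_MV = -50.0
THRESHOLD_PERCENTILE = 5.0
PLATEAU_LEVEL_MV = -35.0
PLATEAU_MIN_MS = 100.0
PLATEAU_MERGE_MS = 10.0
AUC_HALF_WINDOW_CM = 30.0
GOAL_PF_SHIFT_CM = 92.0
PF_RATE_FLOOR_FRAC = 0.10
MIN_PRE_TRIALS = 4
MIN_POST_TRIALS = 3


# ---------------------------------------------------------------------------
# spikes and baseline
# ---------------------------------------------------------------------------


def detect_spikes(vm: np.ndarray, fs: float):
    """Spike onsets by dV/dt threshold.

    Returns (onset_indices, threshold_estimates). The onset is the last
    sample before the slope first exceeds 20 mV/ms; its V_m value
    estimates the AP threshold. Fast rises that do not reach 0 mV
    within 2 ms (for example plateau edges) are rejected.
    """
    vm = np.asarray(vm, dtype=float)
    slope = np.diff(vm) * fs / 1000.0  # mV/ms
    fast = slope > SLOPE_THRESHOLD_MV_PER_MS
    starts = np.flatnonzero(fast & ~np.concatenate([[False], fast[:-1]]))
    look = max(int(round(0.002 * fs)), 2)
    refractory = int(round(0.004 * fs))
    onsets, thresholds = [], []
    last = -np.inf
    for i in starts:
        if i - last < refractory:
            continue
        if np.max(vm[i : i + look]) < 0.0:
            continue
        onsets.append(int(i))
        thresholds.append(float(vm[i]))
        last = i
    return np.array(onsets, dtype=int), np.array(thresholds)


def strip_spikes(vm: np.ndarray, fs: float, onsets: np.ndarray) -> np.ndarray:
    """Excise 1 ms before to 4 ms after each onset, linearly interpolated."""
    out = np.asarray(vm, dtype=float).copy()
    n = out.size
    pre = int(round(EXCISE_BEFORE_MS / 1000.0 * fs))
    post = int(round(EXCISE_AFTER_MS / 1000.0 * fs))
    for i in onsets:
        a, b = max(i - pre, 0), min(i + post, n - 1)
        out[a : b + 1] = np.linspace(out[a], out[b], b - a + 1)
    return out


def trial_baseline_offsets(thresholds: np.ndarray, spike_laps: np.ndarray, n_trials: int):
    """Per-trial baseline offset: (5th pct of the trial's AP-threshold
    estimates) - (-50 mV). Trials without spikes inherit the session
    median offset (0 if no trial has one)."""
    offsets = np.full(n_trials, np.nan)
    for k in range(n_trials):
        t = thresholds[spike_laps == k]
        if t.size:
            offsets[k] = np.percentile(t, THRESHOLD_PERCENTILE) - BASELINE_TARGET_MV
    if np.all(np.isnan(offsets)):
        return np.zeros(n_trials), True
    med = float(np.nanmedian(offsets))
    return np.where(np.isnan(offsets), med, offsets), False


# ---------------------------------------------------------------------------
# plateaus
# ---------------------------------------------------------------------------


def detect_plateaus(vm: np.ndarray, fs: float):
    """Supra-(-35 mV) segments lasting over 100 ms after merging gaps <= 10 ms.

    Returns a list of (start_index, duration_ms).
    """
    above = np.asarray(vm) > PLATEAU_LEVEL_MV
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.astype(int), [0]])))
    segs = list(zip(edges[::2], edges[1::2]))  # [a, b)
    if not segs:
        return []
    merge_gap = PLATEAU_MERGE_MS / 1000.0 * fs
    merged = [list(segs[0])]
    for a, b in segs[1:]:
        if a - merged[-1][1] <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = PLATEAU_MIN_MS / 1000.0 * fs
    return [(int(a), (b - a) / fs * 1000.0) for a, b in merged if (b - a) > min_len]


def plateau_rate(n_plateaus: int, n_spikes: int) -> float:
    """Plateau rate per 100 spikes; undefined (NaN) with zero spikes."""
    if n_spikes == 0:
        return float("nan")
    return 100.0 * n_plateaus / n_spikes


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@dataclass
class VmRampSet:
    """Per-trial 1-cm-binned V_m ramps and AP rates in both frames."""

    ramps_space: np.ndarray  # (n_trials, n_bins)
    ramps_goal: np.ndarray
    rate_space: np.ndarray  # per-trial AP rate maps (n_trials, n_bins)
    rate_goal: np.ndarray
    trial_has_plateau: np.ndarray  # bool per trial
    goal_frame_valid: np.ndarray  # bool per trial (running start detected)
    n_laps_pre: int
    bin_cm: float
    belt_length_cm: float

    @property
    def n_trials(self) -> int:
        return self.ramps_space.shape[0]

    def condition_trials(self, condition: str) -> np.ndarray:
        if condition == "pre":
            return np.arange(self.n_laps_pre)
        return np.arange(self.n_laps_pre, self.n_trials)

    def mean_rate_map(self, condition: str, frame: str = "space") -> np.ndarray:
        """Trial-averaged AP rate map for one condition and frame."""
        trials = self.condition_trials(condition)
        rates = self.rate_space if frame == "space" else self.rate_goal
        if frame == "goal":
            trials = trials[self.goal_frame_valid[trials]]
        with np.errstate(invalid="ignore"):
            return (
                np.nanmean(rates[trials], axis=0)
                if trials.size
                else np.full(rates.shape[1], np.nan)
            )


def _bin_means(values, bins, n_bins):
    cnt = np.bincount(bins, minlength=n_bins).astype(float)
    s = np.bincount(bins, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, s / cnt, np.nan)


def bin_vm(
    vm_raw: VmRaw,
    behavior: BehaviorSession,
    n_laps_pre: int,
    bin_cm: float = 1.0,
    starts: pd.DataFrame | None = None,
) -> VmRampSet:
    """Strip spikes, baseline-correct per trial, and bin V_m at 1 cm in
    the space frame and (re-zeroed at each lap's running start) the
    goal frame. Also bins spatial AP rates (spikes / time per bin,
    averaged across trials)."""
    fs = behavior.frame_rate
    vm = np.asarray(vm_raw.vm, dtype=float)
    n_trials = behavior.n_laps
    L = behavior.belt_length_cm
    n_bins = int(round(L / bin_cm))

    onsets, thresholds = detect_spikes(vm, fs)
    spike_laps = behavior.lap_index[onsets] if onsets.size else np.empty(0, dtype=int)
    offsets, _no_spikes = trial_baseline_offsets(thresholds, spike_laps, n_trials)
    clean = strip_spikes(vm, fs, onsets) - offsets[behavior.lap_index]

    plateaus = detect_plateaus(vm, fs)
    has_plateau = np.zeros(n_trials, dtype=bool)
    for a, dur_ms in plateaus:
        b = min(a + int(round(dur_ms / 1000.0 * fs)), behavior.n_frames - 1)
        has_plateau[np.unique(behavior.lap_index[a : b + 1])] = True

    # goal-frame coordinate: distance run since the lap's running start
    if starts is None:
        starts = running_start_table(behavior)
    start_times = starts["start_time"].to_numpy()
    x = behavior.lap_index * L + behavior.position
    start_x = np.interp(start_times, behavior.time, x)
    k = np.searchsorted(start_times, behavior.time, side="right") - 1
    valid_frame = k >= 0
    goal_coord = np.where(valid_frame, wrap(x - start_x[np.clip(k, 0, None)], L), 0.0)
    goal_frame_valid = np.zeros(n_trials, dtype=bool)

    bins_space = np.minimum((behavior.position / bin_cm).astype(int), n_bins - 1)
    bins_goal = np.minimum((goal_coord / bin_cm).astype(int), n_bins - 1)

    ramps_space = np.full((n_trials, n_bins), np.nan)
    ramps_goal = np.full((n_trials, n_bins), np.nan)
    rate_space = np.full((n_trials, n_bins), np.nan)
    rate_goal = np.full((n_trials, n_bins), np.nan)
    bounds = np.searchsorted(behavior.lap_index, np.arange(n_trials + 1))
    for t in range(n_trials):
        a, b = int(bounds[t]), int(bounds[t + 1])
        if a == b:
            continue
        ramps_space[t] = _bin_means(clean[a:b], bins_space[a:b], n_bins)
        occ_t = np.bincount(bins_space[a:b], minlength=n_bins) / fs
        spk = onsets[(onsets >= a) & (onsets < b)] if onsets.size else np.empty(0, dtype=int)
        cnt = np.bincount(bins_space[spk], minlength=n_bins) if spk.size else np.zeros(n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate_space[t] = np.where(occ_t > 0, cnt / occ_t, np.nan)
        vf = valid_frame[a:b]
        if np.any(vf):
            bg = bins_goal[a:b][vf]
            ramps_goal[t] = _bin_means(clean[a:b][vf], bg, n_bins)
            occ_g = np.bincount(bg, minlength=n_bins) / fs
            spkg = spk[valid_frame[spk]] if spk.size else spk
            cntg = np.bincount(bins_goal[spkg], minlength=n_bins) if spkg.size else np.zeros(n_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                rate_goal[t] = np.where(occ_g > 0, cntg / occ_g, np.nan)
            goal_frame_valid[t] = True

    return VmRampSet(
        ramps_space=ramps_space,
        ramps_goal=ramps_goal,
        rate_space=rate_space,
        rate_goal=rate_goal,
        trial_has_plateau=has_plateau,
        goal_frame_valid=goal_frame_valid,
        n_laps_pre=n_laps_pre,
        bin_cm=bin_cm,
        belt_length_cm=L,
    )


# ---------------------------------------------------------------------------
# place-field location and decomposition
# ---------------------------------------------------------------------------


def pf_location(rate_map: np.ndarray, bin_cm: float = 1.0, smooth_sigma_bins: float = 2.0):
    """PF location: circular COM of the smoothed rate map, excluding bins
    below 10% of the peak.

    Returns (location_cm, two_fields_flag). Cells whose smoothed map
    has a second above-threshold region peaking over half the global
    maximum are flagged as having two distinct fields.
    """
    x = np.nan_to_num(np.asarray(rate_map, dtype=float))
    if x.max() <= 0:
        return float("nan"), False
    sm = gaussian_filter1d(x, smooth_sigma_bins, mode="wrap")
    peak = sm.max()
    keep = sm >= PF_RATE_FLOOR_FRAC * peak
    n = x.size
    L = n * bin_cm
    com = circular_com(np.where(keep, sm, 0.0), (np.arange(n) + 0.5) * bin_cm, L)
    # count disjoint circular regions above threshold
    ids = np.flatnonzero(np.diff(np.concatenate([[0], keep.astype(int), [0]])))
    regions = list(zip(ids[::2], ids[1::2]))
    if len(regions) > 1 and keep[0] and keep[-1]:
        a0, b0 = regions[0]
        regions[-1] = (regions[-1][0], b0 + n)
        regions = regions[1:]
    two = False
    if len(regions) > 1:
        maxima = sorted((sm[np.arange(a, b) % n].max() for a, b in regions), reverse=True)
        two = maxima[1] >= 0.5 * peak
    return com, two


def ramp_pf_location(mean_ramp: np.ndarray, bin_cm: float = 1.0):
    """PF location from the subthreshold ramp itself (used when a
    recording has too few spikes for an AP-rate map): the ramp is
    baselined at its 20th percentile and treated as a rate map."""
    r = np.asarray(mean_ramp, dtype=float)
    r = np.nan_to_num(r, nan=np.nanmin(r))
    bumps = np.clip(r - np.percentile(r, 20), 0.0, None)
    return pf_location(bumps, bin_cm)


@dataclass
class VmDecomposition:
    area_goal: float
    area_space: float
    index: float
    symmetry: float
    area_goal_left: float
    area_goal_right: float
    area_space_left: float
    area_space_right: float
    reconstruction_deviation: float
    n_pre_trials: int
    n_post_trials: int
    excluded: bool = False
    exclusion_reason: str = ""
    pf_pre_space_cm: float = float("nan")
    pf_pre_goal_cm: float = float("nan")


def _window_area(delta: np.ndarray, center_cm: float, bin_cm: float):
    """Signed AUC of a binned trace within +-30 cm of ``center_cm``,
    returned as (total, left, right) in mV*cm with circular wrap.

    The center bin contributes to the total but to neither flank, so a
    perfectly symmetric bump has equal left and right subareas.
    """
    n = delta.size
    c = int(np.floor(center_cm / bin_cm))
    half = int(round(AUC_HALF_WINDOW_CM / bin_cm))
    vals = np.nan_to_num(delta, nan=0.0)
    left = float(vals[(c + np.arange(-half, 0)) % n].sum() * bin_cm)
    right = float(vals[(c + np.arange(1, half + 1)) % n].sum() * bin_cm)
    center = float(vals[c % n] * bin_cm)
    return left + center + right, left, right


def clean_trial_sets(rampset: VmRampSet):
    """Trials usable for the decomposition means: pre trials after the
    last pre-switch plateau, post trials before the first post-switch
    plateau, all themselves plateau-free (and with a valid goal frame).

    The first post-switch trial is a transition lap — its running start
    is still anchored to the old reward, so neither frame isolates a
    single component on it — and is excluded.
    """
    n_pre = rampset.n_laps_pre
    pre = np.arange(n_pre)
    post = np.arange(n_pre + 1, rampset.n_trials)
    hp = rampset.trial_has_plateau
    pre_plateaus = pre[hp[pre]]
    if pre_plateaus.size:
        pre = pre[pre > pre_plateaus.max()]
    post_plateaus = post[hp[post]]
    if post_plateaus.size:
        post = post[post < post_plateaus.min()]
    pre = pre[rampset.goal_frame_valid[pre]]
    post = post[rampset.goal_frame_valid[post]]
    return pre, post


def decompose(
    rampset: VmRampSet,
    pf_pre_space_cm: float,
    pf_pre_goal_cm: float,
    post_start_cm: float | None = None,
) -> VmDecomposition:
    """Goal/space decomposition of the reward-switch dV_m.

    ``pf_pre_space_cm`` / ``pf_pre_goal_cm`` are the pre-switch field
    locations in the space and goal frames (from ``pf_location`` on the
    corresponding AP-rate maps, or ``ramp_pf_location`` for sparsely
    spiking recordings). ``post_start_cm`` — the typical post-switch
    running-start belt position — maps the goal frame back onto the
    belt exactly when reconstructing; without it the mapping falls back
    to aligning the two estimated field centers.
    """
    bin_cm = rampset.bin_cm
    L = rampset.belt_length_cm
    pre, post = clean_trial_sets(rampset)
    first_post = rampset.n_laps_pre
    if rampset.trial_has_plateau[first_post : first_post + 2].any():
        return _excluded("immediate post-switch plateau", pre.size, post.size)
    if pre.size < MIN_PRE_TRIALS or post.size < MIN_POST_TRIALS:
        return _excluded(
            f"too few clean trials (pre {pre.size}, post {post.size})", pre.size, post.size
        )

    with np.errstate(invalid="ignore"):
        pre_space = np.nanmean(rampset.ramps_space[pre], axis=0)
        post_space = np.nanmean(rampset.ramps_space[post], axis=0)
        pre_goal = np.nanmean(rampset.ramps_goal[pre], axis=0)
        post_goal = np.nanmean(rampset.ramps_goal[post], axis=0)
    delta_space = post_space - pre_space
    delta_goal = post_goal - pre_goal

    goal_center = wrap(pf_pre_space_cm + GOAL_PF_SHIFT_CM, L)
    space_center_goalframe = wrap(pf_pre_goal_cm + GOAL_PF_SHIFT_CM, L)
    area_goal, gl, gr = _window_area(delta_space, goal_center, bin_cm)
    area_space, sl, sr = _window_area(delta_goal, space_center_goalframe, bin_cm)

    denom = area_goal + area_space
    index = (area_goal - area_space) / denom if denom > 0 else float("nan")
    num = min(gl, gr) + min(sl, sr)
    den = max(gl, gr) + max(sl, sr)
    symmetry = num / den if den > 0 else float("nan")

    deviation = _reconstruction_deviation(
        delta_space,
        delta_goal,
        post_space,
        pf_pre_space_cm,
        goal_center,
        space_center_goalframe,
        bin_cm,
        post_start_cm=post_start_cm,
    )
    return VmDecomposition(
        area_goal=area_goal,
        area_space=area_space,
        index=index,
        symmetry=symmetry,
        area_goal_left=gl,
        area_goal_right=gr,
        area_space_left=sl,
        area_space_right=sr,
        reconstruction_deviation=deviation,
        n_pre_trials=int(pre.size),
        n_post_trials=int(post.size),
        pf_pre_space_cm=float(pf_pre_space_cm),
        pf_pre_goal_cm=float(pf_pre_goal_cm),
    )


def _excluded(reason: str, n_pre: int, n_post: int) -> VmDecomposition:
    nan = float("nan")
    return VmDecomposition(
        area_goal=nan,
        area_space=nan,
        index=nan,
        symmetry=nan,
        area_goal_left=nan,
        area_goal_right=nan,
        area_space_left=nan,
        area_space_right=nan,
        reconstruction_deviation=nan,
        n_pre_trials=n_pre,
        n_post_trials=n_post,
        excluded=True,
        exclusion_reason=reason,
    )


def _reconstruction_deviation(
    delta_space,
    delta_goal,
    post_space,
    pf_pre_space_cm,
    goal_center,
    space_center_goalframe,
    bin_cm,
    post_start_cm=None,
):
    """Reconstruct the post ramp from the two extracted components and
    report integral |recon - original| / integral |original| over the
    union of the two +-30 cm windows (belt coordinates)."""
    n = delta_space.size
    L = n * bin_cm
    half = int(round(AUC_HALF_WINDOW_CM / bin_cm))
    offs = np.arange(-half, half + 1)

    recon = np.zeros(n)
    cg = int(np.floor(goal_center / bin_cm))
    recon[(cg + offs) % n] += np.nan_to_num(delta_space, nan=0.0)[(cg + offs) % n]
    # the space component is extracted in the goal frame and placed back
    # on the belt: goal-frame coordinate u corresponds to belt position
    # u + post running start (fallback: align the two field centers)
    cs_belt = int(np.floor(pf_pre_space_cm / bin_cm))
    if post_start_cm is not None and np.isfinite(post_start_cm):
        shift = int(round(post_start_cm / bin_cm))
        dg = np.roll(np.nan_to_num(delta_goal, nan=0.0), shift)
        recon[(cs_belt + offs) % n] += dg[(cs_belt + offs) % n]
    else:
        cs_goal = int(np.floor(space_center_goalframe / bin_cm))
        recon[(cs_belt + offs) % n] += np.nan_to_num(delta_goal, nan=0.0)[(cs_goal + offs) % n]

    union = np.unique(np.concatenate([(cg + offs) % n, (cs_belt + offs) % n]))
    baseline_mask = np.ones(n, dtype=bool)
    baseline_mask[union] = False
    original = np.nan_to_num(post_space, nan=np.nanmedian(post_space))
    original = original - (
        np.median(original[baseline_mask]) if baseline_mask.any() else np.min(original)
    )
    num = float(np.abs(recon[union] - original[union]).sum())
    den = float(np.abs(original[union]).sum())
    return num / den if den > 0 else float("nan")
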