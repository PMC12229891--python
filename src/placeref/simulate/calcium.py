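"""Synthetic calcium fluorescence with known place-field ground truth.

Each simulated cell belongs to one of four categories. *Space* cells
fire when the animal crosses a fixed belt position in both conditions.
*Goal* cells fire at a fixed arc-distance from the running start that
begins each lap, so their belt position rotates with the reward switch.
*Intermediate* cells shift their belt anchor by a uniform 16-74 cm draw,
and *nonplace* cells carry only noise. Every traversal of a cell's
anchor elicits a calcium-like transient (instantaneous rise, 0.5-s
exponential decay, GCaMP6f-like) with probability ``reliability``.

Raw fluorescence is returned (baseline plus slow sinusoidal drift plus
signal plus Gaussian noise) so that dF/F extraction is exercised
downstream. Scheduled BTSP-like events relocate a cell's field to a
given location on a given lap with a large first-lap amplitude.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from ..circular import arc_distance, forward_distance, wrap
from ..config import InvalidConfigError, SimConfig
from ..session import BehaviorSession, GroundTruth
from .treadmill import LapSchedule, simulate_behavior_full

TRANSIENT_TAU_S = 0.5
INTERMEDIATE_SHIFT_RANGE = (16.0, 74.0)


def _allocate_categories(fractions: dict, n_cells: int, rng) -> list:
    """Largest-remainder allocation so cohort fractions match exactly."""
    cats = [c for c in ("space", "goal", "intermediate", "nonplace") if fractions.get(c, 0) > 0]
    raw = np.array([fractions[c] * n_cells for c in cats])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n_cells - counts.sum()]:
        counts[i] += 1
    labels = [c for c, n in zip(cats, counts) for _ in range(n)]
    return [labels[i] for i in rng.permutation(n_cells)]


def simulate_calcium(
    config: SimConfig,
    behavior: BehaviorSession,
    schedule: LapSchedule | None = None,
):
    """Simulate a raw fluorescence matrix [n_cells x n_frames] + GroundTruth."""
    if schedule is None:
        _, schedule = simulate_behavior_full(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    L = config.belt_length_cm
    n_laps = config.n_laps_pre + config.n_laps_post
    n_cells = config.n_cells
    for cell, lap, loc in config.btsp_injection:
        if not 0 <= lap < n_laps:
            raise InvalidConfigError(f"btsp injection lap {lap} outside session")

    x_unwrapped = behavior.lap_index * L + behavior.position
    dt = 1.0 / config.frame_rate_hz
    n_frames = behavior.n_frames

    categories = _allocate_categories(config.fractions, n_cells, rng)
    injected = {int(c): (int(lap), float(loc)) for c, lap, loc in config.btsp_injection}

    # mean running-start belt position per condition (lap 0 starts at the
    # belt origin and is excluded from the pre average)
    start_pos = wrap(schedule.start_positions_unwrapped, L)
    pre_laps = np.arange(1, config.n_laps_pre)
    post_laps = np.arange(config.n_laps_pre, n_laps)
    mean_start_pre = float(np.median(start_pos[pre_laps]))
    mean_start_post = float(np.median(start_pos[post_laps])) if len(post_laps) else np.nan

    truth = GroundTruth(
        running_start_times=list(schedule.start_times),
        running_start_positions=list(start_pos),
    )
    raw_f = np.empty((n_cells, n_frames), dtype=np.float32)
    decay = np.exp(-dt / TRANSIENT_TAU_S)

    for c in range(n_cells):
        # per-cell stream: a cell's draws do not depend on the other
        # cells or on another cell's scheduled events
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, c + 1]))
        cat = categories[c]
        anchor_pre = anchor_post = np.nan
        goal_offset = np.nan
        if cat == "space":
            anchor_pre = anchor_post = rng.uniform(0, L)
            true_shift = 0.0
        elif cat == "goal":
            goal_offset = rng.uniform(5.0, 80.0)
            anchor_pre = wrap(mean_start_pre + goal_offset, L)
            anchor_post = wrap(mean_start_post + goal_offset, L)
            true_shift = float(arc_distance(anchor_pre, anchor_post, L))
        elif cat == "intermediate":
            anchor_pre = rng.uniform(0, L)
            true_shift = rng.uniform(*INTERMEDIATE_SHIFT_RANGE)
            anchor_post = wrap(anchor_pre + rng.choice([-1.0, 1.0]) * true_shift, L)
        else:
            true_shift = np.nan

        fires = rng.random(n_laps) < config.reliability
        amps = config.transient_amp * np.maximum(
            1.0 + 0.2 * rng.standard_normal(n_laps), 0.4
        )
        event_lap, event_loc = injected.get(c, (None, None))
        onset = 0 if cat != "nonplace" else np.nan

        impulses = np.zeros(n_frames)
        for lap in range(n_laps):
            if event_lap is not None and lap >= event_lap:
                target = lap * L + event_loc
                amp = (
                    max(2.5, 2.0 * config.transient_amp)
                    if lap == event_lap
                    else config.transient_amp * max(1.0 + 0.2 * rng.standard_normal(), 0.4)
                )
            else:
                if cat == "nonplace" or not fires[lap]:
                    continue
                if cat == "goal":
                    target = schedule.start_positions_unwrapped[lap] + goal_offset
                else:
                    anchor = anchor_pre if lap < config.n_laps_pre else anchor_post
                    target = lap * L + anchor
                amp = amps[lap]
            f = int(np.searchsorted(x_unwrapped, target))
            if 0 < f < n_frames:
                impulses[f] += amp
        dff_true = lfilter([1.0], [1.0, -decay], impulses)

        drift = config.drift_amp * np.sin(
            2 * np.pi * behavior.time / 600.0 + rng.uniform(0, 2 * np.pi)
        )
        f_trace = (config.baseline_f + drift) * (1.0 + dff_true)
        if config.noise_sd > 0:
            f_trace = f_trace + config.baseline_f * config.noise_sd * rng.standard_normal(
                n_frames
            )
        raw_f[c] = f_trace

        if event_lap is not None:
            onset = event_lap
            truth.btsp_events.append((c, event_lap, event_loc))
            if event_lap >= config.n_laps_pre:
                anchor_post = event_loc
                true_shift = (
                    float(arc_distance(anchor_pre, anchor_post, L))
                    if np.isfinite(anchor_pre)
                    else np.nan
                )
        truth.category.append(cat)
        truth.pf_pre_cm.append(float(anchor_pre))
        truth.pf_post_cm.append(float(anchor_post))
        truth.onset_lap.append(onset)
        truth.shift_cm.append(true_shift)

    return raw_f, truth
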