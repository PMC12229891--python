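"""Detection of abrupt, persistent place-field formation events (BTSP).

Behavioral-timescale synaptic plasticity shows up in lap-by-lap dF/F
maps as a single very large transient followed by a reliable field at
the same location. A lap qualifies as a putative event when all of:

1. its peak dF/F is in the top tenth percentile of the cell's event
   amplitudes in the same condition (separate pre/post thresholds);
2. lap activity is compared within ~45 cm of the event peak;
3. at least 4 of the 5 subsequent laps have a significant event there;
4. the mean in-window amplitude of the following five laps exceeds
   twice that of the preceding five laps;
5. the event's peak dF/F exceeds 2.

Events on the last five laps of a condition are excluded (not enough
following laps to evaluate persistence).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .circular import arc_distance, forward_distance

AMP_PERCENTILE = 90.0
PEAK_MIN_DFF = 2.0
WINDOW_CM = 45.0
FIELD_THRESHOLD_FRAC = 0.35
MEAN_PF_MAX_WIDTH_FRAC = 0.9
MEAN_PF_MIN_PEAK = 0.2
MEAN_PF_IN_OUT_RATIO = 2.0
SELECTIVITY_WINDOW_BINS = 13  # ~45 cm at 3.6 cm per bin
SELECTIVITY_THRESHOLD = 0.33
EXCLUDE_LAST_LAPS = 5


@dataclass
class FieldDefinition:
    bins: np.ndarray  # contiguous (circularly) bin indices
    width_cm: float
    peak_bin: int
    in_field_max: float
    in_out_ratio: float


@dataclass
class BTSPEvent:
    cell: int
    lap: int  # condition-relative induction lap
    peak_bin: int
    location_cm: float
    peak_dff: float
    induction_velocity: float = float("nan")
    pf_width_after: float = float("nan")
    com_pre5: float = float("nan")
    com_post5: float = float("nan")
    com_shift: float = float("nan")
    distance_from_pre_pf: float = float("nan")
    selectivity_before: float = float("nan")
    selectivity_after: float = float("nan")
    category_before: str = ""
    category_after: str = ""


def field_and_width(map_vals: np.ndarray, bin_cm: float) -> Optional[FieldDefinition]:
    """Contiguous circular bins above 35% of the map peak, around the peak."""
    x = np.nan_to_num(np.asarray(map_vals, dtype=float))
    n = x.size
    peak_bin = int(np.argmax(x))
    peak = x[peak_bin]
    if peak <= 0:
        return None
    above = x > FIELD_THRESHOLD_FRAC * peak
    bins = [peak_bin]
    i = peak_bin
    while above[(i - 1) % n] and len(bins) < n:
        i = (i - 1) % n
        bins.insert(0, i)
    j = peak_bin
    while above[(j + 1) % n] and len(bins) < n:
        j = (j + 1) % n
        bins.append(j)
    bins = np.array(bins)
    out_mask = np.ones(n, dtype=bool)
    out_mask[bins % n] = False
    out_mean = float(x[out_mask].mean()) if out_mask.any() else 0.0
    in_mean = float(x[bins % n].mean())
    ratio = in_mean / out_mean if out_mean > 0 else np.inf
    return FieldDefinition(
        bins=bins % n,
        width_cm=len(bins) * bin_cm,
        peak_bin=peak_bin,
        in_field_max=float(peak),
        in_out_ratio=ratio,
    )


def mean_activity_field(map_vals: np.ndarray, bin_cm: float) -> Optional[FieldDefinition]:
    """Field of a mean 5-lap map, with the additional qualification rules:
    width < 90% of the track, in-field max > 0.2, in/out mean ratio > 2."""
    f = field_and_width(map_vals, bin_cm)
    if f is None:
        return None
    n = np.asarray(map_vals).size
    if f.width_cm >= MEAN_PF_MAX_WIDTH_FRAC * n * bin_cm:
        return None
    if f.in_field_max <= MEAN_PF_MIN_PEAK:
        return None
    if not f.in_out_ratio > MEAN_PF_IN_OUT_RATIO:
        return None
    return f


def com(map_vals: np.ndarray, field: FieldDefinition, bin_cm: float) -> float:
    """COM = sum(x_i * d_i) / sum(x_i) over within-field bins only.

    Positions are bin centers; a field wrapping the belt origin is
    unwrapped before averaging and the result reduced mod L.
    """
    x = np.nan_to_num(np.asarray(map_vals, dtype=float))[field.bins]
    n = np.asarray(map_vals).size
    L = n * bin_cm
    # unwrap: field.bins are stored in traversal order around the peak
    b = field.bins.astype(float)
    jumps = np.flatnonzero(np.diff(b) < 0)
    if jumps.size:
        b[jumps[0] + 1 :] += n
    d = (b + 0.5) * bin_cm
    if x.sum() <= 0:
        return float("nan")
    return float(np.mod(np.sum(x * d) / np.sum(x), L))


def detect_btsp(
    lap_maps: np.ndarray,
    sig_threshold: float,
    bin_cm: float,
    cell: int = 0,
    peak_min: float = PEAK_MIN_DFF,
) -> list:
    """Putative BTSP events in one cell-condition's per-lap max maps."""
    lm = np.asarray(lap_maps, dtype=float)
    n_laps, n_bins = lm.shape
    if n_laps < 11:
        return []
    filled = np.nan_to_num(lm, nan=-np.inf)
    amps = filled.max(axis=1)
    peak_bins = filled.argmax(axis=1)
    sig_laps = amps > sig_threshold
    if not np.any(sig_laps):
        return []
    amp_cut = np.percentile(amps[sig_laps], AMP_PERCENTILE)
    half = int(round(WINDOW_CM / bin_cm))
    events = []
    for e in range(n_laps - EXCLUDE_LAST_LAPS):
        if not sig_laps[e] or amps[e] < amp_cut or amps[e] <= peak_min:
            continue
        window = (peak_bins[e] + np.arange(-half, half + 1)) % n_bins
        win_vals = np.nan_to_num(lm[:, window], nan=0.0)
        win_max = win_vals.max(axis=1)
        nxt = win_max[e + 1 : e + 6]
        if np.sum(nxt > sig_threshold) < 4:
            continue
        prev = win_max[max(e - 5, 0) : e]
        prev_mean = float(prev.mean()) if prev.size else 0.0
        next_mean = float(nxt.mean())
        if prev_mean > 0 and next_mean <= 2.0 * prev_mean:
            continue
        if prev_mean == 0 and next_mean <= 0:
            continue
        events.append(
            BTSPEvent(
                cell=cell,
                lap=e,
                peak_bin=int(peak_bins[e]),
                location_cm=(peak_bins[e] + 0.5) * bin_cm,
                peak_dff=float(amps[e]),
            )
        )
    return events


def event_metrics(
    event: BTSPEvent,
    lap_maps: np.ndarray,
    bin_cm: float,
    pre_pf_cm: float = float("nan"),
    velocity_map: np.ndarray | None = None,
) -> BTSPEvent:
    """Fill field, COM-shift, distance and velocity metrics in place.

    ``lap_maps`` is the cell-condition per-lap max map set containing
    the event. ``velocity_map`` is the event lap's per-bin mean running
    speed; induction velocity is its mean over the post-event field.
    """
    lm = np.asarray(lap_maps, dtype=float)
    n_laps, n_bins = lm.shape
    L = n_bins * bin_cm
    e = event.lap
    with np.errstate(invalid="ignore"):
        post5 = np.nanmean(lm[e + 1 : e + 6], axis=0)
        pre5 = np.nanmean(lm[max(e - 5, 0) : e], axis=0) if e > 0 else None
    f_post = mean_activity_field(post5, bin_cm)
    if f_post is not None:
        event.pf_width_after = f_post.width_cm
        event.com_post5 = com(post5, f_post, bin_cm)
        if velocity_map is not None:
            v = np.asarray(velocity_map, dtype=float)[f_post.bins]
            event.induction_velocity = float(np.nanmean(v))
    if pre5 is not None:
        f_pre = mean_activity_field(pre5, bin_cm)
        if f_pre is not None:
            event.com_pre5 = com(pre5, f_pre, bin_cm)
    if np.isfinite(event.com_pre5) and np.isfinite(event.com_post5):
        d = forward_distance(event.com_pre5, event.com_post5, L)
        event.com_shift = float(d if d <= L / 2 else d - L)  # signed, running direction +
    if np.isfinite(pre_pf_cm):
        event.distance_from_pre_pf = float(arc_distance(event.location_cm, pre_pf_cm, L))
    return event


def goal_selectivity(
    lap_maps: np.ndarray,
    space_center_bin: int,
    goal_center_bin: int,
    event_lap: int | None = None,
    window_bins: int = SELECTIVITY_WINDOW_BINS,
):
    """Per-lap goal-referenced selectivity and before/after summaries.

    Selectivity = (G - S) / (G + S) where G and S are the lap's peak
    dF/F within ~45-cm windows centered on the goal-referenced and
    space-referenced field locations. Laps with G + S = 0 are NaN.
    Category: > +0.33 goal-referenced, < -0.33 space-referenced,
    otherwise non-selective.

    Returns (per-lap selectivity, before_mean, after_mean) where the
    before/after split is at ``event_lap`` (before excludes it, after
    includes it); both are NaN when no event lap is given.
    """
    lm = np.nan_to_num(np.asarray(lap_maps, dtype=float), nan=0.0)
    n_laps, n_bins = lm.shape
    half = window_bins // 2

    def win_vals(center):
        idx = (center + np.arange(-half, half + 1)) % n_bins
        return lm[:, idx].max(axis=1)

    g = win_vals(goal_center_bin)
    s = win_vals(space_center_bin)
    with np.errstate(invalid="ignore", divide="ignore"):
        sel = np.where(g + s > 0, (g - s) / (g + s), np.nan)
    def _mean(vals):
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    before = after = float("nan")
    if event_lap is not None:
        if event_lap > 0:
            before = _mean(sel[:event_lap])
        after = _mean(sel[event_lap:])
    return sel, before, after


def selectivity_category(value: float) -> str:
    if not np.isfinite(value):
        return "undefined"
    if value > SELECTIVITY_THRESHOLD:
        return "goal"
    if value < -SELECTIVITY_THRESHOLD:
        return "space"
    return "non-selective"
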