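"""Place-cell identification from dF/F.

Pipeline per cell and condition (before / after the reward switch,
first 100 laps each):

1. spatial maps on 50 bins (3.6 cm) from frames faster than 5 cm/s:
   per-lap maps hold the per-bin *maximum* dF/F (used for event
   detection), the trial-averaged map holds the per-bin *mean* (used
   for tuning, SI and place-field location);
2. onset lap: first lap where the lap and at least 2 of the next 5 laps
   have >=3 consecutive significant bins within +-45 cm of the field
   peak;
3. spatial information SI = sum_i p_i * x_i * log2(|x_i / xbar|),
   tested against a 200-fold circular-shift / 6-chunk shuffle null
   (spatially modulated if SI exceeds the null's 95th percentile);
4. reliability: fraction of post-onset laps with an in-field event;
   a place cell is both spatially modulated (>95th pct) and reliable
   (>0.2).

The SI weight is the activity x_i itself (not the normalized rate of
the classical formulation), so SI scales linearly with the map:
SI(k*x) = k*SI(x). ``si_classical`` provides the textbook variant; the
two are never silently exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import VELOCITY_FLOOR_CM_S
from .session import BehaviorSession

N_BINS_DEFAULT = 50
ONSET_WINDOW_CM = 45.0  # half-width of the event window around the field peak
MIN_CONSECUTIVE_BINS = 3
RELIABILITY_THRESHOLD = 0.2
SI_PERCENTILE = 95.0
SHUFFLE_MIN_SHIFT = 500
SHUFFLE_CHUNKS = 6


@dataclass
class BinnedFrames:
    """Reusable frame->bin indexing for one condition's laps."""

    frames: np.ndarray  # indices into the session
    bins: np.ndarray  # spatial bin per frame
    lap: np.ndarray  # condition-relative lap per frame
    retained: np.ndarray  # velocity filter
    n_laps: int
    n_bins: int
    bin_cm: float
    occupancy_counts: np.ndarray
    # precomputed segment layout for per-lap per-bin maxima
    _order: np.ndarray
    _seg_starts: np.ndarray
    _seg_keys: np.ndarray

    @property
    def occupancy(self) -> np.ndarray:
        total = self.occupancy_counts.sum()
        return self.occupancy_counts / total if total else self.occupancy_counts


def frame_binning(
    session: BehaviorSession, laps, n_bins: int = N_BINS_DEFAULT
) -> BinnedFrames:
    laps = np.asarray(list(laps), dtype=int)
    sel = np.isin(session.lap_index, laps)
    frames = np.flatnonzero(sel)
    L = session.belt_length_cm
    bins = np.minimum((session.position[frames] / L * n_bins).astype(int), n_bins - 1)
    lap_lookup = {int(l): i for i, l in enumerate(laps)}
    lap = np.array([lap_lookup[int(l)] for l in session.lap_index[frames]])
    retained = session.velocity[frames] > VELOCITY_FLOOR_CM_S
    occ = np.bincount(bins[retained], minlength=n_bins).astype(float)
    key = lap[retained] * n_bins + bins[retained]
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    seg_starts = np.concatenate(
        [[0], np.flatnonzero(np.diff(sorted_key)) + 1]
    ) if sorted_key.size else np.empty(0, dtype=int)
    seg_keys = sorted_key[seg_starts] if sorted_key.size else np.empty(0, dtype=int)
    return BinnedFrames(
        frames=frames,
        bins=bins,
        lap=lap,
        retained=retained,
        n_laps=len(laps),
        n_bins=n_bins,
        bin_cm=L / n_bins,
        occupancy_counts=occ,
        _order=order,
        _seg_starts=seg_starts,
        _seg_keys=seg_keys,
    )


def mean_map(dff_c: np.ndarray, bf: BinnedFrames) -> np.ndarray:
    """Trial-averaged per-bin mean dF/F (NaN where unoccupied)."""
    w = np.bincount(bf.bins[bf.retained], weights=dff_c[bf.retained], minlength=bf.n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(bf.occupancy_counts > 0, w / bf.occupancy_counts, np.nan)


def lap_max_maps(dff_c: np.ndarray, bf: BinnedFrames) -> np.ndarray:
    """Per-lap per-bin maximum dF/F, NaN where the lap never occupied the bin."""
    out = np.full((bf.n_laps, bf.n_bins), np.nan)
    vals = dff_c[bf.retained][bf._order]
    if vals.size:
        seg_max = np.maximum.reduceat(vals, bf._seg_starts)
        out[bf._seg_keys // bf.n_bins, bf._seg_keys % bf.n_bins] = seg_max
    return out


def spatial_information(x: np.ndarray, p: np.ndarray) -> float:
    """SI = sum_i p_i * x_i * log2(|x_i / xbar|), with 0*log(0) := 0."""
    x = np.nan_to_num(np.asarray(x, dtype=float))
    p = np.asarray(p, dtype=float)
    xbar = float(np.sum(p * x))
    if xbar == 0:
        return float("nan")
    nz = x != 0
    with np.errstate(divide="ignore"):
        return float(np.sum(p[nz] * x[nz] * np.log2(np.abs(x[nz] / xbar))))


def si_classical(x: np.ndarray, p: np.ndarray) -> float:
    """Classical bits-per-event form: sum_i p_i * (x_i/xbar) * log2(x_i/xbar)."""
    x = np.nan_to_num(np.asarray(x, dtype=float))
    p = np.asarray(p, dtype=float)
    xbar = float(np.sum(p * x))
    if xbar <= 0:
        return float("nan")
    r = x / xbar
    nz = r > 0
    return float(np.sum(p[nz] * r[nz] * np.log2(r[nz])))


def shuffle_null(
    dff_c: np.ndarray,
    bf: BinnedFrames,
    n_shuffles: int = 200,
    rng=None,
    min_shift: int = SHUFFLE_MIN_SHIFT,
    n_chunks: int = SHUFFLE_CHUNKS,
    si_fn=spatial_information,
) -> np.ndarray:
    """Null SI distribution: circular shift >=500 frames, then 6 equal
    chunks in randomly permuted order, maps rebuilt, SI recomputed."""
    rng = np.random.default_rng(rng)
    n = dff_c.size
    if n <= 2 * min_shift + n_chunks:
        raise ValueError(f"series too short for shuffling ({n} frames)")
    edges = np.linspace(0, n, n_chunks + 1).astype(int)
    p = bf.occupancy
    counts = bf.occupancy_counts
    bins_r = bf.bins[bf.retained]
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shift = int(rng.integers(min_shift, n - min_shift + 1))
        rolled = np.roll(dff_c, shift)
        order = rng.permutation(n_chunks)
        shuf = np.concatenate([rolled[edges[i] : edges[i + 1]] for i in order])
        w = np.bincount(bins_r, weights=shuf[bf.retained], minlength=bf.n_bins)
        with np.errstate(invalid="ignore"):
            x = np.where(counts > 0, w / counts, 0.0)
        null[s] = si_fn(x, p)
    return null


def event_bins(lap_maps: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean (n_laps, n_bins): per-lap bins with a significant event."""
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(lap_maps, nan=-np.inf) > threshold


def _qualifying_laps(ev: np.ndarray, peak_bin: int, bin_cm: float) -> np.ndarray:
    """Laps with >=3 consecutive significant bins within +-45 cm of the peak."""
    n_laps, n_bins = ev.shape
    half = int(round(ONSET_WINDOW_CM / bin_cm))
    idx = (peak_bin + np.arange(-half, half + 1)) % n_bins
    win = ev[:, idx].astype(int)
    # run-length of consecutive ones along the window
    run = np.zeros(n_laps, dtype=int)
    best = np.zeros(n_laps, dtype=int)
    for j in range(win.shape[1]):
        run = (run + 1) * win[:, j]
        best = np.maximum(best, run)
    return best >= MIN_CONSECUTIVE_BINS


def onset_lap(ev: np.ndarray, peak_bin: int, bin_cm: float):
    """First lap where the lap and >=2 of the next five laps qualify.

    Returns (onset or None, qualifying-lap mask). The onset is the
    condition-relative lap index; None means no onset was identified
    (identification then continues from lap 0).
    """
    qual = _qualifying_laps(ev, peak_bin, bin_cm)
    n = qual.size
    for l in np.flatnonzero(qual):
        if qual[l + 1 : l + 6].sum() >= 2:
            return int(l), qual
    return None, qual


def reliability(qual: np.ndarray, onset) -> float:
    """Fraction of post-onset laps with an in-field significant event."""
    start = 0 if onset is None else int(onset) + 1
    post = qual[start:]
    return float(post.mean()) if post.size else 0.0


def identify_place_cells(
    dff_mat: np.ndarray,
    thresholds: np.ndarray,
    bf: BinnedFrames,
    n_shuffles: int = 200,
    seed: int = 0,
    si_fn=spatial_information,
) -> pd.DataFrame:
    """Per-cell place-cell statistics for one condition.

    ``dff_mat`` is (n_cells, n_session_frames); ``thresholds`` is the
    per-cell significant-transient threshold. Columns: onset (NaN if
    unidentified), si, si_percentile, reliability, is_place_cell,
    peak_bin, peak_cm, com_cm.
    """
    from .circular import circular_com

    rng = np.random.default_rng(seed)
    p = bf.occupancy
    rows = []
    L = bf.n_bins * bf.bin_cm
    for c in range(dff_mat.shape[0]):
        dff_c = dff_mat[c, bf.frames]
        x = mean_map(dff_c, bf)
        x_filled = np.nan_to_num(x)
        peak_bin = int(np.argmax(x_filled))  # ties break toward the lowest bin
        si = si_fn(x_filled, p)
        lm = lap_max_maps(dff_c, bf)
        ev = event_bins(lm, thresholds[c])
        onset, qual = onset_lap(ev, peak_bin, bf.bin_cm)
        rel = reliability(qual, onset)
        if np.isfinite(si):
            null = shuffle_null(
                dff_c, bf, n_shuffles=n_shuffles, rng=rng.spawn(1)[0], si_fn=si_fn
            )
            si_pct = float(100.0 * np.mean(si > null))
            modulated = si > np.percentile(null, SI_PERCENTILE)
        else:
            si_pct, modulated = float("nan"), False
        peak_cm = (peak_bin + 0.5) * bf.bin_cm
        com_cm = circular_com(
            x_filled, (np.arange(bf.n_bins) + 0.5) * bf.bin_cm, L
        )
        rows.append(
            {
                "cell": c,
                "onset": np.nan if onset is None else onset,
                "si": si,
                "si_percentile": si_pct,
                "reliability": rel,
                "is_place_cell": bool(modulated and rel > RELIABILITY_THRESHOLD),
                "peak_bin": peak_bin,
                "peak_cm": peak_cm,
                "com_cm": com_cm,
            }
        )
    return pd.DataFrame(rows)


def condition_laps(session: BehaviorSession, condition: str, max_laps: int = 100):
    """Lap ids of the pre or post condition, capped at the first 100."""
    switch = session.reward_switch_lap
    if condition == "pre":
        laps = np.arange(0, min(switch, max_laps))
    elif condition == "post":
        laps = np.arange(switch, min(session.n_laps, switch + max_laps))
    else:
        raise ValueError("condition must be 'pre' or 'post'")
    return laps
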