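"""dF/F conversion and significant-transient detection.

Raw fluorescence is baseline-corrected with a rolling-window (5,000
frame) percentile baseline, F0 is taken as the histogram mode of the
corrected trace, and dF/F = (F - F0)/F0. The noise s.d. is estimated
from deviations *below* the dF/F histogram mode (reflecting the
sub-mode half-distribution), and frames exceeding 3 s.d. above the mode
are significant.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

BASELINE_WINDOW_FRAMES = 5000
_BASELINE_PERCENTILE = 8.0
_ANCHOR_STRIDE = 250


class InvalidCellError(ValueError):
    """Raised when a fluorescence trace yields no usable baseline (F0 <= 0)."""


def _histogram_mode(x: np.ndarray) -> float:
    """Mode of a continuous sample: median of the values in the tallest
    histogram bin, with counts smoothed over 5 bins to damp sampling
    jitter in the argmax."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(x, bins=100)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(counts, kernel, mode="same")
    i_s = int(np.argmax(smooth))
    a = max(i_s - 2, 0)
    i = a + int(np.argmax(counts[a : i_s + 3]))
    inside = x[(x >= edges[i]) & (x <= edges[i + 1])]
    return float(np.median(inside)) if inside.size else float(0.5 * (edges[i] + edges[i + 1]))


def rolling_baseline(raw_f: np.ndarray, window: int = BASELINE_WINDOW_FRAMES) -> np.ndarray:
    """Rolling low-percentile baseline, evaluated on a strided grid and
    linearly interpolated between anchors."""
    raw_f = np.asarray(raw_f, dtype=float)
    n = raw_f.size
    if n < window:
        log.info("trace shorter than baseline window (%d < %d); window shrunk", n, window)
        window = n
    half = window // 2
    anchors = np.arange(0, n, _ANCHOR_STRIDE)
    vals = np.array(
        [
            np.percentile(raw_f[max(0, a - half) : min(n, a + half + 1)], _BASELINE_PERCENTILE)
            for a in anchors
        ]
    )
    return np.interp(np.arange(n), anchors, vals)


def dff(raw_f: np.ndarray, window: int = BASELINE_WINDOW_FRAMES) -> np.ndarray:
    """Convert raw fluorescence to dF/F."""
    raw_f = np.asarray(raw_f, dtype=float)
    baseline = rolling_baseline(raw_f, window)
    corrected = raw_f - baseline + np.median(baseline)
    f0 = _histogram_mode(corrected)
    if f0 <= 0:
        raise InvalidCellError(f"baseline F0={f0:.3g} is not positive")
    return (corrected - f0) / f0


def noise_sd(dff_trace: np.ndarray) -> float:
    """Noise s.d. from the reflected sub-mode half-distribution."""
    mode = _histogram_mode(dff_trace)
    below = mode - dff_trace[dff_trace < mode]
    if below.size == 0:
        raise ValueError("degenerate dF/F histogram: no sub-mode deviations")
    return float(np.sqrt(np.mean(below**2)))


def significant_transients(dff_trace: np.ndarray):
    """Boolean mask of frames exceeding mode + 3 x noise s.d.

    Returns (mask, threshold).
    """
    dff_trace = np.asarray(dff_trace, dtype=float)
    if dff_trace.size == 0 or np.ptp(dff_trace) == 0:
        return np.zeros(dff_trace.shape, dtype=bool), np.inf
    mode = _histogram_mode(dff_trace)
    sd = noise_sd(dff_trace)
    threshold = mode + 3.0 * sd
    return dff_trace > threshold, float(threshold)
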