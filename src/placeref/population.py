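"""Population-vector (PV) correlation analysis.

A PV is the vector of all cells' trial-averaged activity at one spatial
bin. Correlating PVs at every pair of locations across two conditions
gives a 50 x 50 Pearson matrix M; the mean of its diagonal measures
*space similarity* (same belt position) and the mean of the 25-bin
(90-cm) circularly shifted diagonal measures *goal similarity* (the
position rotated with the reward). Zero-variance PVs yield undefined
correlations, which are stored as NaN and excluded from the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OFFDIAG_SHIFT_BINS = 25  # 90 cm on a 180-cm belt with 50 bins


@dataclass
class PVMatrix:
    M: np.ndarray  # (n_bins, n_bins) Pearson correlations
    label_a: str
    label_b: str

    @property
    def diag_mean(self) -> float:
        return float(np.nanmean(np.diag(self.M)))

    def offdiag_mean(self, shift: int = OFFDIAG_SHIFT_BINS) -> float:
        n = self.M.shape[0]
        i = np.arange(n)
        return float(np.nanmean(self.M[i, (i + shift) % n]))

    def similarity(self, shift: int = OFFDIAG_SHIFT_BINS):
        """(space_similarity, goal_similarity) = (diag mean, off-diag mean)."""
        return self.diag_mean, self.offdiag_mean(shift)


def pv_matrix(maps_a: np.ndarray, maps_b: np.ndarray, label_a: str = "A", label_b: str = "B") -> PVMatrix:
    """Pearson correlation between PVs of two map sets [n_cells x n_bins].

    Cell sets must be identical and identically ordered. Bins whose PV
    has zero variance produce NaN entries.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape:
        raise ValueError(f"map sets differ in shape: {maps_a.shape} vs {maps_b.shape}")
    if maps_a.shape[0] < 2:
        raise ValueError("need at least 2 cells for PV correlation")
    a = np.nan_to_num(maps_a) - np.nanmean(np.nan_to_num(maps_a), axis=0, keepdims=True)
    b = np.nan_to_num(maps_b) - np.nanmean(np.nan_to_num(maps_b), axis=0, keepdims=True)
    sa = np.sqrt(np.sum(a**2, axis=0))
    sb = np.sqrt(np.sum(b**2, axis=0))
    # columns constant up to floating-point rounding have no defined correlation
    tol_a = 1e-9 * (np.abs(maps_a).max() + 1.0)
    tol_b = 1e-9 * (np.abs(maps_b).max() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = (a.T @ b) / np.outer(sa, sb)
    M[:, sb <= tol_b] = np.nan
    M[sa <= tol_a, :] = np.nan
    return PVMatrix(M=M, label_a=label_a, label_b=label_b)


def odd_even_matrix(lap_maps: np.ndarray, label: str = "pre") -> PVMatrix:
    """PV matrix between odd- and even-lap averaged maps.

    ``lap_maps`` is (n_cells, n_laps, n_bins); per-lap maps are averaged
    over odd and even laps separately (NaN bins ignored) before
    correlation.
    """
    lap_maps = np.asarray(lap_maps, dtype=float)
    if lap_maps.ndim != 3 or lap_maps.shape[1] < 2:
        raise ValueError("need per-lap maps with at least 2 laps")
    with np.errstate(invalid="ignore"):
        odd = np.nanmean(lap_maps[:, 1::2, :], axis=1)
        even = np.nanmean(lap_maps[:, 0::2, :], axis=1)
    return pv_matrix(odd, even, label_a=f"{label}-odd", label_b=f"{label}-even")
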