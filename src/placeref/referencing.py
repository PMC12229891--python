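"""Reference-frame classification of place cells across a reward switch.

A cell reliable in both conditions is classified by the circular arc
distance between its pre- and post-switch place-field peaks: shifts of
0-15 cm are *space*-referenced (the field stayed with the belt cues),
75-90 cm are *goal*-referenced (the field followed the 90-cm reward
displacement), and 16-74 cm are *intermediate*. Both boundaries are
inclusive. A random-remapping null (post fields placed uniformly on the
belt) gives the chance expectation of ~15/90 = 0.167 for either
referenced category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import arc_distance, forward_distance

SPACE_MAX_CM = 15.0
GOAL_MIN_CM = 75.0
GOAL_MAX_CM = 90.0


@dataclass
class RemapNull:
    n_sim: int
    shift_edges: np.ndarray  # histogram bin edges (cm)
    shift_counts_mean: np.ndarray  # expected per-bin fraction of cells
    envelope_lo: np.ndarray  # 5th percentile of simulated per-bin fractions
    envelope_hi: np.ndarray  # 95th percentile
    expected_fractions: dict


def pf_shift(pf_pre_cm: float, pf_post_cm: float, belt_length_cm: float) -> float:
    """Circular arc distance between field locations, in [0, L/2]."""
    return float(arc_distance(pf_pre_cm, pf_post_cm, belt_length_cm))


def classify(shift_cm: float, belt_length_cm: float = 180.0) -> str:
    """Category from the shift distance; boundaries are inclusive."""
    half = belt_length_cm / 2.0
    if not 0.0 <= shift_cm <= half + 1e-9:
        raise ValueError(f"shift {shift_cm} cm impossible on a {belt_length_cm}-cm belt")
    if shift_cm <= SPACE_MAX_CM:
        return "space"
    if GOAL_MIN_CM <= shift_cm <= GOAL_MAX_CM:
        return "goal"
    return "intermediate"


def classification_table(
    table_pre: pd.DataFrame,
    table_post: pd.DataFrame,
    belt_length_cm: float = 180.0,
) -> pd.DataFrame:
    """Join pre/post place-cell tables and classify each cell.

    Cells that are not a place cell in both conditions are categorized
    'unreliable' and carry NaN shifts; they are excluded from fraction
    summaries.
    """
    pre = table_pre.set_index("cell")
    post = table_post.set_index("cell")
    rows = []
    for cell in pre.index:
        ok = bool(pre.loc[cell, "is_place_cell"]) and bool(post.loc[cell, "is_place_cell"])
        if ok:
            shift = pf_shift(pre.loc[cell, "peak_cm"], post.loc[cell, "peak_cm"], belt_length_cm)
            cat = classify(shift, belt_length_cm)
        else:
            shift, cat = np.nan, "unreliable"
        rows.append(
            {
                "cell": cell,
                "pf_pre_cm": pre.loc[cell, "peak_cm"],
                "pf_post_cm": post.loc[cell, "peak_cm"],
                "shift_cm": shift,
                "category": cat,
            }
        )
    return pd.DataFrame(rows)


def category_fractions(table: pd.DataFrame) -> dict:
    """Fractions of space/goal/intermediate among reliable-both cells."""
    ok = table[table["category"] != "unreliable"]
    n = len(ok)
    return {
        cat: float((ok["category"] == cat).sum()) / n if n else float("nan")
        for cat in ("space", "goal", "intermediate")
    }


def random_remapping_null(
    n_pc: int,
    n_sim: int = 1000,
    seed=None,
    belt_length_cm: float = 180.0,
    bin_cm: float = 3.6,
    pf_pre_cm=None,
    uniform_in: str = "position",
) -> RemapNull:
    """Random-remapping model: post fields placed uniformly on the belt.

    Simulates ``n_sim`` cohorts of ``n_pc`` cells, returning the shift
    histogram envelope and the expected category fractions. Under a
    continuous uniform placement the expected fraction of shifts within
    any 15-cm band of the 0-90 cm range is 15/90 ~ 0.167.
    ``uniform_in='shift'`` draws the shift itself uniformly instead.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    L = belt_length_cm
    if pf_pre_cm is None:
        pf_pre = rng.uniform(0, L, size=n_pc)
    else:
        pf_pre = np.asarray(pf_pre_cm, dtype=float)

    edges = np.arange(0.0, L / 2.0 + bin_cm, bin_cm)
    fracs = np.empty((n_sim, edges.size - 1))
    counts = {"space": 0, "goal": 0, "intermediate": 0}
    for s in range(n_sim):
        if uniform_in == "shift":
            shifts = rng.uniform(0, L / 2.0, size=n_pc)
        else:
            post = rng.uniform(0, L, size=n_pc)
            shifts = arc_distance(pf_pre, post, L)
        fracs[s] = np.histogram(shifts, bins=edges)[0] / n_pc
        counts["space"] += int(np.sum(shifts <= SPACE_MAX_CM))
        counts["goal"] += int(np.sum((shifts >= GOAL_MIN_CM) & (shifts <= GOAL_MAX_CM)))
    total = n_sim * n_pc
    expected = {k: v / total for k, v in counts.items()}
    expected["intermediate"] = 1.0 - expected["space"] - expected["goal"]
    return RemapNull(
        n_sim=n_sim,
        shift_edges=edges,
        shift_counts_mean=fracs.mean(axis=0),
        envelope_lo=np.percentile(fracs, 5, axis=0),
        envelope_hi=np.percentile(fracs, 95, axis=0),
        expected_fractions=expected,
    )


def category_by_location(
    table: pd.DataFrame,
    reward_cm: float,
    belt_length_cm: float = 180.0,
    n_bins: int = 10,
):
    """Spatial distribution of categories and the goal/(goal+space) ratio.

    Bins cells by the forward distance of their pre-switch field from
    the reward and fits a count-weighted least-squares line to the
    ratio r(d) = G(d) / (G(d) + S(d)).

    Returns (per-bin DataFrame, (slope, intercept) or None).
    """
    ok = table[table["category"].isin(["space", "goal"])]
    if len(ok) == 0:
        raise ValueError("no space or goal cells to bin")
    d = forward_distance(reward_cm, ok["pf_pre_cm"].to_numpy(), belt_length_cm)
    edges = np.linspace(0, belt_length_cm, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = ok[which == b]
        g = int((sel["category"] == "goal").sum())
        s = int((sel["category"] == "space").sum())
        rows.append(
            {
                "distance_cm": 0.5 * (edges[b] + edges[b + 1]),
                "n_goal": g,
                "n_space": s,
                "ratio": g / (g + s) if (g + s) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    valid = df.dropna(subset=["ratio"])
    fit = None
    if len(valid) >= 2:
        w = (valid["n_goal"] + valid["n_space"]).to_numpy(dtype=float)
        coeffs = np.polyfit(valid["distance_cm"], valid["ratio"], 1, w=np.sqrt(w))
        fit = (float(coeffs[0]), float(coeffs[1]))
    return df, fit


def crossday_bootstrap(
    day1_categories,
    day2_categories,
    n_boot: int = 10000,
    seed=None,
    sample_fraction: float = 0.8,
    observed_index: float | None = None,
):
    """Bootstrap the space/(space+goal) stability index across two days.

    The index is the number of day-1 space cells that stayed space-
    referenced divided by those that stayed space or became goal. Each
    resample draws ``sample_fraction`` of the matched cells with
    replacement; degenerate resamples (empty denominator) are redrawn.

    Returns a dict with the bootstrap distribution, its 5th percentile,
    and, if ``observed_index`` is given, the verdict on whether it falls
    below that percentile (with the exceedance-based confidence level).
    """
    d1 = np.asarray(day1_categories)
    d2 = np.asarray(day2_categories)
    if d1.shape != d2.shape:
        raise ValueError("day-1 and day-2 category arrays must be matched")
    space1 = np.flatnonzero(d1 == "space")
    if space1.size == 0:
        raise ValueError("no day-1 space cells")
    stayed = (d2[space1] == "space").astype(int)
    became_goal = (d2[space1] == "goal").astype(int)
    rng = np.random.default_rng(seed)
    m = max(int(round(sample_fraction * space1.size)), 1)
    boot = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            pick = rng.integers(0, space1.size, size=m)
            ns, ng = stayed[pick].sum(), became_goal[pick].sum()
            if ns + ng > 0:
                break
            redraws += 1
        boot[b] = ns / (ns + ng)
    p5 = float(np.percentile(boot, 5))
    out = {
        "bootstrap": boot,
        "p5": p5,
        "mean": float(boot.mean()),
        "n_redraws": redraws,
    }
    if observed_index is not None:
        out["observed"] = float(observed_index)
        out["below_p5"] = bool(observed_index < p5)
        frac_below = float(np.mean(observed_index < boot))
        out["confidence"] = frac_below
        out["verdict"] = "CI > 99%" if frac_below > 0.99 else f"CI = {100 * frac_below:.1f}%"
    return out


def stability_index(day1_categories, day2_categories) -> float:
    """Observed space/(space+goal) index for matched cells across days."""
    d1 = np.asarray(day1_categories)
    d2 = np.asarray(day2_categories)
    space1 = d1 == "space"
    ns = int(np.sum(space1 & (d2 == "space")))
    ng = int(np.sum(space1 & (d2 == "goal")))
    if ns + ng == 0:
        return float("nan")
    return ns / (ns + ng)
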