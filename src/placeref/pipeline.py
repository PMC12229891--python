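"""End-to-end pipeline: simulate or load a session, extract dF/F,
identify place cells per condition, classify reference frames, and run
the population-vector, BTSP, space-time and V_m analyses.

Every stage is also callable on its own; ``run`` wires them together
from a single configuration mapping and writes CSV/JSON outputs plus a
log of every parameter used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import btsp as btsp_mod
from . import placecells as pc
from . import population as pv_mod
from . import referencing as ref
from . import spacetime as st
from . import vm as vm_mod
from .config import SimConfig
from .dff import InvalidCellError, dff, significant_transients
from .session import BehaviorSession, save_session, load_session
from .simulate import simulate_behavior_full, simulate_calcium, simulate_vm

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "input": None,  # session HDF5; simulated when absent
    "out_dir": "results",
    "sim": {},  # SimConfig overrides
    "n_bins": 50,
    "n_shuffles": 200,
    "shuffle_seed": 1,
    "bootstrap_seed": 2,
    "n_remap_sim": 1000,
    "stages": ["behavior", "identify", "classify", "pv", "btsp", "spacetime"],
}


class ConfigError(ValueError):
    pass


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    overrides = overrides or {}
    for key, val in overrides.items():
        if key not in cfg:
            raise ConfigError(f"unknown configuration key: {key!r}")
        cfg[key] = val
    sim_fields = set(SimConfig.__dataclass_fields__)
    unknown = set(cfg["sim"]) - sim_fields
    if unknown:
        raise ConfigError(f"unknown sim keys: {sorted(unknown)}")
    return cfg


def load_yaml_config(path) -> dict:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return resolve_config(raw)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def compute_dff_matrix(raw_f: np.ndarray):
    """dF/F per cell; cells with an invalid baseline get NaN rows."""
    out = np.empty_like(raw_f, dtype=float)
    invalid = []
    for c in range(raw_f.shape[0]):
        try:
            out[c] = dff(raw_f[c])
        except InvalidCellError:
            out[c] = np.nan
            invalid.append(c)
    if invalid:
        log.warning("%d cells flagged invalid during dF/F", len(invalid))
    return out, invalid


@dataclass
class ConditionResult:
    condition: str
    bf: pc.BinnedFrames
    table: pd.DataFrame
    mean_maps: np.ndarray  # (n_cells, n_bins)
    lap_maps: np.ndarray  # (n_cells, n_laps, n_bins)


def analyze_condition(
    dff_mat: np.ndarray,
    thresholds: np.ndarray,
    session: BehaviorSession,
    condition: str,
    n_bins: int = 50,
    n_shuffles: int = 200,
    seed: int = 0,
) -> ConditionResult:
    laps = pc.condition_laps(session, condition)
    bf = pc.frame_binning(session, laps, n_bins)
    table = pc.identify_place_cells(dff_mat, thresholds, bf, n_shuffles=n_shuffles, seed=seed)
    n_cells = dff_mat.shape[0]
    mean_maps = np.empty((n_cells, n_bins))
    lap_maps = np.empty((n_cells, bf.n_laps, n_bins))
    for c in range(n_cells):
        dff_c = dff_mat[c, bf.frames]
        mean_maps[c] = pc.mean_map(dff_c, bf)
        lap_maps[c] = pc.lap_max_maps(dff_c, bf)
    return ConditionResult(condition, bf, table, mean_maps, lap_maps)


def identify_stage(
    dff_mat: np.ndarray,
    session: BehaviorSession,
    n_bins: int = 50,
    n_shuffles: int = 200,
    seed: int = 0,
):
    thresholds = np.array(
        [significant_transients(dff_mat[c])[1] for c in range(dff_mat.shape[0])]
    )
    pre = analyze_condition(dff_mat, thresholds, session, "pre", n_bins, n_shuffles, seed)
    post = analyze_condition(
        dff_mat, thresholds, session, "post", n_bins, n_shuffles, seed + 1
    )
    return pre, post, thresholds


def classify_stage(pre: ConditionResult, post: ConditionResult, session: BehaviorSession):
    table = ref.classification_table(pre.table, post.table, session.belt_length_cm)
    fractions = ref.category_fractions(table)
    return table, fractions


def pv_stage(pre: ConditionResult, post: ConditionResult):
    """PV matrices over place cells (cells reliable in either condition)."""
    pc_mask = (
        pre.table["is_place_cell"].to_numpy() | post.table["is_place_cell"].to_numpy()
    )
    if pc_mask.sum() < 2:
        raise ValueError("fewer than 2 place cells for PV analysis")
    m_prepost = pv_mod.pv_matrix(
        pre.mean_maps[pc_mask], post.mean_maps[pc_mask], "pre", "post"
    )
    m_oddeven = pv_mod.odd_even_matrix(pre.lap_maps[pc_mask], "pre")
    space_sim, goal_sim = m_prepost.similarity()
    return {
        "pre_post": m_prepost,
        "odd_even": m_oddeven,
        "space_similarity": space_sim,
        "goal_similarity": goal_sim,
        "odd_even_diag": m_oddeven.diag_mean,
        "odd_even_offdiag": m_oddeven.offdiag_mean(),
    }


def btsp_stage(
    pre: ConditionResult,
    post: ConditionResult,
    session: BehaviorSession,
    thresholds: np.ndarray,
):
    """Detect BTSP events per cell and condition and fill their metrics."""
    rows = []
    n_cells = pre.mean_maps.shape[0]
    for cond, res in (("pre", pre), ("post", post)):
        for c in range(n_cells):
            events = btsp_mod.detect_btsp(
                res.lap_maps[c], thresholds[c], res.bf.bin_cm, cell=c
            )
            pre_peak_cm = pre.table.loc[c, "peak_cm"] if cond == "post" else float("nan")
            for ev in events:
                vel_map = _lap_velocity_map(session, res.bf, ev.lap)
                btsp_mod.event_metrics(
                    ev, res.lap_maps[c], res.bf.bin_cm, pre_pf_cm=pre_peak_cm, velocity_map=vel_map
                )
                if cond == "post" and np.isfinite(pre_peak_cm):
                    space_bin = int(pre.table.loc[c, "peak_bin"])
                    goal_bin = (space_bin + res.bf.n_bins // 2) % res.bf.n_bins
                    _, before, after = btsp_mod.goal_selectivity(
                        res.lap_maps[c], space_bin, goal_bin, event_lap=ev.lap
                    )
                    ev.selectivity_before = before
                    ev.selectivity_after = after
                    ev.category_before = btsp_mod.selectivity_category(before)
                    ev.category_after = btsp_mod.selectivity_category(after)
                rows.append({"condition": cond, **ev.__dict__})
    return pd.DataFrame(rows)


def _lap_velocity_map(session: BehaviorSession, bf: pc.BinnedFrames, lap_rel: int):
    sel = bf.lap == lap_rel
    bins = bf.bins[sel]
    v = session.velocity[bf.frames[sel]]
    cnt = np.bincount(bins, minlength=bf.n_bins).astype(float)
    s = np.bincount(bins, weights=v, minlength=bf.n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, s / cnt, np.nan)


def spacetime_stage(
    dff_mat: np.ndarray,
    session: BehaviorSession,
    classification: pd.DataFrame,
    pre: ConditionResult,
):
    """Space/time tercile peaks for goal-referenced cells."""
    starts = beh.running_start_table(session, laps=range(session.reward_switch_lap))
    goal_cells = classification.loc[classification["category"] == "goal", "cell"]
    rows = []
    for c in goal_cells:
        maps = st.build_spacetime_maps(dff_mat[c], session, starts)
        start_pos = starts["start_position"].median()
        pf_dist = float(
            np.mod(pre.table.loc[c, "peak_cm"] - start_pos, session.belt_length_cm)
        )
        if pf_dist > st.MAX_PEAK_DISTANCE_CM:
            continue
        speeds = st.lap_speeds_to_peak(session, starts, pf_dist, maps.lap_ids)
        try:
            groups = st.speed_terciles(speeds)
        except ValueError:
            continue
        peaks = st.tercile_peaks(maps, groups)
        if not st.cell_passes_exclusions(peaks, pf_dist):
            continue
        for _, row in peaks.iterrows():
            rows.append({"cell": int(c), "pf_distance_cm": pf_dist, **row.to_dict()})
    return pd.DataFrame(rows)


def vm_stage(vm_raw, session: BehaviorSession, n_laps_pre: int, starts=None):
    """Bin V_m, locate the pre-switch field in both frames, decompose.

    The pre-switch field is located on the *pre-condition* AP-rate map
    (falling back to the subthreshold ramp for sparsely spiking
    recordings); the emergence of two distinct fields is checked on the
    post-condition space-frame map and excludes the cell.
    """
    if starts is None:
        starts = beh.running_start_table(session)
    rampset = vm_mod.bin_vm(vm_raw, session, n_laps_pre, starts=starts)
    pre_trials, post_trials = vm_mod.clean_trial_sets(rampset)
    pf_space, _ = _pf_with_fallback(rampset, pre_trials, "space")
    pf_goal, _ = _pf_with_fallback(rampset, pre_trials, "goal")
    post_starts = starts.loc[starts["lap"] >= n_laps_pre, "start_position"]
    post_start = float(post_starts.median()) if len(post_starts) else float("nan")
    decomp = vm_mod.decompose(rampset, pf_space, pf_goal, post_start_cm=post_start)
    _, two_post = _pf_with_fallback(rampset, post_trials, "space")
    if two_post and not decomp.excluded:
        decomp.excluded = True
        decomp.exclusion_reason = "two distinct place fields after the switch"
    return rampset, decomp


def _pf_with_fallback(rampset, trials, frame: str, min_spikes_per_trial=0.5):
    """AP-rate field location over the given trials, falling back to the
    subthreshold ramp when spikes are too sparse."""
    trials = np.asarray(trials, dtype=int)
    rates = rampset.rate_space if frame == "space" else rampset.rate_goal
    ramps = rampset.ramps_space if frame == "space" else rampset.ramps_goal
    if frame == "goal":
        trials = trials[rampset.goal_frame_valid[trials]]
    if trials.size == 0:
        return float("nan"), False
    with np.errstate(invalid="ignore"):
        rate_map = np.nanmean(rates[trials], axis=0)
        mean_ramp = np.nanmean(ramps[trials], axis=0)
    occupied = np.nansum(np.nan_to_num(rate_map)) * rampset.bin_cm
    if occupied >= min_spikes_per_trial:
        return vm_mod.pf_location(rate_map)
    return vm_mod.ramp_pf_location(mean_ramp)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run(config: dict | None = None) -> dict:
    """Run the configured stages; returns the summary dict (also written
    to ``out_dir/summary.json``)."""
    cfg = resolve_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "params.json").write_text(json.dumps(cfg, indent=2, sort_keys=True, default=str))

    sim_cfg = SimConfig(**cfg["sim"])
    if cfg["input"]:
        session, raw_f, vm_raw, truth = load_session(cfg["input"])
    else:
        session, schedule = simulate_behavior_full(sim_cfg)
        raw_f, truth = simulate_calcium(sim_cfg, session, schedule)
        vm_raw = None
    summary: dict = {"n_laps": session.n_laps, "belt_length_cm": session.belt_length_cm}
    stages = cfg["stages"]

    if "behavior" in stages:
        starts = beh.running_start_table(session)
        starts.to_csv(out / "behavior_report.csv", index=False)
        vel_map, lick_count, lick_prob = beh.bin_behavior(session, cfg["n_bins"])
        pd.DataFrame(
            {"velocity": vel_map, "lick_count": lick_count, "lick_prob": lick_prob}
        ).to_csv(out / "behavior_maps.csv", index=False)
        summary["n_running_starts"] = int(len(starts))

    pre = post = thresholds = None
    dff_mat = None
    if raw_f is not None and ("identify" in stages or "classify" in stages):
        dff_mat, invalid = compute_dff_matrix(raw_f)
        pre, post, thresholds = identify_stage(
            dff_mat, session, cfg["n_bins"], cfg["n_shuffles"], cfg["shuffle_seed"]
        )
        pre.table.to_csv(out / "place_cells_pre.csv", index=False)
        post.table.to_csv(out / "place_cells_post.csv", index=False)
        summary["n_place_cells_pre"] = int(pre.table["is_place_cell"].sum())
        summary["n_place_cells_post"] = int(post.table["is_place_cell"].sum())

    classification = None
    if pre is not None and "classify" in stages:
        classification, fractions = classify_stage(pre, post, session)
        classification.to_csv(out / "classification.csv", index=False)
        summary["category_fractions"] = fractions
        null = ref.random_remapping_null(
            n_pc=max((classification["category"] != "unreliable").sum(), 1),
            n_sim=cfg["n_remap_sim"],
            seed=cfg["bootstrap_seed"],
            belt_length_cm=session.belt_length_cm,
        )
        summary["random_remap_expected"] = null.expected_fractions

    if pre is not None and "pv" in stages:
        pvres = pv_stage(pre, post)
        np.savetxt(out / "pv_pre_post.csv", pvres["pre_post"].M, delimiter=",")
        summary["pv"] = {
            k: pvres[k]
            for k in ("space_similarity", "goal_similarity", "odd_even_diag", "odd_even_offdiag")
        }

    if pre is not None and "btsp" in stages:
        events = btsp_stage(pre, post, session, thresholds)
        events.to_csv(out / "btsp_events.csv", index=False)
        summary["n_btsp_events"] = int(len(events))

    if classification is not None and "spacetime" in stages:
        peaks = spacetime_stage(dff_mat, session, classification, pre)
        peaks.to_csv(out / "spacetime_peaks.csv", index=False)
        summary["n_spacetime_cells"] = int(peaks["cell"].nunique()) if len(peaks) else 0

    if cfg["input"] is None and "vm" in stages:
        vm_session, vm_schedule = simulate_behavior_full(sim_cfg)
        vm_raw, _ = simulate_vm(sim_cfg, vm_session, vm_schedule)
        session_for_vm = vm_session
    else:
        session_for_vm = session
    if vm_raw is not None and "vm" in stages:
        rampset, decomp = vm_stage(vm_raw, session_for_vm, sim_cfg.n_laps_pre)
        (out / "vm_decomposition.json").write_text(
            json.dumps({k: _jsonable(v) for k, v in decomp.__dict__.items()}, indent=2)
        )
        np.savetxt(out / "vm_ramps_space.csv", rampset.ramps_space, delimiter=",")
        np.savetxt(out / "vm_ramps_goal.csv", rampset.ramps_goal, delimiter=",")
        summary["vm_index"] = decomp.index

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def simulate_to_file(sim_cfg: SimConfig, path, include_vm: bool = False) -> None:
    """Simulate one session and write the HDF5 container + CSV manifest."""
    session, schedule = simulate_behavior_full(sim_cfg)
    raw_f, truth = simulate_calcium(sim_cfg, session, schedule)
    vm_raw = None
    if include_vm or sim_cfg.vm_weights:
        vm_raw, vm_truth = simulate_vm(sim_cfg, session, schedule)
        truth.vm_weights = vm_truth.vm_weights
        truth.vm_index = vm_truth.vm_index
        truth.plateau_times = vm_truth.plateau_times
    save_session(path, session, raw_f=raw_f, vm=vm_raw, truth=truth)
    truth.manifest().to_csv(str(path) + ".manifest.csv", index=False)
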