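"""Core data containers and the HDF5 session format.

A *session* is one behavioral recording (one animal, one day) together
with whatever neural data accompanies it: a calcium fluorescence matrix
(cells x frames) and/or a membrane-potential trace sampled at the
behavior clock. Synthetic sessions additionally carry their ground
truth. Everything is stored in a single HDF5 container with groups
``/behavior``, ``/calcium``, ``/vm`` and ``/ground_truth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd


@dataclass
class BehaviorSession:
    """Time-aligned behavior on a circular belt.

    ``position`` is in cm on ``[0, belt_length_cm)``; ``lap_index`` is
    the nondecreasing count of belt-origin crossings; ``rewards`` holds
    one (time, position) row per delivery. ``reward_switch_lap`` is the
    first lap on which the reward is delivered at the new location.
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    lick_times: np.ndarray
    reward_times: np.ndarray
    reward_positions: np.ndarray
    lap_index: np.ndarray
    belt_length_cm: float
    reward_switch_lap: int

    def __post_init__(self) -> None:
        if np.any(self.position < 0) or np.any(self.position >= self.belt_length_cm):
            raise ValueError("position outside [0, belt_length)")
        if np.any(np.diff(self.lap_index) < 0):
            raise ValueError("lap_index must be nondecreasing")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n_laps(self) -> int:
        return int(self.lap_index[-1]) + 1

    def lick_frames(self) -> np.ndarray:
        return np.searchsorted(self.time, self.lick_times)

    def reward_frames(self) -> np.ndarray:
        return np.searchsorted(self.time, self.reward_times)

    def lap_slice(self, lap: int) -> slice:
        idx = np.flatnonzero(self.lap_index == lap)
        if idx.size == 0:
            raise ValueError(f"lap {lap} not in session")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def lap_reward(self, lap: int):
        """(time, position) of the reward delivered on ``lap`` or None.

        A reward belongs to the lap that is current at (or begins
        exactly at) its delivery time, so rewards delivered on the lap
        boundary are attributed to the lap they start.
        """
        frames = np.minimum(
            np.searchsorted(self.time, self.reward_times), self.n_frames - 1
        )
        hit = np.flatnonzero(self.lap_index[frames] == lap)
        if hit.size == 0:
            return None
        i = int(hit[0])
        return float(self.reward_times[i]), float(self.reward_positions[i])


@dataclass
class GroundTruth:
    """What the generator actually simulated, for recovery tests."""

    category: list = field(default_factory=list)  # per cell
    pf_pre_cm: list = field(default_factory=list)
    pf_post_cm: list = field(default_factory=list)
    onset_lap: list = field(default_factory=list)
    shift_cm: list = field(default_factory=list)
    btsp_events: list = field(default_factory=list)  # (cell, lap, location_cm)
    vm_weights: list = field(default_factory=list)  # (w_goal, w_space)
    vm_index: list = field(default_factory=list)
    plateau_times: list = field(default_factory=list)  # (cell, trial, t_start_s, dur_ms)
    running_start_times: list = field(default_factory=list)  # per-lap scheduled start
    running_start_positions: list = field(default_factory=list)

    def manifest(self) -> pd.DataFrame:
        n = len(self.category)
        return pd.DataFrame(
            {
                "cell": np.arange(n),
                "category": self.category,
                "pf_pre_cm": self.pf_pre_cm,
                "pf_post_cm": self.pf_post_cm,
                "onset_lap": self.onset_lap,
                "shift_cm": self.shift_cm,
            }
        )


@dataclass
class VmRaw:
    """Raw intracellular recording aligned to behavior."""

    vm: np.ndarray  # mV, behavior clock (20 kHz)
    spike_times: np.ndarray  # s
    plateau_events: list  # (t_start_s, duration_ms)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def save_session(
    path,
    behavior: BehaviorSession,
    raw_f: Optional[np.ndarray] = None,
    vm: Optional[VmRaw] = None,
    truth: Optional[GroundTruth] = None,
) -> None:
    with h5py.File(path, "w") as h5:
        b = h5.create_group("behavior")
        for name in ("time", "position", "velocity", "lap_index"):
            b.create_dataset(name, data=getattr(behavior, name))
        b.create_dataset("lick_times", data=behavior.lick_times)
        b.create_dataset("reward_times", data=behavior.reward_times)
        b.create_dataset("reward_positions", data=behavior.reward_positions)
        b.attrs["belt_length_cm"] = behavior.belt_length_cm
        b.attrs["reward_switch_lap"] = behavior.reward_switch_lap
        if raw_f is not None:
            h5.create_group("calcium").create_dataset(
                "raw_f", data=np.asarray(raw_f, dtype=np.float32)
            )
        if vm is not None:
            g = h5.create_group("vm")
            g.create_dataset("vm", data=np.asarray(vm.vm, dtype=np.float32))
            g.create_dataset("spike_times", data=vm.spike_times)
            g.create_dataset(
                "plateau_events",
                data=np.asarray(vm.plateau_events, dtype=float).reshape(-1, 2),
            )
        if truth is not None:
            g = h5.create_group("ground_truth")
            g.attrs["category"] = ",".join(truth.category)
            for name in ("pf_pre_cm", "pf_post_cm", "onset_lap", "shift_cm", "vm_index"):
                g.create_dataset(name, data=np.asarray(getattr(truth, name), dtype=float))
            g.create_dataset(
                "btsp_events", data=np.asarray(truth.btsp_events, dtype=float).reshape(-1, 3)
            )
            g.create_dataset(
                "vm_weights", data=np.asarray(truth.vm_weights, dtype=float).reshape(-1, 2)
            )
            g.create_dataset(
                "plateau_times",
                data=np.asarray(truth.plateau_times, dtype=float).reshape(-1, 4),
            )
            g.create_dataset(
                "running_start_times", data=np.asarray(truth.running_start_times, dtype=float)
            )
            g.create_dataset(
                "running_start_positions",
                data=np.asarray(truth.running_start_positions, dtype=float),
            )


def load_session(path):
    """Load a session container; returns (behavior, raw_f, vm, truth)."""
    with h5py.File(path, "r") as h5:
        b = h5["behavior"]
        behavior = BehaviorSession(
            time=b["time"][:],
            position=b["position"][:],
            velocity=b["velocity"][:],
            lick_times=b["lick_times"][:],
            reward_times=b["reward_times"][:],
            reward_positions=b["reward_positions"][:],
            lap_index=b["lap_index"][:].astype(int),
            belt_length_cm=float(b.attrs["belt_length_cm"]),
            reward_switch_lap=int(b.attrs["reward_switch_lap"]),
        )
        raw_f = h5["calcium/raw_f"][:].astype(float) if "calcium" in h5 else None
        vm = None
        if "vm" in h5:
            vm = VmRaw(
                vm=h5["vm/vm"][:].astype(float),
                spike_times=h5["vm/spike_times"][:],
                plateau_events=[tuple(row) for row in h5["vm/plateau_events"][:]],
            )
        truth = None
        if "ground_truth" in h5:
            g = h5["ground_truth"]
            cats = g.attrs["category"]
            truth = GroundTruth(
                category=cats.split(",") if cats else [],
                pf_pre_cm=list(g["pf_pre_cm"][:]),
                pf_post_cm=list(g["pf_post_cm"][:]),
                onset_lap=list(g["onset_lap"][:]),
                shift_cm=list(g["shift_cm"][:]),
                btsp_events=[tuple(r) for r in g["btsp_events"][:]],
                vm_weights=[tuple(r) for r in g["vm_weights"][:]],
                vm_index=list(g["vm_index"][:]),
                plateau_times=[tuple(r) for r in g["plateau_times"][:]],
                running_start_times=list(g["running_start_times"][:]),
                running_start_positions=list(g["running_start_positions"][:]),
            )
    return behavior, raw_f, vm, truth
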