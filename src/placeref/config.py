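"""Simulation and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

PC_CATEGORIES = ("space", "goal", "intermediate", "nonplace")


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of one simulated reward-switch session.

    Defaults reproduce the imaging task: a 180-cm circular belt divided
    into 50 spatial bins, reward at 50 cm for the first 100 laps and at
    140 cm for the next 100, calcium sampled at 30 Hz, and a ~6.8-s
    post-reward stationary period. ``for_vm()`` switches to the
    intracellular configuration (184-cm belt, 1-cm bins, reward moved
    from the lap origin to 92 cm, 20-kHz sampling).
    """

    belt_length_cm: float = 180.0
    n_bins: int = 50
    reward_pre_cm: float = 50.0
    reward_post_cm: float = 140.0
    n_laps_pre: int = 100
    n_laps_post: int = 100
    frame_rate_hz: float = 30.0
    n_cells: int = 100
    fractions: dict = field(
        default_factory=lambda: {
            "space": 0.25,
            "goal": 0.31,
            "intermediate": 0.44,
            "nonplace": 0.0,
        }
    )
    reliability: float = 0.8
    transient_amp: float = 1.0
    noise_sd: float = 0.1
    mean_stop_duration_s: float = 6.8
    stop_duration_sd_s: float = 0.6
    cruise_speed_cm_s: float = 15.0
    speed_jitter: float = 0.10  # lap-to-lap s.d. as a fraction of cruise speed
    field_width_cm: float = 20.0
    baseline_f: float = 100.0
    drift_amp: float = 5.0  # slow multiplicative baseline drift of raw F (a.u.)
    btsp_injection: list = field(default_factory=list)  # (cell, lap, location_cm)
    extra_stops: list = field(default_factory=list)  # (lap, position_cm, duration_s)
    # --- membrane-potential mode ---
    vm_weights: list = field(default_factory=list)  # per-cell (w_goal, w_space)
    plateau_schedule: list = field(default_factory=list)  # (cell, trial, time_s, duration_ms)
    vm_resting_mv: float = -65.0
    vm_spike_threshold_mv: float = -50.0
    vm_ramp_peak_mv: float = 9.0
    vm_noise_sd_mv: float = 0.0
    vm_trial_offset_sd_mv: float = 0.0  # per-trial baseline drift exercised by correction
    vm_spike_rate_hz: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        L = self.belt_length_cm
        if L <= 0:
            raise InvalidConfigError("belt_length_cm must be positive")
        for name in ("reward_pre_cm", "reward_post_cm"):
            r = getattr(self, name)
            if not (0 <= r < L) and r != L:  # L is accepted as an alias of 0
                raise InvalidConfigError(f"{name}={r} outside belt [0, {L})")
        if self.n_laps_pre < 1 or self.n_laps_post < 0:
            raise InvalidConfigError("lap counts must satisfy n_laps_pre>=1, n_laps_post>=0")
        if not 0.0 <= self.reliability <= 1.0:
            raise InvalidConfigError("reliability must lie in [0, 1]")
        total = sum(self.fractions.get(k, 0.0) for k in PC_CATEGORIES)
        unknown = set(self.fractions) - set(PC_CATEGORIES)
        if unknown:
            raise InvalidConfigError(f"unknown cell categories: {sorted(unknown)}")
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"cell-category fractions sum to {total}, expected 1")
        for w in self.vm_weights:
            if min(w) < 0:
                raise InvalidConfigError("vm weights must be nonnegative")
        n_total = self.n_laps_pre + self.n_laps_post
        for cell, lap, loc in self.btsp_injection:
            if not 0 <= lap < n_total:
                raise InvalidConfigError(f"btsp injection lap {lap} outside session")
            if not 0 <= loc < L:
                raise InvalidConfigError(f"btsp injection location {loc} outside belt")

    @classmethod
    def for_vm(cls, **overrides) -> "SimConfig":
        """Intracellular-recording configuration (184-cm belt, 20 kHz)."""
        base = dict(
            belt_length_cm=184.0,
            n_bins=184,
            reward_pre_cm=184.0,  # lap origin
            reward_post_cm=92.0,
            n_laps_pre=16,
            n_laps_post=20,
            frame_rate_hz=20000.0,
            n_cells=1,
            fractions={"space": 0.0, "goal": 1.0, "intermediate": 0.0, "nonplace": 0.0},
            vm_weights=[(1.0, 1.0)],
            vm_noise_sd_mv=1.0,
            vm_trial_offset_sd_mv=1.0,
        )
        base.update(overrides)
        return cls(**base)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)
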