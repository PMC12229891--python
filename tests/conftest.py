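import numpy as np
import pytest

from placeref.config import SimConfig
from placeref.simulate import simulate_behavior_full, simulate_calcium


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_laps_pre=30, n_laps_post=30, n_cells=12, seed=2)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    session, schedule = simulate_behavior_full(small_cfg)
    return session, schedule


@pytest.fixture(scope="session")
def small_calcium(small_cfg, small_session):
    session, schedule = small_session
    raw_f, truth = simulate_calcium(small_cfg, session, schedule)
    return raw_f, truth


def make_flat_session(
    n_laps=3,
    belt=180.0,
    speed=20.0,
    fr=30.0,
    reward_cm=50.0,
    lick_times=(),
):
    """Minimal constructed session: constant-speed laps, no stops."""
    from placeref.session import BehaviorSession

    duration = n_laps * belt / speed
    t = np.arange(0.0, duration, 1.0 / fr)
    x = speed * t
    pos = np.mod(x, belt)
    lap = np.floor(x / belt).astype(int)
    reward_times = np.array([(k * belt + reward_cm) / speed for k in range(n_laps)])
    return BehaviorSession(
        time=t,
        position=pos,
        velocity=np.full(t.size, speed),
        lick_times=np.asarray(lick_times, dtype=float),
        reward_times=reward_times,
        reward_positions=np.full(n_laps, reward_cm),
        lap_index=lap,
        belt_length_cm=belt,
        reward_switch_lap=n_laps,
    )
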