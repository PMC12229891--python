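"""BTSP event detection, field/COM measurement, selectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placeref import btsp

BIN_CM = 3.6


def make_lap_maps(n_laps=30, n_bins=50):
    return np.zeros((n_laps, n_bins))


def add_field(maps, laps, center, amp, width=2):
    """Triangular field peaking at ``center`` (unique argmax)."""
    for l in laps:
        for off in range(-width, width + 1):
            b = (center + off) % maps.shape[1]
            val = amp * (1.0 - abs(off) / (width + 1.0))
            maps[l, b] = max(maps[l, b], val)
    return maps


def event_maps(event_lap=10, center=30, n_laps=30, amp_event=3.0, amp_after=1.0):
    """Lap maps with a silent start, one large transient, then a
    persistent field — the canonical BTSP signature."""
    maps = make_lap_maps(n_laps)
    add_field(maps, [event_lap], center, amp_event)
    add_field(maps, range(event_lap + 1, n_laps), center, amp_after)
    return maps


# --- detection criteria -----------------------------------------------------


def test_canonical_event_detected():
    maps = event_maps()
    events = btsp.detect_btsp(maps, sig_threshold=0.3, bin_cm=BIN_CM)
    assert len(events) == 1
    assert events[0].lap == 10
    assert events[0].peak_bin == 30
    assert events[0].peak_dff == pytest.approx(3.0)


def test_stable_field_without_jump_not_detected():
    maps = add_field(make_lap_maps(), range(30), 30, 1.0)
    maps[12, 30] = 2.5  # strong lap, but no amplitude doubling afterwards
    assert btsp.detect_btsp(maps, 0.3, BIN_CM) == []


def test_peak_below_two_rejected():
    maps = event_maps(amp_event=1.5, amp_after=0.6)
    assert btsp.detect_btsp(maps, 0.3, BIN_CM) == []


def test_events_in_last_five_laps_excluded():
    maps = event_maps(event_lap=27)
    assert btsp.detect_btsp(maps, 0.3, BIN_CM) == []


def test_four_of_five_subsequent_laps_required():
    maps = make_lap_maps()
    add_field(maps, [10], 30, 3.0)
    add_field(maps, [11, 13], 30, 1.0)  # only 2 of the next 5 laps
    assert btsp.detect_btsp(maps, 0.3, BIN_CM) == []
    add_field(maps, [12, 14], 30, 1.0)  # now 4 of 5
    assert len(btsp.detect_btsp(maps, 0.3, BIN_CM)) == 1


def test_amplitude_doubling_required():
    maps = add_field(make_lap_maps(), range(30), 30, 1.0)
    maps[10, 30] = 3.0
    add_field(maps, range(11, 30), 30, 1.8)  # < 2x the preceding 1.0
    assert btsp.detect_btsp(maps, 0.3, BIN_CM) == []
    maps2 = add_field(make_lap_maps(), range(5, 10), 30, 0.5)
    maps2[10, 30] = 3.0
    add_field(maps2, range(11, 30), 30, 1.2)  # > 2x
    assert len(btsp.detect_btsp(maps2, 0.3, BIN_CM)) == 1


def test_removing_peak_criterion_only_adds_events():
    rng = np.random.default_rng(6)
    for _ in range(20):
        maps = rng.random((20, 50)) * rng.choice([0.5, 3.0], size=(20, 1))
        with_cut = btsp.detect_btsp(maps, 0.3, BIN_CM)
        without = btsp.detect_btsp(maps, 0.3, BIN_CM, peak_min=-np.inf)
        keys = {(e.lap, e.peak_bin) for e in with_cut}
        keys_wo = {(e.lap, e.peak_bin) for e in without}
        assert keys <= keys_wo


def test_too_few_laps_no_events():
    maps = event_maps(event_lap=4, n_laps=10)
    assert btsp.detect_btsp(maps, 0.3, BIN_CM) == []


# --- field, width, COM -------------------------------------------------------


def test_field_threshold_and_width():
    x = np.zeros(50)
    x[20:25] = [0.5, 1.0, 2.0, 1.0, 0.5]
    f = btsp.field_and_width(x, BIN_CM)
    # 35% of peak = 0.7: bins 21-23 qualify
    assert set(f.bins) == {21, 22, 23}
    assert f.width_cm == pytest.approx(3 * BIN_CM)
    assert f.peak_bin == 22


def test_field_wraps_around_origin():
    x = np.zeros(50)
    x[[48, 49, 0, 1]] = [1.0, 2.0, 1.8, 0.9]
    f = btsp.field_and_width(x, BIN_CM)
    assert set(f.bins) == {48, 49, 0, 1}


def test_com_printed_formula():
    # COM = sum(x*d)/sum(x) with explicit positions d = 3.6..18
    x = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
    d = np.array([3.6, 7.2, 10.8, 14.4, 18.0])
    assert np.sum(x * d) / np.sum(x) == pytest.approx(10.8)


def test_com_symmetric_field_at_center():
    x = np.zeros(50)
    x[18:23] = [0.5, 1.5, 3.0, 1.5, 0.5]  # symmetric around bin 20
    f = btsp.field_and_width(x, BIN_CM)
    assert btsp.com(x, f, BIN_CM) == pytest.approx((20 + 0.5) * BIN_CM)


@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_com_within_field_span(seed):
    rng = np.random.default_rng(seed)
    x = np.clip(rng.standard_normal(50), 0, None)
    x[rng.integers(0, 50)] += 3.0
    f = btsp.field_and_width(x, BIN_CM)
    c = btsp.com(x, f, BIN_CM)
    span = [(b + 0.5) * BIN_CM for b in f.bins]
    from placeref.circular import arc_distance

    assert min(arc_distance(c, s, 180.0) for s in span) <= BIN_CM


def test_mean_activity_field_extra_criteria():
    # in/out ratio 1.5 -> disqualified
    x = np.full(50, 1.0)
    x[20:23] = 1.6
    assert btsp.mean_activity_field(x, BIN_CM) is None
    # in-field max 0.15 < 0.2 -> disqualified
    y = np.zeros(50)
    y[20:23] = 0.15
    assert btsp.mean_activity_field(y, BIN_CM) is None
    # a clean field passes
    z = np.zeros(50)
    z[20:25] = [0.4, 1.0, 2.2, 1.0, 0.4]
    assert btsp.mean_activity_field(z, BIN_CM) is not None


# --- event metrics and selectivity -------------------------------------------


def test_event_metrics_distance_and_com_shift():
    maps = event_maps(event_lap=10, center=30)
    ev = btsp.detect_btsp(maps, 0.3, BIN_CM)[0]
    vel = np.full(50, 15.0)
    btsp.event_metrics(ev, maps, BIN_CM, pre_pf_cm=(5 + 0.5) * BIN_CM, velocity_map=vel)
    # event at bin 30 vs pre field at bin 5: 25 bins = 90 cm
    assert ev.distance_from_pre_pf == pytest.approx(90.0)
    assert ev.induction_velocity == pytest.approx(15.0)
    assert ev.pf_width_after > 0
    assert np.isfinite(ev.com_post5)


def test_selectivity_extremes_and_crossing():
    maps = make_lap_maps(n_laps=20)
    add_field(maps, range(0, 10), 10, 1.0)  # space field first
    add_field(maps, range(10, 20), 35, 1.0)  # jumps 90 cm at lap 10
    sel, before, after = btsp.goal_selectivity(
        maps, space_center_bin=10, goal_center_bin=35, event_lap=10
    )
    assert before == pytest.approx(-1.0)
    assert after == pytest.approx(1.0)
    assert btsp.selectivity_category(before) == "space"
    assert btsp.selectivity_category(after) == "goal"
    assert btsp.selectivity_category(0.1) == "non-selective"


def test_selectivity_equal_fields_zero():
    maps = make_lap_maps()
    add_field(maps, range(30), 10, 1.0)
    add_field(maps, range(30), 35, 1.0)
    sel, _, _ = btsp.goal_selectivity(maps, 10, 35, event_lap=5)
    np.testing.assert_allclose(sel, 0.0, atol=1e-12)


def test_selectivity_missing_when_silent():
    maps = make_lap_maps()
    sel, before, after = btsp.goal_selectivity(maps, 10, 35, event_lap=5)
    assert np.isnan(sel).all()
    assert btsp.selectivity_category(after) == "undefined"


def test_generator_injected_event_recovered(small_session):
    """End-to-end: an injected abrupt field is detected at the scheduled
    lap and location."""
    from placeref.config import SimConfig
    from placeref.simulate import simulate_calcium
    from placeref.dff import dff, significant_transients
    from placeref import placecells as pc

    session, schedule = small_session
    cfg = SimConfig(
        n_laps_pre=30, n_laps_post=30, n_cells=2, seed=2,
        fractions={"space": 1.0}, btsp_injection=[(0, 45, 100.0)],
    )
    raw, truth = simulate_calcium(cfg, session, schedule)
    d = dff(raw[0])
    thr = significant_transients(d)[1]
    bf = pc.frame_binning(session, pc.condition_laps(session, "post"))
    lm = pc.lap_max_maps(d[bf.frames], bf)
    events = btsp.detect_btsp(lm, thr, bf.bin_cm)
    assert any(
        abs(e.lap - 15) <= 1 and abs(e.location_cm - 100.0) <= 2 * BIN_CM for e in events
    )
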