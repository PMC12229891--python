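"""V_m processing: spikes, baseline, plateaus, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placeref import vm

FS = 20_000.0


# --- plateau detection -------------------------------------------------------


def square_pulse_trace(pulses, n=200_000, base=-65.0, level=-30.0):
    """pulses: list of (start_index, n_samples)."""
    x = np.full(n, base)
    for a, w in pulses:
        x[a : a + w] = level
    return x


def brute_force_plateaus(x, fs=FS):
    """Independent oracle: enumerate supra-threshold samples, merge gaps
    <= 10 ms sample-by-sample, keep runs > 100 ms."""
    above = x > -35.0
    events = []
    i = 0
    n = x.size
    gap = int(0.010 * fs)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        end = i
        while j < n:
            if above[j]:
                end = j
                j += 1
            elif np.any(above[j : j + gap + 1]):
                j += 1
            else:
                break
        if (end - i + 1) > 0.100 * fs:
            events.append((i, (end - i + 1) / fs * 1000.0))
        i = j + 1
    return events


def test_150ms_square_pulse_is_one_event():
    x = square_pulse_trace([(50_000, int(0.150 * FS))])
    events = vm.detect_plateaus(x, FS)
    assert len(events) == 1
    assert events[0][1] == pytest.approx(150.0, abs=0.1)


def test_90ms_pulse_is_no_event():
    x = square_pulse_trace([(50_000, int(0.090 * FS))])
    assert vm.detect_plateaus(x, FS) == []


def test_two_80ms_pulses_with_5ms_gap_merge():
    w = int(0.080 * FS)
    gap = int(0.005 * FS)
    x = square_pulse_trace([(50_000, w), (50_000 + w + gap, w)])
    events = vm.detect_plateaus(x, FS)
    assert len(events) == 1
    assert events[0][1] == pytest.approx(165.0, abs=0.2)


def test_gap_over_10ms_not_merged():
    w = int(0.080 * FS)
    gap = int(0.015 * FS)
    x = square_pulse_trace([(50_000, w), (50_000 + w + gap, w)])
    assert vm.detect_plateaus(x, FS) == []  # each 80 ms alone is too short


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_plateau_detector_matches_brute_force(seed):
    """Random square-pulse layouts: detector output is event-for-event
    identical to exhaustive segment enumeration."""
    rng = np.random.default_rng(seed)
    pulses = []
    pos = 1000
    for _ in range(rng.integers(1, 6)):
        w = int(rng.uniform(0.03, 0.2) * FS)
        pulses.append((pos, w))
        pos += w + int(rng.uniform(0.003, 0.05) * FS)
    x = square_pulse_trace(pulses, n=pos + 10_000)
    got = vm.detect_plateaus(x, FS)
    expect = brute_force_plateaus(x)
    assert len(got) == len(expect)
    for (a, d), (a2, d2) in zip(got, expect):
        assert a == a2
        assert d == pytest.approx(d2, abs=0.2)


def test_plateau_rate_definition():
    assert vm.plateau_rate(3, 200) == pytest.approx(1.5)
    assert np.isnan(vm.plateau_rate(1, 0))


# --- spikes and baseline correction ------------------------------------------


def spike_trace(onsets, base=-60.0, theta=-50.0, n=100_000):
    """Stylized spikes: slow approach to threshold, fast upstroke."""
    x = np.full(n, base)
    for i in onsets:
        x[i : i + 10] = np.linspace(base, theta, 10, endpoint=False)
        x[i + 10 : i + 14] = np.linspace(theta, 20.0, 4, endpoint=False)
        x[i + 14 : i + 30] = np.linspace(20.0, base, 16, endpoint=False)
    return x


def test_spike_detection_and_threshold_estimate():
    onsets = [10_000, 30_000, 70_000]
    x = spike_trace(onsets)
    found, thr = vm.detect_spikes(x, FS)
    assert len(found) == 3
    np.testing.assert_allclose(thr, -50.0, atol=0.6)


def test_plateau_edges_not_mistaken_for_spikes():
    x = square_pulse_trace([(50_000, int(0.150 * FS))])
    found, _ = vm.detect_spikes(x, FS)
    assert len(found) == 0


def test_spike_excision_leaves_no_residual():
    onsets = [40_000]
    x = spike_trace(onsets)
    clean = vm.strip_spikes(x, FS, np.array([40_010]))
    twin = np.full_like(x, -60.0)
    assert np.abs(clean - twin).max() < 1.0


def test_spikeless_trial_keeps_trace_unchanged():
    offsets, none_found = vm.trial_baseline_offsets(np.array([]), np.array([]), 3)
    assert none_found
    np.testing.assert_array_equal(offsets, 0.0)


def test_known_drift_removed_via_threshold():
    # trial 0 threshold -50 (offset 0), trial 1 threshold -47 (3 mV drift)
    thresholds = np.array([-50.0, -50.0, -47.0, -47.0])
    spike_laps = np.array([0, 0, 1, 1])
    offsets, _ = vm.trial_baseline_offsets(thresholds, spike_laps, 2)
    assert offsets[0] == pytest.approx(0.0, abs=1e-9)
    assert offsets[1] == pytest.approx(3.0, abs=1e-9)


def test_missing_trial_inherits_median_offset():
    thresholds = np.array([-48.0, -48.0])
    spike_laps = np.array([0, 0])
    offsets, _ = vm.trial_baseline_offsets(thresholds, spike_laps, 3)
    assert offsets[1] == pytest.approx(2.0)
    assert offsets[2] == pytest.approx(2.0)


# --- field location -----------------------------------------------------------


def test_pf_location_gaussian_bump():
    i = np.arange(184)
    rate = np.exp(-0.5 * ((i - 120) / 5.0) ** 2)
    loc, two = vm.pf_location(rate, bin_cm=1.0)
    assert loc == pytest.approx(120.5, abs=0.5)
    assert not two


def test_pf_location_bimodal_flagged():
    i = np.arange(184)
    rate = np.exp(-0.5 * ((i - 50) / 5.0) ** 2) + 0.9 * np.exp(
        -0.5 * ((i - 140) / 5.0) ** 2
    )
    _, two = vm.pf_location(rate, bin_cm=1.0)
    assert two


def test_pf_location_empty_map_missing():
    loc, two = vm.pf_location(np.zeros(184), bin_cm=1.0)
    assert np.isnan(loc)


# --- decomposition on constructed ramps ---------------------------------------


def bump(center, n=184, amp=1.0, sigma=10.0):
    i = np.arange(n)
    d = np.minimum(np.abs(i - center), n - np.abs(i - center))
    return amp * np.exp(-0.5 * (d / sigma) ** 2)


def make_rampset(w_goal, w_space, p0=60, n_pre=8, n_post=8, rest=-50.0):
    """Synthetic binned ramps with the exact two-component geometry:
    space bump fixed at p0, goal bump at p0 pre and p0+92 post; the goal
    frame sees the converse."""
    n = 184
    start_pre, start_post = 3.0, 95.0
    d0 = (p0 - start_pre) % n
    pre_space = rest + (w_space + w_goal) * bump(p0)
    post_space = rest + w_space * bump(p0) + w_goal * bump((p0 + 92) % n)
    pre_goal = rest + (w_space + w_goal) * bump(d0)
    post_goal = rest + w_goal * bump(d0) + w_space * bump((d0 + 92) % n)
    ramps_space = np.vstack([np.tile(pre_space, (n_pre, 1)), np.tile(post_space, (n_post, 1))])
    ramps_goal = np.vstack([np.tile(pre_goal, (n_pre, 1)), np.tile(post_goal, (n_post, 1))])
    rates = np.zeros_like(ramps_space)
    return vm.VmRampSet(
        ramps_space=ramps_space,
        ramps_goal=ramps_goal,
        rate_space=rates,
        rate_goal=rates.copy(),
        trial_has_plateau=np.zeros(n_pre + n_post, dtype=bool),
        goal_frame_valid=np.ones(n_pre + n_post, dtype=bool),
        n_laps_pre=n_pre,
        bin_cm=1.0,
        belt_length_cm=184.0,
    ), p0, d0, start_post


@pytest.mark.parametrize(
    "w_goal,w_space,expect",
    [(0.0, 1.0, -1.0), (1.0, 3.0, -0.5), (1.0, 1.0, 0.0), (3.0, 1.0, 0.5), (1.0, 0.0, 1.0)],
)
def test_decompose_exact_on_constructed_ramps(w_goal, w_space, expect):
    rs, p0, d0, start_post = make_rampset(w_goal, w_space)
    dec = vm.decompose(rs, p0, d0, post_start_cm=start_post)
    assert dec.index == pytest.approx(expect, abs=0.02)
    assert dec.reconstruction_deviation < 0.05
    assert dec.symmetry == pytest.approx(1.0, abs=0.05)


def test_decompose_linearity():
    """Scaling the ramps scales both areas and leaves the index fixed."""
    rs, p0, d0, sp = make_rampset(2.0, 1.0)
    dec1 = vm.decompose(rs, p0, d0, post_start_cm=sp)
    rs2, *_ = make_rampset(2.0, 1.0)
    rest = -50.0
    rs2.ramps_space = rest + 3.0 * (rs2.ramps_space - rest)
    rs2.ramps_goal = rest + 3.0 * (rs2.ramps_goal - rest)
    dec2 = vm.decompose(rs2, p0, d0, post_start_cm=sp)
    assert dec2.area_goal == pytest.approx(3.0 * dec1.area_goal, rel=1e-6)
    assert dec2.area_space == pytest.approx(3.0 * dec1.area_space, rel=1e-6)
    assert dec2.index == pytest.approx(dec1.index, abs=1e-9)


def test_symmetry_half_amplitude_flank():
    """A single-component cell whose dV_m has a half-amplitude left
    flank scores symmetry 0.5."""
    n = 184
    i = np.arange(n)
    center = 100
    tri = np.clip(1.0 - np.abs(i - center) / 30.0, 0, None)
    tri[i < center] *= 0.5  # left flank halved
    # build areas directly through the window helper
    total, left, right = vm._window_area(tri, center, 1.0)
    assert left == pytest.approx(0.5 * right, rel=0.05)
    sym = (min(left, right) + 0.0) / (max(left, right) + 0.0)
    assert sym == pytest.approx(0.5, rel=0.05)


def test_decompose_exclusions():
    rs, p0, d0, sp = make_rampset(1.0, 1.0)
    rs.trial_has_plateau[rs.n_laps_pre] = True  # immediate post plateau
    dec = vm.decompose(rs, p0, d0, post_start_cm=sp)
    assert dec.excluded and "plateau" in dec.exclusion_reason
    rs2, p0, d0, sp = make_rampset(1.0, 1.0, n_post=3)
    # transition-lap exclusion leaves only 2 clean post trials
    dec2 = vm.decompose(rs2, p0, d0, post_start_cm=sp)
    assert dec2.excluded and "too few" in dec2.exclusion_reason


def test_index_missing_when_areas_nonpositive():
    rs, p0, d0, sp = make_rampset(0.0, 1.0)
    rs.ramps_goal = np.full_like(rs.ramps_goal, -50.0)  # no space signal either
    rs.ramps_space = np.full_like(rs.ramps_space, -50.0)
    dec = vm.decompose(rs, p0, d0, post_start_cm=sp)
    assert np.isnan(dec.index)
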