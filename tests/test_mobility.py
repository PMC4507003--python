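"""MSD, D_Inst, mobility populations, and binding-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brownian_track, make_track
from searchkin.dwell import ExponentialDwell
from searchkin.mobility import (
    MSDCurve,
    classify_populations,
    compute_msd,
    correct_bleaching,
    detect_binding_events,
    dinst_table,
    estimate_bleach_rate,
    fit_dinst,
    fit_event_rate,
    running_dinst,
)
from searchkin.protocols import continuous
from searchkin.simulate import KineticsConfig, simulate_trajectories


def brute_force_msd(x, y, max_lag):
    """Exhaustive displacement-pair enumeration (independent oracle)."""
    out = []
    for k in range(1, max_lag + 1):
        pairs = [
            (x[i + k] - x[i]) ** 2 + (y[i + k] - y[i]) ** 2 for i in range(len(x) - k)
        ]
        out.append(sum(pairs) / len(pairs))
    return np.array(out)


def test_msd_stationary_track_is_zero():
    traj = make_track(np.ones(10), np.ones(10))
    assert np.all(compute_msd(traj, 4).msd_um2 == 0)


def test_msd_ballistic_closed_form():
    dt, v = 0.01, 2.0
    t = np.arange(20) * dt
    traj = make_track(v * t, np.zeros_like(t), dt=dt)
    msd = compute_msd(traj, 5)
    np.testing.assert_allclose(msd.msd_um2, (v * msd.lags * dt) ** 2, rtol=1e-12)


def test_msd_toy_track_matches_exhaustive_enumeration():
    x = np.array([0, 1, 1, 2, 2], dtype=float)
    y = np.array([0, 0, 1, 1, 2], dtype=float)
    traj = make_track(x, y)
    msd = compute_msd(traj, 3)
    np.testing.assert_allclose(msd.msd_um2, brute_force_msd(x, y, 3))
    np.testing.assert_allclose(msd.msd_um2, [1.0, 2.0, 5.0])
    assert list(msd.n_pairs) == [4, 3, 2]
    with pytest.raises(ValueError):
        compute_msd(traj, 5)  # too short


@settings(deadline=None, max_examples=25, derandomize=True)
@given(n=st.integers(8, 50), seed=st.integers(0, 10_000))
def test_msd_equals_oracle_on_random_tracks(n, seed):
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal((2, n))
    traj = make_track(x, y)
    msd = compute_msd(traj, min(5, n - 1))
    np.testing.assert_allclose(msd.msd_um2, brute_force_msd(x, y, min(5, n - 1)), rtol=1e-9)


def test_fit_dinst_exact_on_affine_msd():
    lags = np.arange(1, 6)
    dt = 1 / 197.0
    for D, b in ((1.0, 0.0), (0.3, 0.05), (8.0, -0.01)):
        curve = MSDCurve(lags, 4 * D * lags * dt + b, np.ones(5, int))
        assert fit_dinst(curve, dt) == pytest.approx(D, rel=1e-12)
    flat = MSDCurve(lags, np.full(5, 0.2), np.ones(5, int))
    assert fit_dinst(flat, dt) == pytest.approx(0.0, abs=1e-15)


def test_fit_dinst_four_point_closed_form():
    # MSD (0.05, 0.07, 0.09, 0.11) um^2 at lags 2-5, dt = 1/197 s:
    # slope 0.02 um^2 per lag -> D = 0.02 * 197 / 4 = 0.985 um^2/s
    curve = MSDCurve(np.arange(2, 6), np.array([0.05, 0.07, 0.09, 0.11]), np.ones(4, int))
    assert fit_dinst(curve, 1 / 197.0) == pytest.approx(0.985, rel=1e-12)


def test_dinst_table_skips_short_tracks(no_bleach_continuous):
    long_t = brownian_track(30, 2.0, seed=1, protocol=no_bleach_continuous)
    short_t = brownian_track(5, 2.0, seed=2, protocol=no_bleach_continuous)
    tab = dinst_table([long_t, short_t])
    assert len(tab) == 1


def test_classify_populations_recovers_three_component_mixture():
    rng = np.random.default_rng(99)
    n = 2000
    comp = rng.choice(3, size=n, p=[0.33, 0.43, 0.24])
    means = np.array([0.9, 0.0, -1.0])
    logd = rng.normal(means[comp], 0.3)
    res = classify_populations(10.0**logd, k=3, seed=0)
    np.testing.assert_allclose(np.log10(res.D), means, atol=0.1)
    np.testing.assert_allclose(res.f, [0.33, 0.43, 0.24], atol=0.05)
    assert res.D1 > res.D2 > res.D3
    assert res.f1 + res.f2 + res.f3 == pytest.approx(1.0, abs=1e-9)
    assert "Mobility population" in res.summary()


def test_classify_single_component_trivial():
    rng = np.random.default_rng(0)
    vals = 10.0 ** rng.normal(0.5, 0.2, size=400)
    res = classify_populations(vals, k=1, seed=0)
    assert res.f[0] == pytest.approx(1.0)
    assert np.log10(res.D[0]) == pytest.approx(np.log10(vals).mean(), abs=1e-6)


def test_classify_two_components_matches_threshold_oracle():
    rng = np.random.default_rng(5)
    lo = rng.normal(-2.0, 0.1, 300)
    hi = rng.normal(2.0, 0.1, 300)
    vals = 10.0 ** np.concatenate([lo, hi])
    res = classify_populations(vals, k=2, seed=0)
    # midpoint-threshold oracle: every point classifies to its true side
    logd = np.log10(vals)
    pred_hi = np.abs(logd - np.log10(res.D[0])) < np.abs(logd - np.log10(res.D[1]))
    assert np.array_equal(pred_hi, logd > 0.0)
    assert res.f[0] == pytest.approx(0.5, abs=0.02)


def test_classify_excludes_nonpositive_and_requires_enough_points():
    rng = np.random.default_rng(1)
    vals = np.concatenate([10.0 ** rng.normal(0, 0.3, 100), [-0.1, 0.0]])
    model_res = classify_populations(vals, k=1, seed=0)
    assert model_res.n_excluded == 2 and model_res.n_used == 100
    with pytest.raises(ValueError):
        classify_populations(vals[:5], k=3)


def test_running_dinst_window_and_homogeneous_level(no_bleach_continuous):
    traj = brownian_track(400, 8.0, seed=3, sigma=0.025, protocol=no_bleach_continuous)
    t_win, d = running_dinst(traj)
    assert len(d) == 400 - 16 + 1
    assert np.mean(d) == pytest.approx(8.0, rel=0.25)
    # immobile track: the whole series sits below any mobile threshold
    still = brownian_track(400, 1e-5, seed=4, sigma=0.02, protocol=no_bleach_continuous)
    _, d_still = running_dinst(still)
    assert np.all(d_still < 0.5)
    # too-short trajectory -> no output
    short = brownian_track(30, 8.0, seed=5, protocol=no_bleach_continuous)
    assert len(running_dinst(short)[1]) == 0


def _two_state_track(bound_segments, n, D_free=8.0, D_bound=1e-4, sigma=0.025, seed=0):
    """Brownian track with planted bound (slow) segments, frame units."""
    rng = np.random.default_rng(seed)
    dt = 1 / 197.0
    D = np.full(n - 1, D_free)
    for a, b in bound_segments:
        D[a:b] = D_bound
    steps = rng.standard_normal((2, n - 1)) * np.sqrt(2 * D * dt)
    xy = np.concatenate([np.zeros((2, 1)), np.cumsum(steps, axis=1)], axis=1)
    xy += rng.standard_normal(xy.shape) * sigma
    return make_track(xy[0], xy[1], protocol=continuous(bleach_rate_continuous=0.0))


def test_detect_binding_events_finds_planted_segments():
    # two bound segments of 0.3 s (59 frames) separated by a mobile stretch
    traj = _two_state_track([(100, 159), (300, 359)], n=500, seed=21)
    events = detect_binding_events(traj)
    assert len(events) == 2
    for ev, (a, b) in zip(events, [(100, 159), (300, 359)]):
        assert ev.duration_s == pytest.approx((b - a) / 197.0, abs=0.04)
        assert not ev.censored
    # single planted segment overlaps the truth window
    traj1 = _two_state_track([(150, 209)], n=500, seed=22)
    evs = detect_binding_events(traj1)
    assert len(evs) == 1
    assert evs[0].start_s < 209 / 197.0 and evs[0].start_s + evs[0].duration_s > 150 / 197.0


def test_detect_binding_events_empty_and_false_positive_guard():
    # homogeneous fast diffusion: no events even at a generous threshold
    n_events = 0
    for seed in range(100):
        traj = brownian_track(100, 8.0, seed=seed, sigma=0.025,
                              protocol=continuous(bleach_rate_continuous=0.0))
        n_events += len(detect_binding_events(traj, threshold=0.5))
    assert n_events <= 1  # false-positive rate < 1% of tracks


def test_fit_event_rate_and_bleach_correction_arithmetic():
    # apparent 6.7 1/s, bleach 0.34 1/s -> residence 157 ms
    assert correct_bleaching(6.7, 0.34) == pytest.approx(0.15723, abs=1e-4)
    assert correct_bleaching(5.0, 0.0) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        correct_bleaching(0.3, 0.34)


def test_event_rate_competing_exponentials_oracle():
    """Dissociation (rate 5) competing with bleaching (rate 1): surviving
    durations decay at the summed rate 6; correction recovers 5."""
    rng = np.random.default_rng(17)
    dwell = rng.exponential(1 / 5.0, 4000)
    bleach = rng.exponential(1.0, 4000)
    observed = dwell[dwell < bleach]
    rate = fit_event_rate(observed, left_trunc=None)
    assert rate == pytest.approx(6.0, rel=0.06)
    assert 1.0 / correct_bleaching(rate, 1.0) == pytest.approx(5.0, rel=0.08)


def test_event_rate_histogram_method_and_validation():
    rng = np.random.default_rng(2)
    d = rng.exponential(1 / 3.0, 5000)
    assert fit_event_rate(d, method="histogram", left_trunc=None) == pytest.approx(3.0, rel=0.15)
    with pytest.raises(ValueError):
        fit_event_rate(d[:5])
    with pytest.raises(ValueError):
        fit_event_rate(d, method="bogus")


def test_estimate_bleach_rate():
    t = np.linspace(0, 10, 200)
    assert estimate_bleach_rate(t, np.exp(-0.34 * t)) == pytest.approx(0.34, rel=1e-6)
    assert estimate_bleach_rate(t, np.ones_like(t)) == pytest.approx(0.0, abs=1e-6)
    rng = np.random.default_rng(0)
    rates = [
        estimate_bleach_rate(t, np.exp(-0.2 * t) + rng.standard_normal(len(t)) * 0.02)
        for _ in range(5)
    ]
    assert np.mean(rates) == pytest.approx(0.2, rel=0.1)
    with pytest.warns(UserWarning):
        estimate_bleach_rate(t, np.exp(0.05 * t))


def test_event_pipeline_recovers_known_dwell_rate():
    """Detection + truncated rate fit + bleach correction on simulated
    two-state tracks (dwell rate 6.36, bleach 0.34) recovers the apparent
    rate ~6.7 and the residence time within 10%."""
    kin = KineticsConfig(
        diffusion_states=((8.0, 1.0),),
        D_bound=1e-4,
        mean_unbound_s=6.0,
        dwell_model=ExponentialDwell(rate=6.36),
    )
    trajs = simulate_trajectories(kin, continuous(), 10.0, 6500, seed=1234)
    events = []
    for t in trajs:
        events.extend(detect_binding_events(t))
    uncensored = [e for e in events if not e.censored]
    assert len([e for e in uncensored if e.duration_s > 0.15]) >= 1000
    rate_apparent = fit_event_rate(uncensored, left_trunc=0.15)
    assert rate_apparent == pytest.approx(6.7, rel=0.10)
    tau_rs = correct_bleaching(rate_apparent, 0.34)
    assert tau_rs == pytest.approx(1.0 / (6.7 - 0.34), rel=0.10)
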