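import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiratchet.errors import FitFailureError, InvalidInputError, InvalidLagError
from epiratchet.msd import (MSDCurve, StepAnnotation, Trajectory, compute_msd,
                            detect_steps, fit_msd, msd_model, rolling_gamma,
                            step_metrics)
from epiratchet.synth import random_active_runs, synth_trajectories


def brute_force_msd(values, max_lag, dt):
    """Literal double-loop transcription of the MSD definition."""
    values = np.asarray(values, dtype=float)
    N = values.shape[0]
    out = np.zeros(max_lag + 1)
    for n in range(1, max_lag + 1):
        acc = 0.0
        for k in range(N - n):
            d = values[k + n] - values[k]
            acc += float(np.sum(d * d)) if d.ndim else d * d
        out[n] = acc / (N - n)
    return out


def test_msd_constant_series_is_zero():
    c = compute_msd(Trajectory(np.full(50, 3.7), 1.0))
    assert np.allclose(c.msd, 0.0)


def test_msd_linear_drift_closed_form():
    v = 0.02
    traj = Trajectory(v * np.arange(100) * 1.0, 1.0)
    c = compute_msd(traj, 40)
    assert np.allclose(c.msd, (v * c.lags) ** 2)
    assert np.array_equal(c.counts[1:], 100 - np.arange(1, 41))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.booleans())
def test_msd_matches_brute_force(seed, twod):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(40, 2) if twod else 40)
    traj = Trajectory(vals, 0.5)
    c = compute_msd(traj, 39)
    expect = brute_force_msd(vals, 39, 0.5)
    assert np.allclose(c.msd, expect, rtol=1e-12, atol=1e-14)


def test_msd_invalid_lag():
    with pytest.raises(InvalidLagError):
        compute_msd(Trajectory(np.arange(10.0), 1.0), 10)


def test_msd_missing_frames_counted():
    vals = np.arange(20.0)
    vals[5] = np.nan
    c = compute_msd(Trajectory(vals, 1.0), 3)
    assert c.counts[1] == 17  # two pairs touch the missing frame


def test_fit_ballistic_recovers_speed():
    v = 0.01
    traj = Trajectory(v * np.arange(2000) * 1.0, 1.0)
    fit = fit_msd(compute_msd(traj, 500))
    assert fit.C == pytest.approx(v, rel=0.02)
    assert fit.A < 1e-4 and fit.B < 1e-6


def test_fit_diffusion_recovers_coefficient():
    # single-trajectory time-averaged MSD is only trustworthy at lags
    # far below N, so the curve stops at lag 100 (fit over lags 1..25)
    B = 0.01
    errs = []
    for seed in range(5):
        vals, _ = synth_trajectories(B=B, n=1, n_frames=10_000, seed=seed)
        fit = fit_msd(compute_msd(Trajectory(vals[0], 1.0), 100))
        errs.append(abs(fit.B - B) / B)
    assert np.median(errs) <= 0.10


def test_fit_mixed_curve_parameter_recovery():
    rng = np.random.default_rng(7)
    tau = np.arange(0, 200, dtype=float)
    y = msd_model(tau, 0.5, 0.05, 0.001, 0.005)
    y[1:] *= 1.0 + rng.normal(0, 0.01, tau.size - 1)
    fit = fit_msd(MSDCurve(tau, y, np.full(tau.size, 100)),
                  lag_range=(1, 199))
    assert fit.A == pytest.approx(0.5, rel=0.15)
    assert fit.alpha == pytest.approx(0.05, rel=0.15)
    assert fit.B == pytest.approx(0.001, rel=0.15)
    assert fit.C == pytest.approx(0.005, rel=0.15)


def test_fit_is_fixed_point():
    tau = np.arange(0, 150, dtype=float)
    y = msd_model(tau, 0.3, 0.08, 0.002, 0.004)
    first = fit_msd(MSDCurve(tau, y, np.full(tau.size, 50)),
                    lag_range=(1, 149))
    y2 = first.model(tau)
    second = fit_msd(MSDCurve(tau, y2, np.full(tau.size, 50)),
                     lag_range=(1, 149))
    for attr in ("A", "alpha", "B", "C"):
        assert getattr(second, attr) == pytest.approx(
            getattr(first, attr), rel=1e-3, abs=1e-9)


def test_fit_needs_five_points():
    with pytest.raises(InvalidInputError):
        fit_msd(MSDCurve(np.arange(4.0), np.arange(4.0), np.ones(4)),
                lag_range=(1, 3))


def test_gamma_ballistic_near_two():
    rng = np.random.default_rng(0)
    vals = 0.05 * np.arange(300) + rng.normal(0, 0.01, 300)
    g = rolling_gamma(Trajectory(vals, 1.0))
    assert np.nanmedian(g) >= 1.8


def test_gamma_stationary_noise_low():
    rng = np.random.default_rng(1)
    g = rolling_gamma(Trajectory(rng.normal(0, 0.05, 400), 1.0))
    assert np.nanmedian(g) <= 0.5


def test_gamma_brownian_near_one():
    vals, _ = synth_trajectories(B=0.005, n=20, n_frames=500, seed=2)
    med = np.nanmedian(np.concatenate(
        [rolling_gamma(Trajectory(v, 1.0)) for v in vals]))
    assert med == pytest.approx(1.0, abs=0.15)


def test_gamma_window_edges_are_nan():
    vals = np.arange(100.0)
    g = rolling_gamma(Trajectory(vals, 1.0), windows=(21, 41))
    assert np.isnan(g[:10]).all() and np.isnan(g[-10:]).all()
    assert np.isfinite(g[50])


def test_gamma_rejects_short_trajectory():
    with pytest.raises(InvalidInputError):
        rolling_gamma(Trajectory(np.arange(10.0), 1.0))


def staircase(n_frames=400, seed=3, sign=-1.0, alternating=False):
    rng = np.random.default_rng(seed)
    prof = np.zeros(n_frames)
    truth = []
    t, level, s = 60, 0.0, sign
    while t + 20 + 60 < n_frames:
        ramp = level + (np.arange(1, 21) / 20.0) * s
        prof[t:t + 20] = ramp
        prof[t + 20:] = level + s
        truth.append((t, t + 19, s))
        level += s
        t += 20 + 60
        if alternating:
            s = -s
    return prof + rng.normal(0, 0.05, n_frames), truth


def test_detect_steps_staircase():
    vals, truth = staircase()
    traj = Trajectory(vals, 1.0)
    ann = detect_steps(traj, rolling_gamma(traj))
    assert len(ann.steps) == len(truth)
    for (ts, te, disp), (s, e, dur, d) in zip(truth, ann.steps):
        assert s <= te and e >= ts            # overlaps the true ramp
        assert d == pytest.approx(disp, abs=0.3)
    net = sum(s[3] for s in ann.steps)
    assert net == pytest.approx(sum(t[2] for t in truth), abs=0.5)


def test_detect_steps_min_duration_rule():
    vals = np.zeros(100)
    gamma = np.zeros(100)
    gamma[40:50] = 2.0   # only 10 frames above threshold
    ann = detect_steps(Trajectory(vals, 1.0), gamma)
    assert ann.steps == []
    assert not ann.active_mask.any()


def test_detect_steps_alternating_net_zero():
    vals, truth = staircase(n_frames=770, alternating=True, seed=9)
    assert len(truth) % 2 == 0 and sum(t[2] for t in truth) == 0.0
    traj = Trajectory(vals, 1.0)
    ann = detect_steps(traj, rolling_gamma(traj))
    assert len(ann.steps) >= 4
    assert abs(sum(s[3] for s in ann.steps)) < 0.5


def test_detect_steps_offset_invariance_and_sign_flip():
    vals, _ = staircase(seed=5)
    traj = Trajectory(vals, 1.0)
    g = rolling_gamma(traj)
    ann = detect_steps(traj, g)
    ann_off = detect_steps(Trajectory(vals + 17.0, 1.0),
                           rolling_gamma(Trajectory(vals + 17.0, 1.0)))
    assert [s[:2] for s in ann.steps] == [s[:2] for s in ann_off.steps]
    assert np.allclose([s[3] for s in ann.steps],
                       [s[3] for s in ann_off.steps], atol=1e-9)
    ann_neg = detect_steps(Trajectory(-vals, 1.0),
                           rolling_gamma(Trajectory(-vals, 1.0)))
    assert np.allclose([s[3] for s in ann_neg.steps],
                       [-s[3] for s in ann.steps], atol=1e-9)


def test_step_recall_and_false_positives():
    runs = random_active_runs(n=20, n_frames=500, run_len=20, n_runs=2,
                              seed=13)
    vals, _ = synth_trajectories(C=0.05, noise_sigma=0.05, n=20,
                                 n_frames=500, active_runs=runs, seed=14)
    hits = total = 0
    for i in range(20):
        traj = Trajectory(vals[i], 1.0)
        ann = detect_steps(traj, rolling_gamma(traj))
        for (s, e, _) in runs[i]:
            total += 1
            hits += any(ds <= e and de >= s for (ds, de, _, _) in ann.steps)
    assert hits / total >= 0.9
    diff, _ = synth_trajectories(B=1e-4, noise_sigma=0.05, n=60,
                                 n_frames=500, seed=15)
    active = sum(
        detect_steps(t := Trajectory(diff[i], 1.0),
                     rolling_gamma(t)).active_mask.sum()
        for i in range(60))
    assert active / (60 * 500) <= 0.05


def test_step_metrics_arithmetic():
    ann = StepAnnotation(np.zeros(140), np.zeros(140, bool),
                         [(60, 73, 14.0, -0.8)], 1.0)
    m = step_metrics({"i": ann})
    row = m.loc["i"]
    assert row.frequency_per_min == pytest.approx(1 / (140 / 60))
    assert row.mean_duration_s == pytest.approx(14.0)
    assert row.net_displacement == pytest.approx(-0.8)


def test_step_metrics_empty_annotation():
    ann = StepAnnotation(np.zeros(100), np.zeros(100, bool), [], 1.0)
    m = step_metrics({"i": ann})
    assert m.loc["i"].n_steps == 0
    assert m.loc["i"].net_displacement == 0.0
    assert np.isnan(m.loc["i"].mean_duration_s)
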