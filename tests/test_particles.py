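import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import correlate1d

from epiratchet.errors import InvalidJError
from epiratchet.particles import (ParticleDetection, _dilated_kernel,
                                  atrous_decompose, corrected_mean_lifetime,
                                  detect_movie, detect_particles, link_tracks,
                                  track_lifetimes)
from epiratchet.synth import synth_gap_stubs, synth_spot_frames


def det(t, r, c):
    return ParticleDetection(t, (float(r), float(c)),
                             np.zeros((0, 2), int), 1, 1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 4))
def test_atrous_reconstruction_is_exact(seed, J):
    rng = np.random.default_rng(seed)
    img = rng.normal(10, 3, (48, 48))
    stack = atrous_decompose(img, J)
    assert stack.J == J
    assert np.max(np.abs(stack.reconstruct() - img)) < 1e-9


def test_atrous_impulse_matches_direct_convolution():
    img = np.zeros((65, 65))
    img[32, 32] = 1.0
    stack = atrous_decompose(img, 3)
    smooth = img
    for i, plane in enumerate(stack.planes):
        k = _dilated_kernel(i)
        nxt = correlate1d(correlate1d(smooth, k, axis=0, mode="reflect"),
                          k, axis=1, mode="reflect")
        assert np.allclose(plane, smooth - nxt, atol=1e-12)
        smooth = nxt


def test_atrous_constant_image_zero_planes():
    stack = atrous_decompose(np.full((32, 32), 7.0), 3)
    for plane in stack.planes:
        assert np.allclose(plane, 0.0, atol=1e-12)


def test_atrous_invalid_J():
    with pytest.raises(InvalidJError):
        atrous_decompose(np.zeros((10, 10)), 4)
    with pytest.raises(InvalidJError):
        atrous_decompose(np.zeros((10, 10)), 0)


def test_detect_blank_image():
    assert detect_particles(np.zeros((64, 64))) == []
    assert detect_particles(np.full((64, 64), 5.0)) == []


def spot_image(centers, amp_sigmas, shape=(64, 64), background=100.0,
               read=3.0, seed=5):
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, background, dtype=float)
    sig_bg = np.sqrt(background + read ** 2)
    for (r0, c0), (snr, s) in zip(centers, amp_sigmas):
        img += snr * sig_bg * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s ** 2))
    return rng.poisson(img) + rng.normal(0, read, shape)


def test_detect_single_bright_spot():
    img = spot_image([(30.0, 33.0)], [(10.0, 2.0)])
    dets = detect_particles(img)
    assert len(dets) == 1
    assert np.hypot(dets[0].centroid[0] - 30, dets[0].centroid[1] - 33) < 1.0


def test_detect_two_spots_ten_px_apart():
    img = spot_image([(30.0, 27.0), (30.0, 37.0)], [(10.0, 2.0)] * 2)
    dets = detect_particles(img)
    assert len(dets) == 2


def test_detection_translation_equivariance():
    rng = np.random.default_rng(9)
    rr, cc = np.mgrid[0:96, 0:96]
    base = 100.0 + 60.0 * np.exp(
        -((rr - 40.3) ** 2 + (cc - 38.7) ** 2) / (2 * 1.44))
    noise = rng.normal(0, 5.0, (96, 96))
    d1 = detect_particles(base + noise)
    d2 = detect_particles(np.roll(base + noise, (7, 11), axis=(0, 1)))
    assert len(d1) == len(d2) == 1
    shift = np.array(d2[0].centroid) - np.array(d1[0].centroid)
    assert np.allclose(shift, (7, 11), atol=0.1)


def test_detection_cohort_metrics():
    movie, truth = synth_spot_frames(n_frames=4, spots_per_frame=25,
                                     snr=5.0, seed=21)
    dets = detect_movie(movie)
    tp = fp = 0
    errs = []
    for t in range(4):
        tr = truth[truth.frame == t][["row", "col"]].to_numpy()
        used = set()
        for d in dets[t]:
            dd = np.linalg.norm(tr - np.array(d.centroid), axis=1)
            j = int(np.argmin(dd))
            if dd[j] <= 2.0 and j not in used:
                tp += 1
                used.add(j)
                errs.append(dd[j])
            else:
                fp += 1
    assert tp / len(truth) >= 0.95
    assert tp / (tp + fp) >= 0.95
    assert np.sqrt(np.mean(np.square(errs))) <= 1.0


def test_link_drift_with_missing_frame_closes_gap():
    frames = [[] if t == 5 else [det(t, 20.0 + t, 30.0)] for t in range(10)]
    tracks = link_tracks(frames, 1.0)
    assert len(tracks) == 1
    assert tracks[0].closed_gaps == [(5, 5)]
    assert tracks[0].lifetime_frames == 10


def test_link_distant_stubs_not_joined():
    frames = [[det(0, 10, 10)], [det(1, 10, 10)], [], [],
              [det(4, 10, 16)], [det(5, 10, 16)]]
    tracks = link_tracks(frames, 1.0)
    assert len(tracks) == 2


def test_link_long_time_gap_not_joined():
    frames = [[det(0, 10, 10)], [det(1, 10, 10)], [], [], [],
              [det(5, 10, 11)], [det(6, 10, 11)]]
    tracks = link_tracks(frames, 1.0)  # 4 s gap > 3 s
    assert len(tracks) == 2


def test_fast_crossing_terminates_rather_than_swaps():
    frames = []
    for t in range(7):
        frames.append([det(t, 50.0, 10.0 + 8 * t),
                       det(t, 13.0 + 8 * t, 50.0)])
    tracks = link_tracks(frames, 1.0, max_link_dist=4.0)
    # every displacement is 8 px > max_link_dist and no stub pair
    # satisfies the gap rules, so no detections are ever linked
    assert len(tracks) == 14
    assert all(t.lifetime_frames == 1 for t in tracks)


def test_gap_closing_respects_both_rules():
    dets, designs = synth_gap_stubs(n_pairs=24, seed=7)
    tracks = link_tracks(dets, 1.0)
    for _, row in designs.iterrows():
        ep, sp = np.array(row.end_pos), np.array(row.start_pos)
        closed = any(
            any(np.allclose(d.centroid, ep) for d in tr.detections)
            and any(np.allclose(d.centroid, sp) for d in tr.detections)
            for tr in tracks)
        assert closed == row.should_close, dict(row)


def test_lifetime_formula_and_censoring():
    tracks = [type("T", (), dict(track_id=0, t_start=10, t_end=20,
                                 lifetime_frames=11))(),
              type("T", (), dict(track_id=1, t_start=0, t_end=99,
                                 lifetime_frames=100))()]
    table = track_lifetimes(tracks, 100, 1.0, correct=True)
    assert table.loc[0, "lifetime_frames"] == 11
    assert not table.loc[0, "censored"]
    assert table.loc[1, "censored"]


def test_lifetime_correction_on_stationary_cohort():
    rng = np.random.default_rng(1)
    mean = 20.0
    T = 100
    tracks = []
    i = 0
    for _ in range(20_000):
        t0 = int(rng.integers(-300, T))
        L = max(1, int(round(rng.exponential(mean))))
        t1 = t0 + L - 1
        if t1 < 0 or t0 > T - 1:
            continue
        tr = type("T", (), dict(track_id=i, t_start=max(t0, 0),
                                t_end=min(t1, T - 1)))()
        tr.lifetime_frames = tr.t_end - tr.t_start + 1
        tracks.append(tr)
        i += 1
    table = track_lifetimes(tracks, T, 1.0, correct=True)
    assert corrected_mean_lifetime(table) == pytest.approx(mean, rel=0.10)
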