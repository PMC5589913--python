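import math

import numpy as np
import pandas as pd
import pytest

from epiratchet.association import (AssociationRecord, angle_class, associate,
                                    associate_live, associate_tracks,
                                    classify_interfaces, colocalize_fixed,
                                    density_profile, detection_side,
                                    opposing_area_coupling, pairing_analysis,
                                    pairing_frequencies)
from epiratchet.errors import OutOfTissueError
from epiratchet.geometry import AP, APICAL, TRANSVERSE, TissueFrame
from epiratchet.segmentation import track_cells
from conftest import quad_labels


def brute_force_associate(point, frame, cutoff=10.0):
    """Literal rule-by-rule transcription with plain loops."""
    dists = {}
    for key, rec in frame.interfaces.items():
        if rec.contour_pixels.shape[0] == 0:
            continue
        dists[key] = min(math.hypot(point[0] - r, point[1] - c)
                         for r, c in rec.contour_pixels)
    if not dists:
        return APICAL
    items = sorted(dists.items(), key=lambda kv: kv[1])
    key, d1 = items[0]
    if d1 > cutoff:                                  # rule (i)
        return APICAL
    if len(items) > 1 and not d1 < items[1][1] - 1e-9:  # rule (ii)
        return APICAL
    rec = frame.interfaces[key]
    if rec.vertex_pair is None:
        return APICAL
    dv = min(math.hypot(point[0] - frame.vertices[v].position[0],
                        point[1] - frame.vertices[v].position[1])
             for v in rec.vertex_pair)
    if dv < min(1.0, 0.1 * rec.length_px):           # rule (iii)
        return APICAL
    return key


def random_voronoi_frame(rng, size=120, n_cells=12):
    from scipy.spatial import cKDTree

    pts = rng.uniform(5, size - 5, size=(n_cells, 2))
    rr, cc = np.mgrid[0:size, 0:size]
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    _, idx = cKDTree(pts).query(grid)
    labels = (idx + 1).reshape(size, size).astype(np.int64)
    return TissueFrame.from_labels(labels)


@pytest.fixture
def quad_frame(unit_meta):
    return TissueFrame.from_labels(quad_labels(60), 0, unit_meta)


def test_associate_all_rules_met(quad_frame):
    # near the 1-2 interface (row < 30, around col 30), away from the
    # central vertex and far from the other interfaces
    res = associate((8.0, 28.0), quad_frame)
    assert res == (1, 2)


def test_associate_rule_distance_fails(quad_frame):
    assert associate((15.0, 15.0), quad_frame) == APICAL  # > 10 px away


def test_associate_rule_vertex_fails(quad_frame):
    # central vertex near (29.5, 29.5); a point on the 1-2 interface
    # within the vertex cutoff falls back to APICAL
    assert associate((29.0, 29.4), quad_frame) == APICAL


def test_associate_tie_goes_apical(quad_frame):
    # equidistant from the 1-2 and 1-3 interfaces by symmetry
    assert associate((24.0, 24.0), quad_frame) == APICAL


def test_associate_outside_tissue_raises(quad_frame):
    with pytest.raises(OutOfTissueError):
        associate((-3.0, 10.0), quad_frame)


def test_associate_matches_brute_force_on_random_geometries(unit_meta):
    rng = np.random.default_rng(42)
    n_checked = 0
    for _ in range(6):
        frame = random_voronoi_frame(rng)
        for _ in range(40):
            p = rng.uniform(2, 118, size=2)
            r, c = int(round(p[0])), int(round(p[1]))
            if frame.label_image[r, c] == 0:
                continue
            assert associate(p, frame) == brute_force_associate(p, frame)
            n_checked += 1
    assert n_checked >= 200


def test_association_unique_per_frame(quad_frame):
    rng = np.random.default_rng(3)
    for _ in range(100):
        p = rng.uniform(1, 58, size=2)
        res = associate(p, quad_frame)
        assert res == APICAL or res in quad_frame.interfaces


@pytest.mark.parametrize("angle,expected", [
    (90.0, AP), (0.0, TRANSVERSE), (74.0, TRANSVERSE), (76.0, AP),
    (105.0, AP), (106.0, TRANSVERSE),
])
def test_angle_classification_boundary(angle, expected):
    assert angle_class(angle) == expected


def test_classify_interfaces_on_tissue(static_tissue):
    tracked = track_cells(static_tissue.label_movie, static_tissue.metadata)
    classes = classify_interfaces(tracked)
    joints = set(static_tissue.joint_pair.values())
    for key, cls in classes.items():
        if key in joints:
            assert cls == AP
        else:
            assert cls == TRANSVERSE


def _frames_for_density(static_tissue, n):
    import dataclasses

    fr0 = TissueFrame.from_labels(static_tissue.label_movie[0], 0,
                                  static_tissue.metadata)
    return [dataclasses.replace(fr0, frame_index=t) for t in range(n)]


def test_density_formula_and_sum_property(static_tissue):
    frames = _frames_for_density(static_tissue, 3)
    fr0 = frames[0]
    vertical = [k for k, rec in fr0.interfaces.items()
                if abs(rec.angle_deg - 90) < 1][:3]
    records = [AssociationRecord(i, f"{a}-{b}", 1, 0, 2)
               for i, (a, b) in enumerate(vertical)]
    prof = density_profile(frames, records)
    n_vert = sum(1 for rec in fr0.interfaces.values()
                 if abs(rec.angle_deg - 90) < 1)
    col = prof.per_frame["90-105"]
    assert np.allclose(col.to_numpy(), 3 / n_vert)
    # per-frame counts reproduce total associated particles
    assert prof.n_associated == 3 * 3
    assert prof.vertical_fraction == 1.0


def test_density_no_particles(static_tissue):
    frames = _frames_for_density(static_tissue, 2)
    prof = density_profile(frames, [])
    arr = prof.per_frame.to_numpy()
    assert np.nansum(arr) == 0.0
    assert np.isnan(prof.vertical_fraction)


def test_pairing_definitions():
    recs = [
        AssociationRecord(0, "1-2", +1, 10, 30),
        AssociationRecord(1, "1-2", -1, 20, 40),   # paired with 0
        AssociationRecord(2, "3-4", +1, 5, 15),    # nothing opposite
        AssociationRecord(3, "3-4", +1, 10, 12),   # same side concurrent
    ]
    ev = pairing_analysis(recs).set_index("track_id")
    assert ev.loc[0, "paired"] and ev.loc[1, "paired"]
    assert not ev.loc[2, "paired"] and ev.loc[2, "multiple"]
    f = pairing_frequencies(ev.reset_index())
    assert f["paired"] == pytest.approx(0.5)
    assert f["multiple"] == pytest.approx(1.0)


def test_pairing_generator_fraction_recovered():
    from epiratchet.synth import synth_association_events

    recs, truth = synth_association_events(n=300, pairing_fraction=0.07,
                                           seed=5)
    f = pairing_frequencies(pairing_analysis(recs))
    assert truth == pytest.approx(0.07, abs=0.01)
    assert f["paired"] == pytest.approx(truth, abs=1e-9)


def test_colocalize_identical_and_disjoint():
    m = np.zeros((40, 40), bool)
    m[5:8, 5:8] = True
    _, pct = colocalize_fixed(m, m, 0.164)
    assert pct == 100.0
    other = np.zeros((40, 40), bool)
    other[20:23, 20:23] = True
    _, pct0 = colocalize_fixed(m, other, 0.164)
    assert pct0 == 0.0


def test_colocalize_half_overlapping():
    a = np.zeros((60, 60), bool)
    b = np.zeros((60, 60), bool)
    a[5:8, 5:8] = True          # overlaps b by 3x3 > 2x2
    b[5:8, 5:8] = True
    a[20:23, 20:23] = True      # no overlap
    _, pct = colocalize_fixed(a, b, 0.164)
    assert pct == 50.0


def test_colocalize_size_filter():
    a = np.zeros((40, 40), bool)
    a[5, 5] = True              # 1 px: below the 2 px size floor
    b = np.ones((40, 40), bool)
    table, pct = colocalize_fixed(a, b, 0.164)
    assert math.isnan(pct)


class _FakeTrack:
    def __init__(self, tid, dets):
        from epiratchet.particles import ParticleDetection

        self.track_id = tid
        self.detections = [
            ParticleDetection(t, (float(r), float(c)),
                              np.array(foot, dtype=int), len(foot), 1.0)
            for (t, r, c, foot) in dets]

    @property
    def t_start(self):
        return self.detections[0].frame

    @property
    def t_end(self):
        return self.detections[-1].frame

    @property
    def lifetime_frames(self):
        return self.t_end - self.t_start + 1


def _blob(r, c, k=2):
    return [(r + i, c + j) for i in range(k) for j in range(k)]


def test_associate_live_rules():
    a = _FakeTrack(0, [(t, 10, 10, _blob(10, 10)) for t in range(10)])
    # overlap for exactly 1 frame: not associated (strictly > 1 s)
    b_short = _FakeTrack(1, [(4, 10, 10, _blob(10, 10))])
    df, prof, _ = associate_live([a], [b_short], 1.0)
    assert not df.associated.iloc[0]
    # 5 s overlap late in a's life: associated, onset fraction > 0.5
    b_late = _FakeTrack(2, [(t, 10, 10, _blob(10, 10)) for t in range(6, 10)])
    df2, prof2, _ = associate_live([a], [b_late], 1.0)
    assert df2.associated.iloc[0]
    assert df2.onset_fraction.iloc[0] > 0.5
    assert prof2.sum() == 1


def test_associate_live_overlap_area_rule():
    a = _FakeTrack(0, [(t, 10, 10, _blob(10, 10)) for t in range(6)])
    # 1 px overlap only: not associated (strictly > 1 px)
    b = _FakeTrack(1, [(t, 11, 11, [(11, 11)]) for t in range(6)])
    df, _, _ = associate_live([a], [b], 1.0)
    assert not df.associated.iloc[0]


def test_associate_live_late_onset_profile():
    tracks_a, tracks_b = [], []
    rng = np.random.default_rng(8)
    for i in range(30):
        a = _FakeTrack(i, [(t, 10, 10 + 4 * i, _blob(10, 10 + 4 * i))
                           for t in range(12)])
        onset = int(rng.integers(8, 10))  # final third of a 12-frame life
        b = _FakeTrack(100 + i,
                       [(t, 10, 10 + 4 * i, _blob(10, 10 + 4 * i))
                        for t in range(onset, 12)])
        tracks_a.append(a)
        tracks_b.append(b)
    df, prof, edges = associate_live(tracks_a, tracks_b, 1.0)
    assert df.associated.all()
    assert prof[-2:].sum() == 30  # all onsets in the final bins


def test_opposing_area_coupling_and_time_reversal(static_tissue):
    fr0 = TissueFrame.from_labels(static_tissue.label_movie[0], 0,
                                  static_tissue.metadata)
    pair = next(iter(static_tissue.joint_pair.values()))
    a, b = (int(x) for x in pair.split("-"))
    n = 200
    area = np.full(n, 50.0)
    area[100:] = 50.0 - np.arange(100) * 0.05   # contraction from t=100
    series = pd.DataFrame({a: np.full(n, 50.0), b: area})
    rec = AssociationRecord(0, pair, +1, 70, 100)  # side +1 -> opposing = b
    out = opposing_area_coupling([rec], {t: fr0 for t in range(n)},
                                 series, 1.0)
    assert out.pre_rate.iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out.post_rate.iloc[0] < -1e-4
    # time reversal flips the asymmetry: around the mirrored termination
    # frame, pre and post swap with opposite sign
    series_rev = series.iloc[::-1].reset_index(drop=True)
    rec_rev = AssociationRecord(0, pair, +1, 69, n - 1 - 100)
    out_rev = opposing_area_coupling([rec_rev], {t: fr0 for t in range(n)},
                                     series_rev, 1.0)
    assert out_rev.post_rate.iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out_rev.pre_rate.iloc[0] > 1e-4


def test_detection_side_matches_label(quad_frame):
    # point inside cell 1, near the 1-2 interface
    assert detection_side((10.0, 27.0), quad_frame, (1, 2)) == +1
    assert detection_side((10.0, 33.0), quad_frame, (1, 2)) == -1
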