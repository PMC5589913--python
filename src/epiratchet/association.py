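"""Compartment-to-interface association, polarity and pairing analytics.

A compartment is uniquely associated with an interface iff all three
geometric rules hold: (i) it lies on or within 10 px (1.66 um) of the
interface contour; (ii) it is strictly closer to this interface than to
any other (ties, within 1e-9 px, fall back to APICAL); (iii) it is at
least min(1 px, 0.1 x interface length) away from the closest of the
interface's two endpoint vertices.  Distances to an interface use its
contour pixels (compartments sit on the curved boundary); the vertex
rule uses the vertex positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, OutOfTissueError
from .geometry import (AP, APICAL, TRANSVERSE, UNCLASSIFIED, TissueFrame,
                       TrackedTissue, circular_mean_angle)

DIST_CUTOFF_PX = 10.0
TIE_TOL = 1e-9


@dataclass
class AssociationRecord:
    track_id: int
    interface_id: str            # "a-b" key or APICAL
    side: int                    # +1 / -1: which cell of the pair; 0 unknown
    t_start: int
    t_end: int

    @property
    def lifetime_frames(self) -> int:
        return self.t_end - self.t_start + 1


def _interface_distances(point: np.ndarray, frame: TissueFrame):
    """Min distance from a point to each interface's contour pixels."""
    out = {}
    for key, rec in frame.interfaces.items():
        if rec.contour_pixels.shape[0] == 0:
            continue
        d = np.linalg.norm(rec.contour_pixels - point, axis=1)
        out[key] = float(d.min())
    return out


def associate(point, frame: TissueFrame,
              dist_cutoff: float = DIST_CUTOFF_PX):
    """Assign one detection centroid to an interface id or APICAL."""
    p = np.asarray(point, dtype=float)
    H, W = frame.label_image.shape
    r, c = int(round(p[0])), int(round(p[1]))
    if not (0 <= r < H and 0 <= c < W) or frame.label_image[r, c] == 0:
        raise OutOfTissueError(f"centroid {tuple(p)} outside segmented region")
    dists = _interface_distances(p, frame)
    if not dists:
        return APICAL
    ordered = sorted(dists.items(), key=lambda kv: kv[1])
    best_key, d1 = ordered[0]
    if d1 > dist_cutoff:
        return APICAL
    if len(ordered) > 1 and not (d1 < ordered[1][1] - TIE_TOL):
        return APICAL  # no unique nearest interface
    rec = frame.interfaces[best_key]
    if rec.vertex_pair is None or not np.isfinite(rec.length_px):
        return APICAL
    vpos = np.array([frame.vertices[v].position for v in rec.vertex_pair])
    dv = float(np.linalg.norm(vpos - p, axis=1).min())
    vcut = min(1.0, 0.1 * rec.length_px)
    if dv < vcut:
        return APICAL
    return best_key


def detection_side(point, frame: TissueFrame, interface_key) -> int:
    """Which of the interface's two cells the detection lies in (+1/-1).

    +1 = the lower-id cell of the pair, -1 = the higher-id cell,
    decided by the label containing (or nearest to) the centroid.
    """
    p = np.asarray(point, dtype=float)
    a, b = frame.interfaces[interface_key].cell_pair
    r = int(round(p[0]))
    c = int(round(p[1]))
    lab = int(frame.label_image[r, c])
    if lab == a:
        return +1
    if lab == b:
        return -1
    # centroid on another label (e.g. exactly on a contour pixel of a
    # neighbor): nearest pixel of either cell decides
    da = _min_dist_to_label(p, frame.label_image, a)
    db = _min_dist_to_label(p, frame.label_image, b)
    return +1 if da <= db else -1


def _min_dist_to_label(p, labels, lab):
    pts = np.argwhere(labels == lab)
    return float(np.linalg.norm(pts - p, axis=1).min())


def angle_class(mean_angle_deg: float, tol_deg: float = 15.0) -> str:
    """AP iff within tol of the DV axis (90 deg), else transverse."""
    if not np.isfinite(mean_angle_deg):
        return UNCLASSIFIED
    return AP if abs(mean_angle_deg - 90.0) <= tol_deg else TRANSVERSE


def classify_interfaces(tracked: TrackedTissue, window_s: float = 90.0,
                        tol_deg: float = 15.0) -> dict[str, str]:
    """AP / transverse classification from the initial mean angle.

    The mean orientation over the first ``window_s`` seconds decides:
    within ``tol_deg`` of the DV axis (angle in [75, 105] by default)
    is AP, otherwise transverse; interfaces absent in the window are
    unclassified.
    """
    n_frames = int(round(window_s / tracked.metadata.frame_interval))
    angles: dict[str, list[float]] = {}
    for fr in tracked.frames:
        if fr.frame_index * tracked.metadata.frame_interval >= window_s:
            continue
        for (a, b), rec in fr.interfaces.items():
            if np.isfinite(rec.angle_deg):
                angles.setdefault(f"{a}-{b}", []).append(rec.angle_deg)
    out = {}
    for key in tracked.length_series.columns:
        vals = angles.get(key)
        if not vals:
            out[key] = UNCLASSIFIED
            continue
        out[key] = angle_class(circular_mean_angle(vals), tol_deg)
    return out


def associate_tracks(tracks, frames_by_index: dict[int, TissueFrame],
                     dist_cutoff: float = DIST_CUTOFF_PX) -> list[AssociationRecord]:
    """Track-level association: per-frame associate() + majority vote.

    Ties go to the interface of the first associated frame.  The side
    assignment is the majority side over the voted interface's frames.
    """
    records = []
    for tr in tracks:
        votes: dict = {}
        order: dict = {}
        sides: dict = {}
        for det in tr.detections:
            fr = frames_by_index.get(det.frame)
            if fr is None:
                continue
            try:
                key = associate(det.centroid, fr, dist_cutoff)
            except OutOfTissueError:
                continue
            votes[key] = votes.get(key, 0) + 1
            order.setdefault(key, det.frame)
            if key != APICAL:
                s = detection_side(det.centroid, fr, key)
                sides.setdefault(key, []).append(s)
        if not votes:
            continue
        win = max(votes.items(), key=lambda kv: (kv[1], -order[kv[0]] if
                                                 isinstance(order[kv[0]], int) else 0))[0]
        # deterministic tie-break: earliest first-associated frame
        top = max(votes.values())
        tied = [k for k, v in votes.items() if v == top]
        if len(tied) > 1:
            win = min(tied, key=lambda k: order[k])
        if win == APICAL:
            iface, side = APICAL, 0
        else:
            iface = f"{win[0]}-{win[1]}"
            svals = sides.get(win, [])
            side = 1 if sum(svals) >= 0 else -1
        records.append(AssociationRecord(tr.track_id, iface, side,
                                         tr.t_start, tr.t_end))
    return records


@dataclass
class DensityProfile:
    bin_edges: np.ndarray
    per_frame: pd.DataFrame        # frames x bins, particles per interface
    time_averaged: np.ndarray
    vertical_fraction: float       # associated compartments within 30 deg of DV
    horizontal_fraction: float
    n_associated: int


def density_profile(frames: list[TissueFrame],
                    records: list[AssociationRecord],
                    bin_width: float = 15.0) -> DensityProfile:
    """Compartment density per interface-angle bin.

    Density(t) = N_compartments(t) / N_interfaces(t) per angle bin;
    bins with no interfaces yield NaN (missing, not zero).  The summary
    fractions count associated compartments on interfaces within 30
    degrees of the vertical (DV) or horizontal (AP) image axis.
    """
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    nb = len(edges) - 1
    iface_angle: dict[str, dict[int, float]] = {}
    for fr in frames:
        for (a, b), rec in fr.interfaces.items():
            iface_angle.setdefault(f"{a}-{b}", {})[fr.frame_index] = rec.angle_deg
    active: dict[int, list[str]] = {}
    for r in records:
        if r.interface_id == APICAL:
            continue
        for t in range(r.t_start, r.t_end + 1):
            active.setdefault(t, []).append(r.interface_id)
    per_frame = {}
    vert = horiz = n_assoc = 0
    for fr in frames:
        t = fr.frame_index
        angles = np.array([rec.angle_deg for rec in fr.interfaces.values()])
        angles = angles[np.isfinite(angles)]
        n_if, _ = np.histogram(angles, bins=edges)
        part_angles = []
        for key in active.get(t, []):
            ang = iface_angle.get(key, {}).get(t)
            if ang is not None and np.isfinite(ang):
                part_angles.append(ang)
        n_p, _ = np.histogram(part_angles, bins=edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            dens = np.where(n_if > 0, n_p / np.maximum(n_if, 1), np.nan)
        per_frame[t] = dens
        n_assoc += len(part_angles)
        for ang in part_angles:
            if abs(ang - 90.0) <= 30.0:
                vert += 1
            if ang <= 30.0 or ang >= 150.0:
                horiz += 1
    df = pd.DataFrame.from_dict(per_frame, orient="index").sort_index()
    df.columns = [f"{edges[i]:.0f}-{edges[i+1]:.0f}" for i in range(nb)]
    arr = df.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tavg = np.nanmean(arr, axis=0)
    return DensityProfile(
        edges, df, tavg,
        vertical_fraction=vert / n_assoc if n_assoc else float("nan"),
        horizontal_fraction=horiz / n_assoc if n_assoc else float("nan"),
        n_associated=n_assoc)


def pairing_analysis(records: list[AssociationRecord]) -> pd.DataFrame:
    """Paired/unpaired and single/multiple scoring per interface event.

    paired: a compartment on the opposite side of the same interface
    overlaps in time by >= 1 frame.  multiple: >= 2 compartments
    coexist on the interface (either side) during the event.  Events
    without a side assignment are excluded.
    """
    rows = []
    by_iface: dict[str, list[AssociationRecord]] = {}
    for r in records:
        if r.interface_id == APICAL:
            continue
        by_iface.setdefault(r.interface_id, []).append(r)
    for iface, evs in by_iface.items():
        for r in evs:
            if r.side == 0:
                continue
            others = [o for o in evs if o is not r]
            overlap = [o for o in others
                       if o.t_start <= r.t_end and o.t_end >= r.t_start]
            paired = any(o.side == -r.side for o in overlap)
            rows.append(dict(track_id=r.track_id, interface_id=iface,
                             paired=paired,
                             unpaired_strict=not any(
                                 o.side == -r.side for o in overlap),
                             multiple=len(overlap) > 0))
    df = pd.DataFrame(rows)
    return df


def pairing_frequencies(events: pd.DataFrame) -> dict[str, float]:
    if events.empty:
        return dict(paired=float("nan"), unpaired=float("nan"),
                    single=float("nan"), multiple=float("nan"))
    return dict(paired=float(events.paired.mean()),
                unpaired=float(1.0 - events.paired.mean()),
                single=float(1.0 - events.multiple.mean()),
                multiple=float(events.multiple.mean()))


def colocalize_fixed(mask_a: np.ndarray, mask_b: np.ndarray,
                     pixel_size: float,
                     size_range: tuple[int, int] = (2, 15),
                     grid_um: float = 5.0,
                     min_overlap_px: int = 4) -> tuple[pd.DataFrame, float]:
    """Grid-wise colocalization of two punctate masks.

    Puncta of 2-15 px in either channel are kept; an A-punctum is
    colocalized when its pixel overlap with the B mask exceeds
    ``min_overlap_px`` (the > 2x2 px rule).  Returns the per-grid-cell
    table and the count-weighted average percentage.
    """
    from skimage.measure import label as cc_label

    la = cc_label(np.asarray(mask_a) > 0, connectivity=2)
    lb = cc_label(np.asarray(mask_b) > 0, connectivity=2)

    def _keep(lab):
        ids, counts = np.unique(lab[lab > 0], return_counts=True)
        good = set(int(i) for i, c in zip(ids, counts)
                   if size_range[0] <= c <= size_range[1])
        return good

    good_a, good_b = _keep(la), _keep(lb)
    bmask = np.isin(lb, list(good_b)) if good_b else np.zeros_like(lb, bool)
    step = max(1, int(round(grid_um / pixel_size)))
    rows = []
    for ga in sorted(good_a):
        pts = np.argwhere(la == ga)
        cr, cc_ = pts.mean(axis=0)
        cell = (int(cr // step), int(cc_ // step))
        ov = int(bmask[pts[:, 0], pts[:, 1]].sum())
        rows.append(dict(punctum=ga, grid_row=cell[0], grid_col=cell[1],
                         overlap_px=ov, colocalized=ov > min_overlap_px))
    df = pd.DataFrame(rows)
    if df.empty:
        return df, float("nan")
    per_cell = df.groupby(["grid_row", "grid_col"]).agg(
        n=("punctum", "size"), n_coloc=("colocalized", "sum")).reset_index()
    per_cell["pct"] = per_cell.n_coloc / per_cell.n * 100.0
    overall = float(df.colocalized.mean() * 100.0)  # count-weighted average
    return per_cell, overall


def associate_live(tracks_a, tracks_b, frame_interval: float = 1.0,
                   min_overlap_px: int = 1, min_overlap_s: float = 1.0,
                   n_bins: int = 5):
    """Track-to-track live association with onset timing profile.

    An A-track is associated when its footprint overlaps any B-track by
    more than ``min_overlap_px`` pixels for strictly longer than
    ``min_overlap_s``.  The onset is reported as a fraction of the
    A-track's lifetime and binned into ``n_bins`` equal bins.
    """
    foot_b: dict[int, list[set]] = {}
    for tb in tracks_b:
        for det in tb.detections:
            foot_b.setdefault(det.frame, []).append(
                set(map(tuple, det.footprint)))
    rows = []
    for ta in tracks_a:
        qual = []
        for det in ta.detections:
            ok = False
            fa = set(map(tuple, det.footprint))
            for fb in foot_b.get(det.frame, []):
                if len(fa & fb) > min_overlap_px:
                    ok = True
                    break
            qual.append((det.frame, ok))
        onset = None
        run_start, run_len = None, 0
        for f, ok in qual:
            if ok:
                if run_start is None:
                    run_start, run_len = f, 1
                else:
                    run_len += 1
                if run_len * frame_interval > min_overlap_s:
                    onset = run_start
                    break
            else:
                run_start, run_len = None, 0
        lifetime = ta.lifetime_frames
        frac = (np.nan if onset is None else
                (onset - ta.t_start) / max(lifetime - 1, 1))
        rows.append(dict(track_id=ta.track_id, associated=onset is not None,
                         onset_frame=onset, onset_fraction=frac))
    df = pd.DataFrame(rows)
    fr = df.onset_fraction.dropna().to_numpy()
    profile, edges = np.histogram(fr, bins=n_bins, range=(0.0, 1.0 + 1e-12))
    return df, profile, edges


def opposing_area_coupling(records: list[AssociationRecord],
                           frames_by_index: dict[int, TissueFrame],
                           area_series: pd.DataFrame,
                           frame_interval: float,
                           window_s: float = 30.0) -> pd.DataFrame:
    """Opposing-cell area rates before vs after compartment termination.

    The opposing cell is the interface cell on the side without the
    compartment; rates are normalized area rates (see ``area_rate``)
    over ``window_s`` windows ending/starting at the termination frame.
    Events whose opposing cell is not tracked through both windows are
    skipped.
    """
    from .oscillation import area_rate

    w = int(round(window_s / frame_interval))
    rows = []
    for r in records:
        if r.interface_id == APICAL or r.side == 0:
            continue
        a, b = (int(x) for x in r.interface_id.split("-"))
        opposing = b if r.side == +1 else a
        if opposing not in area_series.columns:
            continue
        y = area_series[opposing].to_numpy(dtype=float)
        t = r.t_end
        if t - w < 0 or t + w >= y.shape[0]:
            continue
        seg = y[t - w:t + w + 1]
        if not np.all(np.isfinite(seg)):
            continue
        rows.append(dict(
            track_id=r.track_id, interface_id=r.interface_id,
            opposing_cell=opposing,
            pre_rate=area_rate(y, frame_interval, t - w, t),
            post_rate=area_rate(y, frame_interval, t, t + w)))
    return pd.DataFrame(rows)
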