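"""Compartment detection by a-trous wavelet correlation, plus tracking.

Detection follows the multiscale-product scheme: the image is expanded
with the B3-spline a-trous wavelet transform into J detail planes W_i;
each plane is thresholded at k times the robust background sigma of
that plane (MAD / 0.6745), the thresholded planes are multiplied into a
correlation image P, a user threshold yields the noise-suppressed image
S, and a pixel belongs to a particle iff

    S > E   and   S > E_[9x9] + 0.5 * Var_[9x9]

with E the global mean of S and E_[9x9] / Var_[9x9] the local 9x9 mean
and population variance.  Connected components of kept pixels become
detections with S-weighted sub-pixel centroids.

Tracking solves per-frame-pair rectangular assignment problems on
squared displacement with birth/death dummy costs, then closes gaps
between track stubs that are within 4 px (0.66 um) and no more than
3 s apart, again by globally optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d, uniform_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import InvalidInputError, InvalidJError

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class WaveletStack:
    planes: list[np.ndarray]
    residual: np.ndarray

    @property
    def J(self) -> int:
        return len(self.planes)

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.planes, axis=0) + self.residual


@dataclass
class ParticleDetection:
    frame: int
    centroid: tuple[float, float]      # (row, col), sub-pixel
    footprint: np.ndarray              # (n, 2) pixel coordinates
    area_px: int
    intensity: float                   # summed raw intensity over footprint


@dataclass
class ParticleTrack:
    track_id: int
    detections: list[ParticleDetection]
    closed_gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def t_start(self) -> int:
        return self.detections[0].frame

    @property
    def t_end(self) -> int:
        return self.detections[-1].frame

    @property
    def lifetime_frames(self) -> int:
        return self.t_end - self.t_start + 1


def _dilated_kernel(level: int) -> np.ndarray:
    """B3 kernel with 2**level - 1 zeros inserted between taps."""
    step = 2 ** level
    k = np.zeros(4 * step + 1)
    k[::step] = _B3
    return k


def atrous_decompose(image: np.ndarray, J: int = 3) -> WaveletStack:
    """Additive a-trous decomposition: sum(planes) + residual == image."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InvalidInputError("image must be 2D")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite values")
    if J < 1:
        raise InvalidJError("J must be >= 1")
    if 4 * 2 ** (J - 1) + 1 > min(img.shape):
        raise InvalidJError(f"J={J} kernel exceeds image size {img.shape}")
    planes = []
    smooth = img
    for i in range(J):
        k = _dilated_kernel(i)
        nxt = correlate1d(smooth, k, axis=0, mode="reflect")
        nxt = correlate1d(nxt, k, axis=1, mode="reflect")
        planes.append(smooth - nxt)
        smooth = nxt
    return WaveletStack(planes, smooth)


def detect_particles(image: np.ndarray, J: int = 3,
                     user_threshold: float | None = None,
                     k_sigma: float = 1.0, k_user: float = 3.0,
                     frame: int = 0,
                     min_area: int = 2) -> list[ParticleDetection]:
    """Wavelet multiscale-product spot detection on one frame.

    The frame is first normalized to zero median and unit robust
    background sigma: the S > E_[9x9] + 0.5 Var_[9x9] rule compares an
    intensity to a variance and is therefore only meaningful at a fixed
    intensity scale.  ``user_threshold`` is the scalar threshold on the
    correlation image; when None it defaults to ``k_user`` times the
    product of the per-plane background sigmas (each plane must, in a
    geometric-mean sense, exceed ``k_user`` sigma for the correlation
    to survive), which suppresses joint noise exceedances.
    """
    img = np.asarray(image, dtype=np.float64)
    med0 = np.median(img)
    mad0 = np.median(np.abs(img - med0)) / 0.6745
    img_n = (img - med0) / max(mad0, 1e-12)
    stack = atrous_decompose(img_n, J)
    prod = np.ones_like(img_n)
    sig_prod = 1.0
    for W in stack.planes:
        med = np.median(W)
        sigma = np.median(np.abs(W - med)) / 0.6745
        sig_prod *= sigma
        prod = prod * np.where(W > k_sigma * sigma, W, 0.0)
    uthr = (k_user ** len(stack.planes)) * sig_prod \
        if user_threshold is None else user_threshold
    S = np.where(prod > uthr, prod, 0.0)
    E = S.mean()
    E9 = uniform_filter(S, size=9, mode="reflect")
    Var9 = uniform_filter(S * S, size=9, mode="reflect") - E9 * E9
    keep = (S > E) & (S > E9 + 0.5 * Var9)
    if not keep.any():
        return []
    comp = cc_label(S > 0, connectivity=2)
    # a support component is a particle candidate iff it contains at
    # least one pixel passing the statistical rules; components holding
    # several well-separated intensity maxima (nearby spots whose
    # supports touch) are split by watershed on the correlation image
    valid = np.unique(comp[keep])
    comp[~np.isin(comp, valid)] = 0
    if comp.max() > 0:
        peaks = peak_local_max(S, min_distance=3, labels=comp,
                               exclude_border=False)
        if peaks.shape[0] > 0:
            markers = np.zeros_like(comp)
            markers[peaks[:, 0], peaks[:, 1]] = np.arange(1,
                                                          peaks.shape[0] + 1)
            split = watershed(-S, markers, mask=comp > 0, connectivity=2)
            unmarked = (comp > 0) & (split == 0)
            split[unmarked] = comp[unmarked] + peaks.shape[0]
            comp = split
    out = []
    for cid in np.unique(comp[comp > 0]):
        foot = np.argwhere(comp == cid)
        if foot.shape[0] < min_area:
            continue
        if not keep[foot[:, 0], foot[:, 1]].any():
            continue
        w = S[foot[:, 0], foot[:, 1]]
        centroid = (foot * w[:, None]).sum(axis=0) / w.sum()
        out.append(ParticleDetection(
            frame=frame,
            centroid=(float(centroid[0]), float(centroid[1])),
            footprint=foot, area_px=int(foot.shape[0]),
            intensity=float(img[foot[:, 0], foot[:, 1]].sum())))
    return out


def detect_movie(stack: np.ndarray, **kwargs) -> list[list[ParticleDetection]]:
    """Run detect_particles on every frame of a (T, H, W) stack."""
    return [detect_particles(stack[t], frame=t, **kwargs)
            for t in range(stack.shape[0])]


_BIG = 1e12


def _frame_assignment(prev: list[ParticleDetection],
                      cur: list[ParticleDetection],
                      max_link_dist: float) -> list[tuple[int, int]]:
    """One-to-one links minimizing total squared displacement."""
    n, m = len(prev), len(cur)
    if n == 0 or m == 0:
        return []
    pa = np.array([p.centroid for p in prev])
    ca = np.array([c.centroid for c in cur])
    d2 = ((pa[:, None, :] - ca[None, :, :]) ** 2).sum(-1)
    link = np.where(d2 <= max_link_dist ** 2, d2, _BIG)
    death = np.full((n, n), _BIG)
    np.fill_diagonal(death, max_link_dist ** 2)
    birth = np.full((m, m), _BIG)
    np.fill_diagonal(birth, max_link_dist ** 2)
    lower_right = np.where(link.T < _BIG, 0.0, _BIG)
    cost = np.block([[link, death], [birth, lower_right]])
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n and c < m and cost[r, c] < _BIG]


def link_tracks(detections_per_frame: list[list[ParticleDetection]],
                frame_interval: float = 1.0,
                max_link_dist: float = 4.0,
                gap_dist: float = 4.0,
                gap_time: float = 3.0) -> list[ParticleTrack]:
    """Frame-to-frame linking followed by stub gap closing.

    Gap closing joins a track end at frame ``te`` to a track start at
    frame ``ts`` iff ``ts - te >= 2`` (at least one missing frame),
    ``(ts - te) * frame_interval <= gap_time`` and the stub endpoints
    are within ``gap_dist`` pixels; conflicts resolve by globally
    optimal squared-distance assignment, iterated until stable.
    """
    tracks: list[list[ParticleDetection]] = []
    open_by_det: dict[int, int] = {}  # index into cur detections -> track idx
    prev: list[ParticleDetection] = []
    for dets in detections_per_frame:
        links = dict()
        if prev and dets:
            links = {c: open_by_det[p]
                     for p, c in _frame_assignment(prev, dets, max_link_dist)
                     if p in open_by_det}
        new_open: dict[int, int] = {}
        for ci, det in enumerate(dets):
            if ci in links:
                tracks[links[ci]].append(det)
                new_open[ci] = links[ci]
            else:
                tracks.append([det])
                new_open[ci] = len(tracks) - 1
        open_by_det = new_open
        prev = dets

    out = [ParticleTrack(i, t) for i, t in enumerate(tracks)]
    out = _close_gaps(out, frame_interval, gap_dist, gap_time)
    for i, tr in enumerate(out):
        tr.track_id = i
    return out


def _close_gaps(tracks: list[ParticleTrack], frame_interval: float,
                gap_dist: float, gap_time: float) -> list[ParticleTrack]:
    while True:
        ends = [(i, t.t_end, np.array(t.detections[-1].centroid))
                for i, t in enumerate(tracks)]
        starts = [(j, t.t_start, np.array(t.detections[0].centroid))
                  for j, t in enumerate(tracks)]
        cand = []
        for ei, (i, te, pe) in enumerate(ends):
            for sj, (j, ts, ps) in enumerate(starts):
                if i == j or ts - te < 2:
                    continue
                if (ts - te) * frame_interval > gap_time:
                    continue
                d = float(np.linalg.norm(pe - ps))
                if d > gap_dist:
                    continue
                cand.append((ei, sj, d * d))
        if not cand:
            return tracks
        eis = sorted({c[0] for c in cand})
        sjs = sorted({c[1] for c in cand})
        cost = np.full((len(eis), len(sjs)), _BIG)
        for ei, sj, c in cand:
            cost[eis.index(ei), sjs.index(sj)] = c
        rows, cols = linear_sum_assignment(cost)
        merges = [(ends[eis[r]][0], starts[sjs[c]][0])
                  for r, c in zip(rows, cols) if cost[r, c] < _BIG]
        if not merges:
            return tracks
        merged_away = set()
        for i, j in merges:
            if i in merged_away or j in merged_away:
                continue  # re-evaluated on the next sweep
            a, b = tracks[i], tracks[j]
            a.closed_gaps.append((a.t_end + 1, b.t_start - 1))
            a.detections.extend(b.detections)
            a.closed_gaps.extend(b.closed_gaps)
            merged_away.add(j)
        tracks = [t for k, t in enumerate(tracks) if k not in merged_away]


def track_lifetimes(tracks: list[ParticleTrack], movie_length: int,
                    frame_interval: float = 1.0,
                    correct: bool = False) -> pd.DataFrame:
    """Lifetime table: (t_end - t_start) + 1 frames, times frame_interval.

    With ``correct=True``, tracks touching the first or last movie frame
    are flagged censored and each complete track receives weight
    1 / (movie_length - lifetime_frames + 1) — the inverse of the number
    of start positions at which it could have been fully observed — so
    the weighted distribution corrects the finite-window bias.
    """
    rows = []
    for tr in tracks:
        lf = tr.lifetime_frames
        censored = tr.t_start == 0 or tr.t_end == movie_length - 1
        w = np.nan
        if correct and not censored:
            w = 1.0 / (movie_length - lf + 1)
        rows.append(dict(track_id=tr.track_id, t_start=tr.t_start,
                         t_end=tr.t_end, lifetime_frames=lf,
                         lifetime_s=lf * frame_interval,
                         censored=censored, weight=w))
    return pd.DataFrame(rows)


def corrected_mean_lifetime(table: pd.DataFrame) -> float:
    """Weighted mean lifetime (s) of the uncensored tracks."""
    d = table[~table.censored]
    if d.empty or not np.isfinite(d.weight).any():
        return float("nan")
    return float((d.lifetime_s * d.weight).sum() / d.weight.sum())
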