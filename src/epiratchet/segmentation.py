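"""Seeded-watershed segmentation, identity tracking and topology counts.

The membrane channel is bright at cell outlines, so cell interiors are
intensity minima: seeds default to the h-minima of the Gaussian-smoothed
image and the watershed floods the smoothed intensity from them,
producing a full label partition (no ridge lines).  Frames are segmented
independently and then linked by maximal pixel overlap, so per-frame
results do not depend on processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.measure import label as cc_label
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .errors import InvalidInputError, NoCellsError, TrackingFailureError
from .geometry import ImagingMetadata, TissueFrame, TrackedTissue


@dataclass(frozen=True)
class SegmentationParams:
    """Watershed parameters.

    ``h_depth`` is the h-minima depth (in intensity units of the
    smoothed image) used to pick one seed per cell interior; a
    ``seed_image`` of nonzero markers overrides seed detection.
    Cells smaller than ``min_area`` pixels are merged into the neighbor
    with the longest shared boundary (ties to the lower id).
    """

    sigma: float = 1.0
    h_depth: float = 0.1
    min_area: int = 20
    seed_image: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")
        if self.min_area < 1:
            raise InvalidInputError("min_area must be >= 1")


def _merge_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Merge regions below min_area into the neighbor sharing the most
    boundary pixels (deterministic: ties break to the lower label)."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_area]
        if small.size == 0:
            return labels
        target = int(small[0])
        mask = labels == target
        # boundary contact counts with each neighbor label
        contact: dict[int, int] = {}
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb = np.roll(labels, shift, axis=ax)
            edge = mask & (nb != target)
            for lab, cnt in zip(*np.unique(nb[edge], return_counts=True)):
                contact[int(lab)] = contact.get(int(lab), 0) + int(cnt)
        contact.pop(0, None)
        if not contact:
            labels[mask] = 0  # isolated speck: discard
            continue
        best = max(contact.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        labels[mask] = best


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    meta: ImagingMetadata | None = None,
    frame_index: int = 0,
) -> TissueFrame:
    """Segment one membrane-channel frame into a TissueFrame."""
    params = params or SegmentationParams()
    meta = meta or ImagingMetadata()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("image must be single-channel 2D")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite values")
    smooth = gaussian_filter(img, params.sigma) if params.sigma > 0 else img
    if params.seed_image is not None:
        markers = np.asarray(params.seed_image)
        if markers.max() == 0:
            raise NoCellsError("seed image contains no markers")
        if markers.dtype == bool or len(np.unique(markers)) <= 2:
            markers = cc_label(markers > 0)
    else:
        minima = h_minima(smooth, params.h_depth)
        if not minima.any():
            raise NoCellsError("no seeds found (flat image?)")
        markers = cc_label(minima)
    labels = watershed(smooth, markers)
    labels = _merge_small(labels, params.min_area)
    if labels.max() == 0:
        raise NoCellsError("segmentation produced no cells")
    return TissueFrame.from_labels(labels, frame_index, meta)


def _relabel(labels: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int64)
    for old, new in mapping.items():
        lut[old] = new
    return lut[labels]


def track_cells(
    frames_or_labels,
    meta: ImagingMetadata | None = None,
) -> TrackedTissue:
    """Link frames by maximal label overlap into a TrackedTissue.

    Accepts a list of TissueFrames or a (T, H, W) label stack.  Cell
    identity is the previous-frame cell with the largest pixel overlap;
    ties break by smaller centroid displacement, then lower id.  A cell
    claimed by two candidates keeps the larger-overlap one and the other
    receives a fresh id.  Interfaces inherit persistence from their cell
    pair, so a T1 exchange ends the old interface id and starts a new one.
    """
    if isinstance(frames_or_labels, np.ndarray):
        meta = meta or ImagingMetadata()
        label_stack = [frames_or_labels[t] for t in range(frames_or_labels.shape[0])]
    else:
        frames_in: list[TissueFrame] = list(frames_or_labels)
        if not frames_in:
            raise InvalidInputError("no frames to track")
        meta = meta or frames_in[0].metadata
        label_stack = [f.label_image for f in frames_in]

    out_frames: list[TissueFrame] = []
    identity_maps: list[dict[int, int]] = []
    next_id = 1
    prev_persistent: np.ndarray | None = None

    for t, labels in enumerate(label_stack):
        labels = np.asarray(labels).astype(np.int64, copy=False)
        cur_ids = [int(i) for i in np.unique(labels) if i != 0]
        mapping: dict[int, int] = {}
        if prev_persistent is None:
            for cid in cur_ids:
                mapping[cid] = next_id
                next_id += 1
        else:
            prev_ids = [int(i) for i in np.unique(prev_persistent) if i != 0]
            if not cur_ids or not prev_ids:
                raise TrackingFailureError(f"empty frame at t={t}")
            # joint histogram of (previous persistent id, current label)
            kmax = int(labels.max()) + 1
            joint = prev_persistent.astype(np.int64) * kmax + labels
            pairs, counts = np.unique(joint[(prev_persistent > 0) & (labels > 0)],
                                      return_counts=True)
            overlap: dict[int, dict[int, int]] = {}
            for p, c in zip(pairs, counts):
                pid, cid = int(p // kmax), int(p % kmax)
                overlap.setdefault(cid, {})[pid] = int(c)
            if not overlap:
                raise TrackingFailureError(
                    f"zero overlap for all cells between frames {t-1} and {t}")
            cent_cur = _centroids(labels)
            cent_prev = _centroids(prev_persistent)
            claims: dict[int, tuple] = {}  # pid -> (count, -disp, -cid, cid)
            choice: dict[int, int] = {}
            for cid in cur_ids:
                cands = overlap.get(cid, {})
                if not cands:
                    continue
                best = None
                for pid, cnt in cands.items():
                    disp = float(np.linalg.norm(cent_cur[cid] - cent_prev[pid]))
                    key = (cnt, -disp, -pid)
                    if best is None or key > best[0]:
                        best = (key, pid)
                choice[cid] = best[1]
            # resolve conflicts: one previous id may be claimed by many
            by_pid: dict[int, list[int]] = {}
            for cid, pid in choice.items():
                by_pid.setdefault(pid, []).append(cid)
            for pid, cids in by_pid.items():
                if len(cids) == 1:
                    mapping[cids[0]] = pid
                    continue
                def rank(cid):
                    disp = float(np.linalg.norm(cent_cur[cid] - cent_prev[pid]))
                    return (overlap[cid][pid], -disp, -cid)
                keep = max(cids, key=rank)
                mapping[keep] = pid
            for cid in cur_ids:
                if cid not in mapping:
                    mapping[cid] = next_id
                    next_id += 1
        persistent = _relabel(labels, mapping)
        identity_maps.append(mapping)
        out_frames.append(TissueFrame.from_labels(persistent, t, meta))
        prev_persistent = persistent

    length_rows, area_rows = {}, {}
    for fr in out_frames:
        length_rows[fr.frame_index] = {
            f"{a}-{b}": rec.length_um
            for (a, b), rec in fr.interfaces.items()}
        area_rows[fr.frame_index] = {
            cid: c.area_um2 for cid, c in fr.cells.items()}
    length_series = pd.DataFrame.from_dict(length_rows, orient="index").sort_index()
    area_series = pd.DataFrame.from_dict(area_rows, orient="index").sort_index()
    length_series = length_series[sorted(length_series.columns)]
    area_series = area_series[sorted(area_series.columns)]
    return TrackedTissue(out_frames, length_series, area_series,
                         identity_maps, meta)


def _centroids(labels: np.ndarray) -> dict[int, np.ndarray]:
    out = {}
    ids = np.unique(labels)
    rr, cc = np.indices(labels.shape)
    for i in ids:
        if i == 0:
            continue
        m = labels == i
        out[int(i)] = np.array([rr[m].mean(), cc[m].mean()])
    return out


def neighbor_distribution(
    tracked: TrackedTissue, sigma_s: float = 5.0,
    ns: tuple[int, ...] = (4, 5, 6, 7, 8),
) -> pd.DataFrame:
    """Per-frame fraction of non-border cells with n neighbors.

    Border-touching cells are excluded (their neighbor count is
    unknown); traces are Gaussian-smoothed in time with sigma given in
    seconds (default 5 s).  Frames with no interior cells yield NaN.
    """
    rows = {}
    for fr in tracked.frames:
        interior = [c for c in fr.cells.values() if not c.touches_border]
        if not interior:
            rows[fr.frame_index] = {n: np.nan for n in ns}
            continue
        counts = np.array([len(c.neighbor_ids) for c in interior])
        rows[fr.frame_index] = {
            n: float((counts == n).mean()) for n in ns}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    sigma_frames = sigma_s / tracked.metadata.frame_interval
    if sigma_frames > 0 and len(df) > 1:
        out = {}
        for n in ns:
            y = df[n].to_numpy(dtype=float)
            m = np.isfinite(y)
            if m.all():
                out[n] = gaussian_filter1d(y, sigma_frames, mode="nearest")
            else:  # normalized convolution around missing frames
                y0 = np.where(m, y, 0.0)
                num = gaussian_filter1d(y0, sigma_frames, mode="nearest")
                den = gaussian_filter1d(m.astype(float), sigma_frames,
                                        mode="nearest")
                s = np.where(den > 0, num / den, np.nan)
                s[~m] = np.nan
                out[n] = s
        df = pd.DataFrame(out, index=df.index)
    return df
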