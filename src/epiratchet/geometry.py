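"""Vertex–interface–cell model of a skeletonized epithelial sheet.

A segmented frame is represented by a label image (0 = background) plus
derived records: cells (area, perimeter, neighbors), vertices (junctions
where three or more regions meet) and interfaces (the shared boundary
between two cells, with its contour pixels, chord length and orientation).

Conventions
-----------
* Coordinates are 0-based ``(row, col)``; vertex positions sit on the
  corner grid between pixels (half-integer coordinates).
* Interface angles are measured from the horizontal image axis
  (the embryo AP axis), counter-clockwise, folded to [0, 180).  A
  vertical interface — one between AP neighbors — reports 90 degrees.
* Interface length is the Euclidean distance between its two endpoint
  vertices times the pixel size; the contour pixels are retained only
  for distance queries (association analysis).
* Lengths are reported in micrometres and areas in squared micrometres,
  with the pixel originals kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import DegenerateInterfaceError, InvalidInputError

APICAL = "APICAL"

AP = "AP"
TRANSVERSE = "transverse"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ImagingMetadata:
    """Physical calibration of a movie.

    Parameters
    ----------
    pixel_size : float
        Micrometres per pixel (default 0.164, a typical spinning-disk
        calibration at 63x).
    frame_interval : float
        Seconds between frames (default 1.0).
    axis_convention : str
        Which image axis is the embryo AP axis; the default
        ``"ap-horizontal"`` means columns run along AP, so the DV axis
        is vertical in the image.
    """

    pixel_size: float = 0.164
    frame_interval: float = 1.0
    axis_convention: str = "ap-horizontal"

    def __post_init__(self):
        if not (self.pixel_size > 0):
            raise InvalidInputError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise InvalidInputError("frame_interval must be > 0")


@dataclass
class CellRecord:
    cell_id: int
    centroid: tuple[float, float]  # (row, col), px
    area_px: float
    area_um2: float
    perimeter_um: float
    neighbor_ids: frozenset[int]
    touches_border: bool


@dataclass
class VertexRecord:
    vertex_id: int
    position: tuple[float, float]  # (row, col), px
    incident_interface_ids: set = field(default_factory=set)


@dataclass
class InterfaceRecord:
    interface_id: tuple[int, int]  # sorted (cell_a, cell_b)
    cell_pair: tuple[int, int]
    vertex_pair: tuple[int, int] | None
    contour_pixels: np.ndarray  # (n, 2) int array, ordered along the chord
    length_px: float
    length_um: float
    angle_deg: float
    interface_class: str = UNCLASSIFIED


def interface_length(v1, v2, meta: ImagingMetadata) -> float:
    """Chord length between two vertex positions, in micrometres."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise InvalidInputError("vertex coordinates must be finite")
    return float(np.hypot(*(v2 - v1)) * meta.pixel_size)


def interface_angle(v1, v2) -> float:
    """Orientation of the segment v1–v2 in degrees, folded to [0, 180).

    Measured counter-clockwise from the horizontal (AP) image axis;
    because rows increase downward, the row difference enters negated.
    Orientation-symmetric: swapping the vertices gives the same angle.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise InvalidInputError("vertex coordinates must be finite")
    dr, dc = v2 - v1
    if dr == 0 and dc == 0:
        raise DegenerateInterfaceError("zero-length interface has no angle")
    theta = math.degrees(math.atan2(-dr, dc)) % 180.0
    return 0.0 if theta >= 180.0 else float(theta)  # fold 180-epsilon rounding


def fold_angle(theta: float) -> float:
    """Fold any angle in degrees to the orientation range [0, 180)."""
    return float(theta % 180.0)


def circular_mean_angle(angles_deg) -> float:
    """Mean of orientations (period 180 degrees) via the doubled-angle trick."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    z = np.exp(2j * np.deg2rad(a))
    return float(np.rad2deg(np.angle(z.mean())) / 2.0 % 180.0)


def _corner_blocks(labels: np.ndarray) -> np.ndarray:
    """4-pixel neighborhoods of every corner-grid point, shape (H+1, W+1, 4)."""
    p = np.pad(labels, 1, mode="constant", constant_values=0)
    return np.stack(
        [p[:-1, :-1], p[:-1, 1:], p[1:, :-1], p[1:, 1:]], axis=-1
    )


def _pair_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class TissueFrame:
    """One segmented frame: label image plus derived geometry records."""

    frame_index: int
    label_image: np.ndarray
    cells: dict[int, CellRecord]
    vertices: dict[int, VertexRecord]
    interfaces: dict[tuple[int, int], InterfaceRecord]
    metadata: ImagingMetadata

    @classmethod
    def from_labels(
        cls, label_image: np.ndarray, frame_index: int = 0,
        meta: ImagingMetadata | None = None,
    ) -> "TissueFrame":
        """Build the full geometry model from an integer label image.

        The label image is a partition of the foreground: each cell a
        positive integer, background 0.  Vertices are detected on the
        corner grid (2x2 pixel blocks containing >= 3 distinct regions,
        background included), 8-connected corner clusters collapsing to
        a single vertex — so 4-fold junctions stay one vertex.
        """
        meta = meta or ImagingMetadata()
        labels = np.asarray(label_image)
        if labels.ndim != 2:
            raise InvalidInputError("label image must be 2D")
        labels = labels.astype(np.int64, copy=False)

        # --- adjacency and interface contour pixels -------------------
        contour: dict[tuple[int, int], set] = {}
        bg_adjacent: set[int] = set()

        def _scan(a_lab, b_lab, a_idx, b_idx):
            diff = a_lab != b_lab
            aa, bb = a_lab[diff], b_lab[diff]
            ai = tuple(x[diff] for x in a_idx)
            bi = tuple(x[diff] for x in b_idx)
            for k in range(aa.size):
                la, lb = int(aa[k]), int(bb[k])
                if la == 0 or lb == 0:
                    bg_adjacent.add(max(la, lb))
                    continue
                key = _pair_key(la, lb)
                s = contour.setdefault(key, set())
                s.add((int(ai[0][k]), int(ai[1][k])))
                s.add((int(bi[0][k]), int(bi[1][k])))

        rr, cc = np.indices(labels.shape)
        _scan(labels[:, :-1], labels[:, 1:],
              (rr[:, :-1], cc[:, :-1]), (rr[:, 1:], cc[:, 1:]))
        _scan(labels[:-1, :], labels[1:, :],
              (rr[:-1, :], cc[:-1, :]), (rr[1:, :], cc[1:, :]))
        bg_adjacent.discard(0)

        # --- vertices on the corner grid ------------------------------
        blocks = _corner_blocks(labels)
        srt = np.sort(blocks, axis=-1)
        ndistinct = 1 + (np.diff(srt, axis=-1) > 0).sum(axis=-1)
        junction = ndistinct >= 3
        vertices: dict[int, VertexRecord] = {}
        vertex_labels: dict[int, set] = {}
        if junction.any():
            comp = cc_label(junction, connectivity=2)
            for vid in range(1, comp.max() + 1):
                ij = np.argwhere(comp == vid)
                pos = ij.mean(axis=0) - 0.5  # corner (i,j) sits at (i-.5, j-.5)
                labset = set()
                for i, j in ij:
                    labset.update(int(x) for x in blocks[i, j])
                vertices[vid] = VertexRecord(vid, (float(pos[0]), float(pos[1])))
                vertex_labels[vid] = labset

        # --- interfaces ----------------------------------------------
        interfaces: dict[tuple[int, int], InterfaceRecord] = {}
        for pair, pixset in contour.items():
            a, b = pair
            cands = [vid for vid, ls in vertex_labels.items()
                     if a in ls and b in ls]
            vpair = None
            if len(cands) >= 2:
                pts = np.array([vertices[v].position for v in cands])
                if len(cands) == 2:
                    vpair = (cands[0], cands[1])
                else:
                    # disjoint shared boundaries are rare; take the most
                    # separated endpoint pair
                    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
                    i, j = np.unravel_index(np.argmax(d), d.shape)
                    vpair = (cands[i], cands[j])
            pix = np.array(sorted(pixset), dtype=np.int64)
            if vpair is not None:
                p1 = np.array(vertices[vpair[0]].position)
                p2 = np.array(vertices[vpair[1]].position)
                axis = p2 - p1
                n = np.linalg.norm(axis)
                if n > 0:
                    order = np.argsort((pix - p1) @ (axis / n))
                    pix = pix[order]
                length_px = float(np.linalg.norm(axis))
                length_um = length_px * meta.pixel_size
                try:
                    ang = interface_angle(p1, p2)
                except DegenerateInterfaceError:
                    ang = float("nan")
            else:
                length_px = float("nan")
                length_um = float("nan")
                ang = float("nan")
            rec = InterfaceRecord(pair, pair, vpair, pix,
                                  length_px, length_um, ang)
            interfaces[pair] = rec
            if vpair is not None:
                for v in vpair:
                    vertices[v].incident_interface_ids.add(pair)

        # --- cells ----------------------------------------------------
        neighbors: dict[int, set] = {}
        for a, b in contour:
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)
        border_touch = set(bg_adjacent)
        edge = np.unique(np.concatenate(
            [labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        border_touch.update(int(x) for x in edge if x != 0)

        cells: dict[int, CellRecord] = {}
        for rp in regionprops(labels):
            cid = int(rp.label)
            cells[cid] = CellRecord(
                cell_id=cid,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                area_px=float(rp.area),
                area_um2=float(rp.area) * meta.pixel_size ** 2,
                perimeter_um=float(rp.perimeter) * meta.pixel_size,
                neighbor_ids=frozenset(neighbors.get(cid, set())),
                touches_border=cid in border_touch,
            )
        return cls(frame_index, labels, cells, vertices, interfaces, meta)

    # -- convenience ------------------------------------------------
    def interface_lengths_um(self) -> dict[tuple[int, int], float]:
        return {k: r.length_um for k, r in self.interfaces.items()}

    def cell_areas_um2(self) -> dict[int, float]:
        return {k: c.area_um2 for k, c in self.cells.items()}


def validate_frame(frame: TissueFrame) -> list[str]:
    """Check every type invariant; returns a list of violation messages."""
    v: list[str] = []
    labels = frame.label_image
    total = labels.size
    fg = sum(c.area_px for c in frame.cells.values())
    bg = int((labels == 0).sum())
    if fg + bg != total:
        v.append(f"areas do not partition the image: {fg}+{bg} != {total}")
    for c in frame.cells.values():
        if not c.area_px > 0:
            v.append(f"cell {c.cell_id}: non-positive area")
        for nb in c.neighbor_ids:
            other = frame.cells.get(nb)
            if other is None or c.cell_id not in other.neighbor_ids:
                v.append(f"adjacency not symmetric: {c.cell_id}<->{nb}")
    for rec in frame.interfaces.values():
        a, b = rec.cell_pair
        ca, cb = frame.cells.get(a), frame.cells.get(b)
        if ca is None or cb is None or b not in ca.neighbor_ids or a not in cb.neighbor_ids:
            v.append(f"interface {rec.interface_id}: cells are not mutual neighbors")
        if rec.vertex_pair is not None:
            p1 = np.array(frame.vertices[rec.vertex_pair[0]].position)
            p2 = np.array(frame.vertices[rec.vertex_pair[1]].position)
            d = float(np.linalg.norm(p2 - p1)) * frame.metadata.pixel_size
            if not math.isclose(d, rec.length_um, rel_tol=1e-9, abs_tol=1e-9):
                v.append(f"interface {rec.interface_id}: stored length "
                         f"{rec.length_um} != vertex distance {d}")
        for (r, c) in rec.contour_pixels:
            if int(labels[r, c]) not in rec.cell_pair:
                v.append(f"interface {rec.interface_id}: contour pixel "
                         f"({r},{c}) not on its cells' boundary")
                break
    for vx in frame.vertices.values():
        labset = set()
        for pair in vx.incident_interface_ids:
            labset.update(pair)
        # interior vertices (no background among incident cells' contours)
        touches_bg = any(frame.cells[c].touches_border
                         for c in labset if c in frame.cells)
        if vx.incident_interface_ids and not touches_bg \
                and len(vx.incident_interface_ids) < 3:
            v.append(f"vertex {vx.vertex_id}: interior vertex with "
                     f"{len(vx.incident_interface_ids)} incident interfaces")
    return v


@dataclass
class TrackedTissue:
    """A time series of TissueFrames under persistent identities.

    ``length_series`` / ``area_series`` are wide DataFrames indexed by
    frame index, one column per persistent interface (``"a-b"`` key) or
    cell; NaN marks frames where the object does not exist.
    """

    frames: list[TissueFrame]
    length_series: pd.DataFrame
    area_series: pd.DataFrame
    identity_maps: list[dict[int, int]]
    metadata: ImagingMetadata

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Serialize all measurements to flat tables (CSV-ready)."""
        cells, interfaces, verts = [], [], []
        for fr in self.frames:
            for c in fr.cells.values():
                cells.append(dict(
                    frame=fr.frame_index, cell_id=c.cell_id,
                    centroid_row=c.centroid[0], centroid_col=c.centroid[1],
                    area_px=c.area_px, area_um2=c.area_um2,
                    perimeter_um=c.perimeter_um,
                    neighbor_ids=";".join(map(str, sorted(c.neighbor_ids))),
                    touches_border=c.touches_border))
            for i in fr.interfaces.values():
                a, b = i.cell_pair
                interfaces.append(dict(
                    frame=fr.frame_index, interface_id=f"{a}-{b}",
                    cell_a=a, cell_b=b,
                    vertex_a=-1 if i.vertex_pair is None else i.vertex_pair[0],
                    vertex_b=-1 if i.vertex_pair is None else i.vertex_pair[1],
                    length_px=i.length_px, length_um=i.length_um,
                    angle_deg=i.angle_deg, interface_class=i.interface_class))
            for vx in fr.vertices.values():
                verts.append(dict(
                    frame=fr.frame_index, vertex_id=vx.vertex_id,
                    row=vx.position[0], col=vx.position[1],
                    n_incident=len(vx.incident_interface_ids)))
        long_len = self.length_series.reset_index(names="frame").melt(
            id_vars="frame", var_name="interface_id",
            value_name="length_um").dropna()
        long_area = self.area_series.reset_index(names="frame").melt(
            id_vars="frame", var_name="cell_id",
            value_name="area_um2").dropna()
        return {
            "cells": pd.DataFrame(cells),
            "interfaces": pd.DataFrame(interfaces),
            "vertices": pd.DataFrame(verts),
            "length_series": long_len,
            "area_series": long_area,
        }


def series_from_long(df: pd.DataFrame, id_col: str, value_col: str) -> pd.DataFrame:
    """Pivot a long (frame, id, value) table back to a wide series."""
    return df.pivot(index="frame", columns=id_col, values=value_col)
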