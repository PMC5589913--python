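"""End-to-end orchestration: segment -> track -> detect -> link ->
associate -> steps -> oscillate -> report.

``run_pipeline`` consumes a ``PipelineConfig`` (optionally read from
YAML), writes every stage's tables under the output directory, and
returns a machine-readable summary of the headline metrics: density
profile and polarity fractions, mean lifetimes by interface class,
step metrics, and oscillation amplitude.  Reruns with the same config
and seed are deterministic; every output carries the config hash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import io as eio
from . import msd as emsd
from . import oscillation as eosc
from . import particles as epart
from . import segmentation as eseg
from . import synth as esynth
from .errors import ConfigError
from .geometry import AP, APICAL, ImagingMetadata, TissueFrame

log = logging.getLogger("epiratchet")


@dataclass
class PipelineConfig:
    """All knobs of a full run.

    Either ``synthetic`` is true (movies generated from ``synth_params``)
    or ``membrane_path`` / ``label_path`` and ``compartment_path`` point
    at TIFF stacks.  ``pixel_size`` / ``frame_interval`` supply metadata
    when the TIFFs carry none.
    """

    output_dir: str = "epiratchet_out"
    seed: int = 0
    synthetic: bool = True
    synth_params: dict = field(default_factory=dict)
    spot_params: dict = field(default_factory=dict)
    membrane_path: str | None = None
    label_path: str | None = None
    compartment_path: str | None = None
    pixel_size: float = 0.164
    frame_interval: float = 1.0
    segmentation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    linking: dict = field(default_factory=dict)
    steps: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = eio.load_config(path)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(cfg) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**cfg)

    def validate(self):
        if not self.synthetic:
            for p in (self.membrane_path or self.label_path,
                      self.compartment_path):
                if p is None:
                    raise ConfigError(
                        "non-synthetic runs need membrane_path or "
                        "label_path, and compartment_path")
                if not Path(p).exists():
                    raise ConfigError(f"input path {p} does not exist")


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = ImagingMetadata(pixel_size=config.pixel_size,
                           frame_interval=config.frame_interval)
    chash = eio.config_hash(asdict(config))
    summary: dict = {"config_hash": chash}

    # --- stage 1: inputs ------------------------------------------------
    if config.synthetic:
        tissue = esynth.synth_tissue(seed=config.seed, **config.synth_params)
        meta = tissue.metadata
        label_movie = tissue.label_movie
        spot_movie, spot_truth = esynth.synth_spot_movie(
            tissue, seed=config.seed + 1, **config.spot_params)
        eio.write_stack(out / "labels.tif", label_movie)
        eio.write_stack(out / "membrane.tif", tissue.membrane_movie)
        eio.write_stack(out / "compartments.tif", spot_movie)
    else:
        if config.label_path:
            label_movie = eio.read_stack(config.label_path).astype(np.int64)
        else:
            membrane = eio.read_stack(config.membrane_path)
            params = eseg.SegmentationParams(**config.segmentation)
            frames = [eseg.segment_frame(membrane[t], params, meta, t)
                      for t in range(membrane.shape[0])]
            label_movie = np.stack([f.label_image for f in frames])
        spot_movie = eio.read_stack(config.compartment_path)

    # --- stage 2: track -------------------------------------------------
    tracked = eseg.track_cells(label_movie, meta)
    log.info("tracked %d frames, %d interfaces, %d cells",
             tracked.n_frames, tracked.length_series.shape[1],
             tracked.area_series.shape[1])
    tables = tracked.to_tables()
    checksums = eio.write_tables(tables, out)

    # --- stage 3: detect + link -----------------------------------------
    dets = epart.detect_movie(spot_movie, **config.detection)
    tracks = epart.link_tracks(dets, meta.frame_interval, **config.linking)
    det_rows = [dict(frame=d.frame, row=d.centroid[0], col=d.centroid[1],
                     area_px=d.area_px, intensity=d.intensity)
                for per in dets for d in per]
    lifetimes = epart.track_lifetimes(tracks, label_movie.shape[0],
                                      meta.frame_interval, correct=True)
    checksums.update(eio.write_tables(
        {"detections": pd.DataFrame(det_rows), "tracks": lifetimes}, out))

    # --- stage 4: associate ----------------------------------------------
    frames_by_index = {f.frame_index: f for f in tracked.frames}
    records = assoc.associate_tracks(tracks, frames_by_index)
    classes = assoc.classify_interfaces(tracked)
    prof = assoc.density_profile(tracked.frames, records)
    events = assoc.pairing_analysis(records)
    pair_freq = assoc.pairing_frequencies(events)
    rec_df = pd.DataFrame([dict(track_id=r.track_id,
                                interface_id=r.interface_id, side=r.side,
                                t_start=r.t_start, t_end=r.t_end,
                                interface_class=classes.get(r.interface_id,
                                                            "apical"))
                           for r in records])
    checksums.update(eio.write_tables(
        {"associations": rec_df, "density": prof.per_frame.reset_index()},
        out))
    by_class = {}
    if not rec_df.empty:
        for cls, grp in rec_df.groupby("interface_class"):
            by_class[cls] = float(
                (grp.t_end - grp.t_start + 1).mean() * meta.frame_interval)

    # --- stage 5: steps on AP interface lengths ---------------------------
    ap_keys = [k for k, v in classes.items() if v == AP]
    annotations = {}
    step_cfg = dict(config.steps)
    for key in ap_keys:
        y = tracked.length_series[key].to_numpy(dtype=float)
        m = np.isfinite(y)
        if m.sum() < emsd.DEFAULT_WINDOWS[0]:
            continue
        traj = emsd.Trajectory(y[m], meta.frame_interval, key)
        gamma = emsd.rolling_gamma(traj)
        annotations[key] = emsd.detect_steps(traj, gamma, **step_cfg)
    step_summary = {}
    if annotations:
        metrics = emsd.step_metrics(annotations)
        step_summary = dict(
            n_interfaces=len(annotations),
            mean_frequency_per_min=float(metrics.frequency_per_min.mean()),
            mean_duration_s=float(np.nanmean(metrics.mean_duration_s)),
            mean_net_displacement=float(metrics.net_displacement.mean()))
        checksums.update(eio.write_tables(
            {"steps": metrics.drop(columns="displacements").reset_index()},
            out))

    # --- stage 6: oscillation ---------------------------------------------
    interior = [c for f in tracked.frames for c, rec in f.cells.items()
                if not rec.touches_border]
    keep = [c for c in tracked.area_series.columns if c in set(interior)]
    osc = assoc_amp = None
    if keep:
        osc = eosc.cell_oscillation_amplitudes(
            tracked.area_series[keep], meta.frame_interval)
        if not osc.empty:
            assoc_amp = float(osc.mean_amplitude_pct.mean())
            checksums.update(eio.write_tables({"oscillations": osc}, out))

    summary.update(
        n_frames=int(label_movie.shape[0]),
        n_cells=int(tracked.area_series.shape[1]),
        n_interfaces=int(tracked.length_series.shape[1]),
        n_tracks=len(tracks),
        density_time_averaged=prof.time_averaged,
        vertical_fraction=prof.vertical_fraction,
        horizontal_fraction=prof.horizontal_fraction,
        pairing=pair_freq,
        mean_lifetime_by_class_s=by_class,
        steps=step_summary,
        mean_oscillation_amplitude_pct=assoc_amp,
        checksums=checksums,
    )
    eio.write_summary(out / "summary.json", summary)
    return summary
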