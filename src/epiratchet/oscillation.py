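"""Apical-area oscillation amplitude and windowed rate analytics.

Oscillation amplitude follows the analytic-signal route: the area
series is smoothed with a Savitzky-Golay filter (order 3, window 81
frames), detrended by subtracting a long-timescale Gaussian filtered
(sigma = 200 s) version of itself — the "local average area" — and the
Hilbert envelope of the detrended signal, divided by the local average,
gives the instantaneous amplitude as a percentage of cell area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert, savgol_filter

from .errors import (InvalidInputError, InvalidIntervalError,
                     InvalidWindowError, NumericDomainError)


@dataclass
class OscillationResult:
    amplitude_pct: np.ndarray      # instantaneous amplitude, % of local area
    mean_amplitude_pct: float      # per-cell average over the time course
    local_average_area: np.ndarray  # the sigma = 200 s trend


def smooth_and_detrend(area: np.ndarray, frame_interval: float,
                       sg_order: int = 3, sg_window: int = 81,
                       trend_sigma_s: float = 200.0):
    """Savitzky-Golay smoothing plus Gaussian detrending.

    Returns ``(filtered, detrended, trend)``.  If the series is shorter
    than ``sg_window`` the window shrinks to the largest odd length
    <= N, with a warning.  The trend filter uses reflected boundaries.
    """
    y = np.asarray(area, dtype=float)
    if y.ndim != 1 or y.shape[0] < 3:
        raise InvalidInputError("area series must be 1D with >= 3 samples")
    N = y.shape[0]
    win = sg_window
    if win > N:
        win = N if N % 2 == 1 else N - 1
        warnings.warn(
            f"series length {N} < window {sg_window}; shrinking to {win}",
            stacklevel=2)
    if win <= sg_order:
        raise InvalidInputError("window must exceed polynomial order")
    filtered = savgol_filter(y, win, sg_order)
    sigma_frames = trend_sigma_s / frame_interval
    trend = gaussian_filter1d(filtered, sigma_frames, mode="reflect")
    return filtered, filtered - trend, trend


def instantaneous_amplitude(detrended: np.ndarray, trend: np.ndarray,
                            frame_interval: float = 1.0,
                            mirror_pad: int | None = None) -> OscillationResult:
    """Hilbert-envelope amplitude as a percentage of the local area.

    The detrended signal is mirror-padded (default: 81 samples, capped
    at N-1) before the analytic-signal transform to tame edge
    transients, then cropped back.
    """
    det = np.asarray(detrended, dtype=float)
    tr = np.asarray(trend, dtype=float)
    if det.shape != tr.shape:
        raise InvalidInputError("detrended and trend must be aligned")
    if np.any(tr <= 0):
        raise NumericDomainError("trend must be positive everywhere")
    N = det.shape[0]
    pad = min(N - 1, 81 if mirror_pad is None else mirror_pad)
    padded = np.concatenate([det[pad:0:-1], det, det[-2:-2 - pad:-1]]) \
        if pad > 0 else det
    env = np.abs(hilbert(padded))
    if pad > 0:
        env = env[pad:pad + N]
    amp = env / tr * 100.0
    return OscillationResult(amp, float(np.mean(amp)), tr)


def cell_oscillation_amplitudes(area_series: pd.DataFrame,
                                frame_interval: float,
                                **kwargs) -> pd.DataFrame:
    """Mean oscillation amplitude (%) per cell column of a wide table."""
    rows = []
    for cid in area_series.columns:
        y = area_series[cid].to_numpy(dtype=float)
        m = np.isfinite(y)
        if m.sum() < 5:
            continue
        y = y[m]
        _, det, tr = smooth_and_detrend(y, frame_interval, **kwargs)
        res = instantaneous_amplitude(det, tr, frame_interval)
        rows.append(dict(cell_id=cid,
                         mean_amplitude_pct=res.mean_amplitude_pct,
                         n_frames=int(m.sum())))
    return pd.DataFrame(rows)


def area_rate(area: np.ndarray, frame_interval: float,
              t_start: int, t_end: int) -> float:
    """Normalized rate of area change over [t_start, t_end] (frames).

    (area(t_end) - area(t_start)) / (t_end - t_start), divided by the
    mean area over the window — a unitless per-second rate.
    """
    y = np.asarray(area, dtype=float)
    if not (0 <= t_start < t_end < y.shape[0]):
        raise InvalidWindowError(
            f"window [{t_start}, {t_end}] invalid for series of {y.shape[0]}")
    seg = y[t_start:t_end + 1]
    dt_s = (t_end - t_start) * frame_interval
    return float((y[t_end] - y[t_start]) / dt_s / np.nanmean(seg))


def ventral_furrow_summary(area_series: pd.DataFrame,
                           frame_interval: float,
                           duration_s: float = 6.6 * 60.0):
    """Normalized constriction trajectories and per-cell rates.

    Each cell's area series is normalized to 100% at t = 0; the mean
    trajectory with its standard error is returned together with the
    per-cell rate (final - initial %) / duration and its mean +/- SE.
    Cells missing the t = 0 sample are excluded.
    """
    n_frames = int(round(duration_s / frame_interval)) + 1
    n_frames = min(n_frames, len(area_series))
    trajs, excluded = [], []
    for cid in area_series.columns:
        y = area_series[cid].to_numpy(dtype=float)[:n_frames]
        if y.shape[0] < n_frames or not np.isfinite(y[0]) or y[0] <= 0:
            excluded.append(cid)
            continue
        trajs.append(y / y[0] * 100.0)
    if not trajs:
        raise InvalidInputError("no cell spans the requested duration")
    arr = np.vstack(trajs)
    mean = np.nanmean(arr, axis=0)
    se = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(arr.shape[0]) \
        if arr.shape[0] > 1 else np.zeros(n_frames)
    T = (n_frames - 1) * frame_interval
    rates = (arr[:, -1] - arr[:, 0]) / T  # % per second
    summary = dict(
        mean_pct=mean, se_pct=se,
        rate_mean=float(np.mean(rates)),
        rate_se=float(np.std(rates, ddof=1) / np.sqrt(rates.size))
        if rates.size > 1 else 0.0,
        n_cells=arr.shape[0], excluded=excluded,
        time_s=np.arange(n_frames) * frame_interval,
    )
    return summary


def interface_rate_windows(lengths: np.ndarray, frame_interval: float,
                           t_start: int, t_end: int,
                           window_s: float = 30.0):
    """Interface contraction rates before/during/after a compartment.

    during = [L(t_end) - L(t_start)] / (t_end - t_start); the pre and
    post rates use a ``window_s`` span immediately before t_start and
    after t_end, clipped to the series with a ``truncated`` flag.
    Returns dict with keys pre/during/post (um/s, negative =
    contraction) and pre_truncated/post_truncated.
    """
    y = np.asarray(lengths, dtype=float)
    N = y.shape[0]
    if not (0 <= t_start < t_end < N):
        raise InvalidIntervalError(
            f"interval [{t_start}, {t_end}] outside series of {N}")
    w = int(round(window_s / frame_interval))

    def rate(i0, i1):
        if i1 <= i0:
            return np.nan
        return float((y[i1] - y[i0]) / ((i1 - i0) * frame_interval))

    pre0 = max(0, t_start - w)
    post1 = min(N - 1, t_end + w)
    return dict(
        pre=rate(pre0, t_start),
        during=rate(t_start, t_end),
        post=rate(t_end, post1),
        pre_truncated=pre0 != t_start - w,
        post_truncated=post1 != t_end + w,
    )
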