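"""MSD decomposition and rolling-window step detection.

The mean squared displacement of an interface-length trajectory l(k*dt),

    MSD(n*dt) = 1/(N-n) * sum_k [ l((k+n)*dt) - l(k*dt) ]^2 ,

is decomposed by least squares into a confined, a diffusive and an
active component,

    MSD(tau) = A (1 - exp(-alpha tau)) + 2 B tau + C^2 tau^2 ,

with A the confinement amplitude (um^2), alpha the relaxation rate
(1/s), B the diffusion coefficient (um^2/s) and C the active speed
(um/s).  Active periods ("steps") are found from the local log-log MSD
slope gamma(t), computed in centered rolling windows of 21, 41, 61 and
81 frames; within each window the slope is fit over lags 5 .. 3(W-1)/4
(the first four lags are excluded because localization error produces
artifactual subdiffusion there), the maximum over window sizes is kept,
and contiguous runs of gamma > 1 lasting at least 14 frames are steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import medfilt

from .errors import FitFailureError, InvalidInputError, InvalidLagError

DEFAULT_WINDOWS = (21, 41, 61, 81)


@dataclass
class Trajectory:
    """Uniformly sampled scalar or 2D trajectory; NaN marks missing frames."""

    values: np.ndarray  # (N,) scalar or (N, 2) positions
    frame_interval: float = 1.0
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] < 2:
            raise InvalidInputError("trajectory needs >= 2 samples")
        if self.frame_interval <= 0:
            raise InvalidInputError("frame_interval must be > 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MSDCurve:
    lags: np.ndarray       # seconds, starting at 0
    msd: np.ndarray
    counts: np.ndarray     # valid displacement pairs per lag


@dataclass
class MSDFit:
    A: float
    alpha: float
    B: float
    C: float
    residual: float
    lag_range: tuple[int, int]

    def model(self, tau: np.ndarray) -> np.ndarray:
        return msd_model(tau, self.A, self.alpha, self.B, self.C)


@dataclass
class StepAnnotation:
    gamma_series: np.ndarray
    active_mask: np.ndarray
    steps: list = field(default_factory=list)  # (start, end, duration_s, disp)
    frame_interval: float = 1.0


def _sq_disp(values: np.ndarray, n: int) -> np.ndarray:
    d = values[n:] - values[:-n]
    if d.ndim == 2:
        return np.einsum("ij,ij->i", d, d)
    return d * d


def compute_msd(traj: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all start times, lag 0 .. max_lag frames."""
    N = traj.n
    if max_lag is None:
        max_lag = N - 1
    if max_lag >= N:
        raise InvalidLagError(f"max_lag {max_lag} >= N {N}")
    if max_lag < 1:
        raise InvalidLagError("max_lag must be >= 1")
    msd = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = N
    for n in range(1, max_lag + 1):
        sq = _sq_disp(traj.values, n)
        ok = np.isfinite(sq)
        counts[n] = int(ok.sum())
        msd[n] = float(np.mean(sq[ok])) if counts[n] else np.nan
    lags = np.arange(max_lag + 1) * traj.frame_interval
    return MSDCurve(lags, msd, counts)


def msd_model(tau, A, alpha, B, C):
    return A * (1.0 - np.exp(-alpha * tau)) + 2.0 * B * tau + C ** 2 * tau ** 2


def fit_msd(curve: MSDCurve, lag_range: tuple[int, int] | None = None,
            n_starts: int = 8, alpha_min_factor: float = 3.0) -> MSDFit:
    """Nonnegative least-squares fit of the three-component MSD model.

    Least squares is taken on relative residuals (model/data - 1):
    time-averaged MSD estimates carry multiplicative sampling error, so
    relative weighting keeps the short-lag region — where the three
    components are identifiable — from being swamped by the large
    absolute values at long lags.  Multi-start over a log-spaced grid
    of relaxation rates; best residual wins.  By default fits lags
    1 .. floor(n_lags/4) of the curve, configurable through
    ``lag_range`` (inclusive frame-lag indices).

    The relaxation rate is bounded below at ``alpha_min_factor / tau_max``
    (default 3, i.e. the confined term must be ~95% saturated by the end
    of the fitted range).  A slower exponential never reaches its
    plateau within the data and is then indistinguishable from the
    diffusive term — the unconstrained fit lets a huge-A, tiny-alpha
    confined term absorb the diffusive slope of noisy curves.
    """
    n_lags = len(curve.lags) - 1
    if lag_range is None:
        lag_range = (1, max(5, n_lags // 4))
    lo, hi = lag_range
    hi = min(hi, n_lags)
    sel = slice(lo, hi + 1)
    tau = curve.lags[sel]
    y = curve.msd[sel]
    ok = np.isfinite(y)
    tau, y = tau[ok], y[ok]
    if tau.size < 5:
        raise InvalidInputError("need >= 5 lag points to fit the MSD model")

    tmax = tau[-1]
    yspan = max(float(y.max()), 1e-30)
    A0 = float(np.median(y))
    B0 = max(float(y[0] / (2.0 * tau[0])), 1e-30)
    C0 = float(np.sqrt(yspan) / tmax)

    scale = np.maximum(np.abs(y), 1e-30)

    def resid(p):
        A, alpha, B, C = p
        return (msd_model(tau, A, alpha, B, C) - y) / scale

    best = None
    diagnostics = []
    alpha_min = alpha_min_factor / tmax
    alphas = np.geomspace(alpha_min * 1.01, 50.0 / tmax, n_starts)
    for a0 in alphas:
        x0 = [A0, a0, B0, C0]
        try:
            sol = least_squares(resid, x0,
                                bounds=([0, alpha_min, 0, 0],
                                        [np.inf] * 4), method="trf")
        except Exception as e:  # pragma: no cover - scipy internal failure
            diagnostics.append((x0, str(e)))
            continue
        if not sol.success:
            diagnostics.append((x0, sol.message))
        if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitFailureError("MSD fit did not converge from any start",
                              diagnostics)
    A, alpha, B, C = best.x
    return MSDFit(float(A), float(alpha), float(B), float(C),
                  float(np.sqrt(2 * best.cost)), (lo, hi))


def _window_gamma(values: np.ndarray, W: int, dt: float) -> np.ndarray:
    """log-log MSD slope for every centered window of W frames.

    Returns an array aligned to the trajectory (NaN where the window
    does not fit).  Vectorized: for each lag, windowed sums of squared
    displacements come from a cumulative sum; the OLS slope over the
    fixed log-lag design is then evaluated for all centers at once.
    """
    N = values.shape[0]
    out = np.full(N, np.nan)
    if W > N:
        return out
    h = W // 2
    L = 3 * (W - 1) // 4
    lags = np.arange(5, L + 1)
    if lags.size < 2:
        return out
    centers = np.arange(h, N - h)
    logmsd = np.empty((lags.size, centers.size))
    for i, n in enumerate(lags):
        sq = _sq_disp(values, n)          # index k -> pair (k, k+n)
        cs = np.concatenate(([0.0], np.cumsum(sq)))
        # pairs fully inside window [t-h, t+h]: k in [t-h, t+h-n]
        m = W - n                          # pairs per window
        starts = centers - h
        msd = (cs[starts + m] - cs[starts]) / m
        logmsd[i] = np.log(np.maximum(msd, np.finfo(float).tiny))
    x = np.log(lags * dt)
    xc = x - x.mean()
    denom = float(xc @ xc)
    slope = (xc @ logmsd) / denom
    out[centers] = slope
    return out


def rolling_gamma(traj: Trajectory,
                  windows: tuple[int, ...] = DEFAULT_WINDOWS) -> np.ndarray:
    """gamma(t): max over window sizes of the local log-log MSD slope."""
    windows = tuple(sorted(int(w) for w in windows))
    if any(w % 2 == 0 for w in windows):
        raise InvalidInputError("window sizes must be odd")
    if traj.n < windows[0]:
        raise InvalidInputError(
            f"trajectory ({traj.n}) shorter than smallest window {windows[0]}")
    stacked = [
        _window_gamma(traj.values, W, traj.frame_interval)
        for W in windows if W <= traj.n
    ]
    g = np.vstack(stacked)
    out = np.full(g.shape[1], np.nan)
    has = ~np.all(np.isnan(g), axis=0)
    if has.any():
        out[has] = np.nanmax(g[:, has], axis=0)
    return out


def detect_steps(traj: Trajectory, gamma_series: np.ndarray,
                 threshold: float = 1.0, min_duration: int = 14,
                 median_order: int = 5) -> StepAnnotation:
    """Contiguous gamma > threshold runs of >= min_duration frames.

    Displacements are read from the median-filtered trajectory at the
    run endpoints (signed; negative = contraction).  For 2D input the
    scalar displacement is the Euclidean norm of the endpoint offset.
    """
    gamma_series = np.asarray(gamma_series, dtype=float)
    if gamma_series.shape[0] != traj.n:
        raise InvalidInputError("gamma series not aligned to trajectory")
    vals = traj.values
    if vals.ndim == 1:
        filt = medfilt(vals, kernel_size=median_order)
    else:
        filt = np.column_stack([
            medfilt(vals[:, j], kernel_size=median_order)
            for j in range(vals.shape[1])])
    active = np.zeros(traj.n, dtype=bool)
    steps = []
    mask = np.where(np.isfinite(gamma_series),
                    gamma_series > threshold, False)
    t = 0
    N = traj.n
    while t < N:
        if not mask[t]:
            t += 1
            continue
        start = t
        while t < N and mask[t]:
            t += 1
        end = t - 1
        if end - start + 1 >= min_duration:
            if filt.ndim == 1:
                disp = float(filt[end] - filt[start])
            else:
                disp = float(np.linalg.norm(filt[end] - filt[start]))
            steps.append((start, end,
                          (end - start + 1) * traj.frame_interval, disp))
            active[start:end + 1] = True
    return StepAnnotation(gamma_series, active, steps, traj.frame_interval)


def step_metrics(annotations: dict[str, StepAnnotation]) -> pd.DataFrame:
    """Per-trajectory step statistics.

    frequency_per_min: steps per minute of trajectory time;
    mean_duration_s: mean step duration; net_displacement: sum of the
    signed step displacements (the ratchet readout — strongly negative
    for progressive contraction, near zero for reversing dynamics).
    """
    if not annotations:
        raise InvalidInputError("need at least one annotated trajectory")
    rows = []
    for key, ann in annotations.items():
        T = ann.active_mask.shape[0] * ann.frame_interval
        n = len(ann.steps)
        durs = [s[2] for s in ann.steps]
        disps = [s[3] for s in ann.steps]
        rows.append(dict(
            trajectory=key, n_steps=n,
            frequency_per_min=n / (T / 60.0),
            mean_duration_s=float(np.mean(durs)) if durs else np.nan,
            net_displacement=float(np.sum(disps)) if disps else 0.0,
            displacements=disps,
        ))
    return pd.DataFrame(rows).set_index("trajectory")
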