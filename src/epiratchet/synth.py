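"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

Three families of generators:

* **Trajectories** — interface-length / position time series composed of
  a mean-reverting confined component (stationary MSD plateau A), a
  Brownian component (diffusion coefficient B), piecewise-ballistic
  active runs (speed C) and i.i.d. localization noise; and staircase
  length trajectories with discrete contraction steps, in a progressive
  ("control") or sign-alternating ("ratchet_off") regime.

* **Tissue** — a running-bond polygonal lattice whose vertical joints
  are the AP interfaces, evolved kinematically with prescribed stepped
  joint-length dynamics and rendered as a label movie plus a noisy
  membrane movie.  Near-horizontal zigzag segments between rows are the
  transverse interfaces.

* **Spots** — compartment movies: Gaussian spots placed on interface
  contours (a prescribed fraction on vertical interfaces), with drawn
  lifetimes, grow-then-shrink intensity profiles and Gaussian noise at
  a target SNR (peak amplitude over background sigma).

Identical seed and parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes, distance_transform_edt, gaussian_filter
from skimage.draw import polygon as draw_polygon

from .errors import ParameterError
from .geometry import ImagingMetadata

# ---------------------------------------------------------------------------
# trajectory generators
# ---------------------------------------------------------------------------


def synth_trajectories(A: float = 0.0, alpha: float = 0.05,
                       B: float = 0.0, C: float = 0.0,
                       noise_sigma: float = 0.0,
                       n: int = 1, n_frames: int = 500,
                       frame_interval: float = 1.0,
                       active_runs=None,
                       seed: int = 0):
    """Confined + diffusive + active trajectories with known components.

    The confined part is a discrete Ornstein-Uhlenbeck process with
    stationary variance A/2 and relaxation rate alpha, so its MSD is
    A (1 - exp(-alpha tau)).  The Brownian part has per-step variance
    2 B dt (MSD 2 B tau).  ``active_runs`` is either None, a list of
    ``(start, end, sign)`` runs applied to every trajectory, or a list
    of such lists (one per trajectory); during a run the trajectory
    drifts at ``sign * C`` um/s.  Returns ``(values, active_mask)`` of
    shape (n, n_frames).
    """
    rng = np.random.default_rng(seed)
    dt = frame_interval
    out = np.zeros((n, n_frames))
    if A > 0:
        phi = np.exp(-alpha * dt)
        s_eq = np.sqrt(A / 2.0)
        x = rng.normal(0.0, s_eq, size=n)
        ou = np.empty((n, n_frames))
        ou[:, 0] = x
        innov_sd = s_eq * np.sqrt(1.0 - phi ** 2)
        for t in range(1, n_frames):
            x = phi * x + rng.normal(0.0, innov_sd, size=n)
            ou[:, t] = x
        out += ou
    if B > 0:
        inc = rng.normal(0.0, np.sqrt(2.0 * B * dt), size=(n, n_frames - 1))
        out[:, 1:] += np.cumsum(inc, axis=1)
    mask = np.zeros((n, n_frames), dtype=bool)
    if active_runs is not None and C > 0:
        per_traj = active_runs
        if per_traj and not isinstance(per_traj[0], (list, tuple)) \
                or (per_traj and isinstance(per_traj[0], tuple)):
            pass
        if per_traj and isinstance(per_traj[0], tuple):
            per_traj = [active_runs] * n
        for i, runs in enumerate(per_traj):
            for (s, e, sign) in runs:
                L = e - s + 1
                ramp = sign * C * dt * np.arange(1, L + 1)
                out[i, s:e + 1] += ramp
                out[i, e + 1:] += ramp[-1]
                mask[i, s:e + 1] = True
    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma, size=out.shape)
    return out, mask


def random_active_runs(n: int, n_frames: int, run_len: int = 20,
                       n_runs: int = 2, margin: int = 45,
                       seed: int = 0):
    """Non-overlapping active runs per trajectory, margin frames apart."""
    rng = np.random.default_rng(seed)
    all_runs = []
    for _ in range(n):
        runs, tries = [], 0
        while len(runs) < n_runs and tries < 500:
            tries += 1
            s = int(rng.integers(margin, n_frames - run_len - margin))
            e = s + run_len - 1
            if all(e + margin < s2 or s > e2 + margin for s2, e2, _ in runs):
                sign = 1 if rng.random() < 0.5 else -1
                runs.append((s, e, sign))
        all_runs.append(sorted(runs))
    return all_runs


def _step_schedule(rng, n_frames: int, mode: str, n_steps: int,
                   step_size: float, dur_range=(16, 26),
                   pause_range=(45, 80)):
    """Piecewise-linear staircase profile and its true step list."""
    profile = np.zeros(n_frames)
    steps = []
    t = int(rng.integers(*pause_range))
    level = 0.0
    sign = -1
    for _ in range(n_steps):
        dur = int(rng.integers(*dur_range))
        if t + dur + 5 >= n_frames:
            break
        disp = sign * step_size
        ramp = level + (np.arange(1, dur + 1) / dur) * disp
        profile[t:t + dur] = ramp
        profile[t + dur:] = level + disp
        steps.append((t, t + dur - 1, disp))
        level += disp
        t += dur + int(rng.integers(*pause_range))
        if mode == "ratchet_off":
            sign = -sign
    return profile, steps


def synth_step_lengths(mode: str = "control", n: int = 50,
                       n_frames: int = 450, frame_interval: float = 1.0,
                       l0: float = 10.0, step_size: float = 1.0,
                       n_steps: int = 4, noise_sigma: float = 0.05,
                       dur_range=(16, 26), pause_range=(45, 80),
                       seed: int = 0):
    """Staircase interface-length trajectories (um) with step truth.

    control: every step contracts by ``step_size``; ratchet_off: steps
    alternate sign (contract, re-lengthen, ...) so the net stepped
    displacement is near zero while per-step size and timing statistics
    match the control regime.  Returns ``(lengths, truth)`` where truth
    is a list (per trajectory) of ``(start, end, displacement)`` tuples.
    """
    if mode not in ("control", "ratchet_off"):
        raise ParameterError(f"unknown mode {mode!r}")
    if l0 - n_steps * step_size <= 0:
        raise ParameterError("steps would drive the length negative")
    rng = np.random.default_rng(seed)
    lengths = np.empty((n, n_frames))
    truth = []
    for i in range(n):
        prof, steps = _step_schedule(rng, n_frames, mode, n_steps,
                                     step_size, dur_range, pause_range)
        lengths[i] = l0 + prof
        truth.append(steps)
    if noise_sigma > 0:
        lengths += rng.normal(0.0, noise_sigma, size=lengths.shape)
    return lengths, truth


def synth_area_series(n_cells: int = 100, n_frames: int = 1200,
                      frame_interval: float = 1.0,
                      baseline: float = 100.0,
                      amplitude_pct: float = 5.0,
                      period_s: float = 120.0,
                      noise_sigma: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Sinusoidally oscillating apical-area series with random phases.

    area_i(t) = A0_i (1 + a/100 sin(2 pi t / T + phi_i)); baselines are
    jittered +/-20% so scale invariance is actually exercised.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    data = {}
    for i in range(n_cells):
        a0 = baseline * rng.uniform(0.8, 1.2)
        phi = rng.uniform(0, 2 * np.pi)
        y = a0 * (1.0 + amplitude_pct / 100.0
                  * np.sin(2 * np.pi * t / period_s + phi))
        if noise_sigma > 0:
            y = y + rng.normal(0.0, noise_sigma, size=n_frames)
        data[i] = y
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# tissue generator
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTissue:
    """Rendered lattice movie plus complete ground truth."""

    label_movie: np.ndarray          # (T, H, W) int32
    membrane_movie: np.ndarray       # (T, H, W) float32
    metadata: ImagingMetadata
    mode: str
    seed: int
    joint_length_px: pd.DataFrame    # frames x vertical-joint key "r,k"
    joint_pair: dict                 # joint key -> "a-b" brick-pair key
    joint_segments: dict             # joint key -> (T, 2, 2) endpoints
    transverse_segments: dict        # seg key -> ((T,2,2) endpoints, "a-b")
    steps: dict                      # joint key -> [(start, end, disp_um)]
    areas_px2: pd.DataFrame          # frames x brick id (shoelace, exact)

    @property
    def n_frames(self) -> int:
        return self.label_movie.shape[0]


def _shoelace(poly: np.ndarray) -> float:
    r, c = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def synth_tissue(mode: str = "control", n_rows: int = 6, n_joint_cols: int = 8,
                 n_frames: int = 240, frame_interval: float = 1.0,
                 pixel_size: float = 0.164,
                 brick_w: int = 30, brick_h: int = 44,
                 l0_frac: float = 0.75,
                 amplitude_pct: float = 0.0, period_s: float = 120.0,
                 n_steps: int = 3, step_size_um: float = 1.0,
                 membrane_noise: float = 0.1,
                 furrow_final_frac: float = 0.5,
                 seed: int = 0) -> SyntheticTissue:
    """Render a brick-lattice epithelium with prescribed joint dynamics.

    modes: ``static`` (frozen geometry), ``control`` (vertical joints
    contract in discrete negative steps with pauses), ``ratchet_off``
    (steps alternate sign), ``furrow`` (global radial contraction of
    the lattice to ``furrow_final_frac`` linear scale over the movie,
    emulating apical constriction).  ``amplitude_pct`` adds sinusoidal
    joint-length modulation with random phases, which makes cell areas
    oscillate; truth areas are the exact polygon areas per frame.
    """
    if mode not in ("static", "control", "ratchet_off", "furrow"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    R, K = n_rows, n_joint_cols
    Wb, Hb = float(brick_w), float(brick_h)
    l0 = l0_frac * Hb
    x0, y0 = Wb, Hb * 0.5
    H_img = int(np.ceil(2 * y0 + R * Hb))
    W_img = int(np.ceil(2 * x0 + (K + 0.5) * Wb))
    step_px = step_size_um / pixel_size
    if mode == "control" and l0 - n_steps * step_px < 0.12 * Hb:
        raise ParameterError("step schedule would collapse the joints")

    def jx(r, k):
        return x0 + (k + 0.5 * (r % 2)) * Wb

    def cy(r):
        return y0 + (r + 0.5) * Hb

    n_bricks_per_row = K - 1

    def bid(r, k):
        return r * n_bricks_per_row + k + 1

    # joint length profiles -------------------------------------------------
    joint_keys = [(r, k) for r in range(R) for k in range(K)]
    interior = [(r, k) for (r, k) in joint_keys if 1 <= k <= K - 2]
    lengths = {}
    steps: dict = {}
    for key in joint_keys:
        base = np.full(n_frames, l0)
        if mode in ("control", "ratchet_off") and key in interior:
            prof, st = _step_schedule(rng, n_frames, mode, n_steps, step_px)
            base = base + prof
            steps[key] = [(s, e, d * pixel_size) for (s, e, d) in st]
        if amplitude_pct > 0:
            phi = rng.uniform(0, 2 * np.pi)
            t = np.arange(n_frames) * frame_interval
            base = base * (1.0 + amplitude_pct / 100.0
                           * np.sin(2 * np.pi * t / period_s + phi))
        if np.any(base <= 0):
            raise ParameterError("joint length went non-positive")
        lengths[key] = base
    scale = np.ones(n_frames)
    if mode == "furrow":
        scale = np.linspace(1.0, furrow_final_frac, n_frames)
    ctr = np.array([H_img / 2.0, W_img / 2.0])

    def pt(row, col, t):
        p = np.array([row, col])
        return ctr + (p - ctr) * scale[t]

    # geometry per frame ----------------------------------------------------
    label_movie = np.zeros((n_frames, H_img, W_img), dtype=np.int32)
    membrane_movie = np.zeros((n_frames, H_img, W_img), dtype=np.float32)
    joint_segments = {k: np.zeros((n_frames, 2, 2)) for k in joint_keys}
    trans_segments: dict = {}
    areas = np.zeros((n_frames, R * n_bricks_per_row))

    for t in range(n_frames):
        frame = np.zeros((H_img, W_img), dtype=np.int32)
        for (r, k) in joint_keys:
            l = lengths[(r, k)][t]
            joint_segments[(r, k)][t, 0] = pt(cy(r) - l / 2, jx(r, k), t)
            joint_segments[(r, k)][t, 1] = pt(cy(r) + l / 2, jx(r, k), t)
        for r in range(R):
            for k in range(n_bricks_per_row):
                kp = k if r % 2 == 0 else k + 1
                lL = lengths[(r, k)][t]
                lR = lengths[(r, k + 1)][t]
                poly = [
                    (cy(r) - lL / 2, jx(r, k)),          # A  top-left
                    (cy(r) + lL / 2, jx(r, k)),          # B  bottom-left
                ]
                if r + 1 < R and 0 <= kp <= K - 1:
                    lD = lengths[(r + 1, kp)][t]
                    poly.append((cy(r + 1) - lD / 2, jx(r + 1, kp)))  # C
                poly.extend([
                    (cy(r) + lR / 2, jx(r, k + 1)),      # D  bottom-right
                    (cy(r) - lR / 2, jx(r, k + 1)),      # E  top-right
                ])
                if r - 1 >= 0 and 0 <= kp <= K - 1:
                    lU = lengths[(r - 1, kp)][t]
                    poly.append((cy(r - 1) + lU / 2, jx(r - 1, kp)))  # F
                p = np.array([pt(rr_, cc_, t) for rr_, cc_ in poly])
                rr, cc = draw_polygon(p[:, 0], p[:, 1], shape=frame.shape)
                frame[rr, cc] = bid(r, k)
                areas[t, bid(r, k) - 1] = _shoelace(p)
                if t == 0:  # transverse truth segments (same keys all frames)
                    if r + 1 < R and 0 <= kp <= K - 1:
                        below_left = kp - 1
                        if 0 <= below_left <= n_bricks_per_row - 1:
                            trans_segments[("TL", r, k)] = (
                                np.zeros((n_frames, 2, 2)),
                                f"{min(bid(r,k), bid(r+1,below_left))}-"
                                f"{max(bid(r,k), bid(r+1,below_left))}")
                        if 0 <= kp <= n_bricks_per_row - 1:
                            trans_segments[("TR", r, k)] = (
                                np.zeros((n_frames, 2, 2)),
                                f"{min(bid(r,k), bid(r+1,kp))}-"
                                f"{max(bid(r,k), bid(r+1,kp))}")
        for (tag, r, k) in list(trans_segments):
            kp = k if r % 2 == 0 else k + 1
            lD = lengths[(r + 1, kp)][t]
            Cpt = pt(cy(r + 1) - lD / 2, jx(r + 1, kp), t)
            if tag == "TL":
                lL = lengths[(r, k)][t]
                Bpt = pt(cy(r) + lL / 2, jx(r, k), t)
                trans_segments[(tag, r, k)][0][t] = [Bpt, Cpt]
            else:
                lR = lengths[(r, k + 1)][t]
                Dpt = pt(cy(r) + lR / 2, jx(r, k + 1), t)
                trans_segments[(tag, r, k)][0][t] = [Cpt, Dpt]
        # fill rasterization seams inside the tissue with the nearest label
        mask = binary_fill_holes(frame > 0)
        holes = mask & (frame == 0)
        if holes.any():
            _, (ir, ic) = distance_transform_edt(frame == 0,
                                                 return_indices=True)
            frame[holes] = frame[ir[holes], ic[holes]]
        label_movie[t] = frame
        boundary = np.zeros_like(frame, dtype=bool)
        boundary[:, :-1] |= frame[:, :-1] != frame[:, 1:]
        boundary[:-1, :] |= frame[:-1, :] != frame[1:, :]
        mem = gaussian_filter(boundary.astype(float), 1.0)
        membrane_movie[t] = mem / max(mem.max(), 1e-12)
    if membrane_noise > 0:
        membrane_movie = membrane_movie + rng.normal(
            0.0, membrane_noise, size=membrane_movie.shape).astype(np.float32)

    joint_pair = {}
    for (r, k) in joint_keys:
        if 1 <= k <= K - 2:
            a, b = bid(r, k - 1), bid(r, k)
            joint_pair[(r, k)] = f"{min(a,b)}-{max(a,b)}"
    meta = ImagingMetadata(pixel_size=pixel_size,
                           frame_interval=frame_interval)
    jl = pd.DataFrame({f"{r},{k}": lengths[(r, k)] for (r, k) in joint_keys})
    ar = pd.DataFrame(areas, columns=[i + 1 for i in range(areas.shape[1])])
    return SyntheticTissue(label_movie, membrane_movie, meta, mode, seed,
                           jl, joint_pair, joint_segments, trans_segments,
                           {k: v for k, v in steps.items()}, ar)


# ---------------------------------------------------------------------------
# spot generators
# ---------------------------------------------------------------------------


def _render_spot(img: np.ndarray, r0: float, c0: float, amp: float,
                 sigma: float):
    h, w = img.shape
    rad = int(np.ceil(4 * sigma))
    r1, r2 = max(0, int(r0) - rad), min(h, int(r0) + rad + 1)
    c1, c2 = max(0, int(c0) - rad), min(w, int(c0) + rad + 1)
    if r1 >= r2 or c1 >= c2:
        return
    rr, cc = np.mgrid[r1:r2, c1:c2]
    img[r1:r2, c1:c2] += amp * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))


@dataclass
class SpotTruth:
    events: pd.DataFrame          # event, class, interface, side, t0, t1
    positions: dict               # event -> (n_live, 3) [frame, row, col]


def synth_spot_movie(tissue: SyntheticTissue, n_events: int = 100,
                     polarity_fraction: float = 0.57,
                     lifetime_mean_s: float = 20.0,
                     lifetime_law: str = "exponential",
                     snr: float = 5.0, sigma_px: float = 1.2,
                     background: float = 100.0, read_noise: float = 3.0,
                     side_offset_px: float = 1.0, min_sep: float = 9.0,
                     refractory_frames: int = 4, seed: int = 0):
    """Compartment-channel movie on a synthetic tissue.

    Each event picks a vertical joint with probability
    ``polarity_fraction`` (else a transverse segment), a position along
    the central 50% of the segment, a side, and a lifetime from the law
    (``exponential`` with the given mean, or ``constant``); at most one
    concurrent event per interface and ``min_sep`` px between
    concurrent events.  Intensity follows a grow-then-shrink triangular
    profile; noise is Poisson shot noise on (background + signal) plus
    Gaussian read noise, and SNR is the peak spot amplitude divided by
    the background sigma sqrt(background + read_noise^2).  The default
    spot width (sigma 1.2 px at 0.164 um/px) is a diffraction-limited
    compartment core.
    """
    if snr <= 0:
        raise ParameterError("snr must be > 0")
    rng = np.random.default_rng(seed)
    T, H, W = tissue.label_movie.shape
    vert = [k for k in tissue.joint_pair]      # interior vertical joints
    trans = list(tissue.transverse_segments)
    if not vert or not trans:
        raise ParameterError("tissue has no interior interfaces")

    def seg_at(key, cls, t):
        if cls == "AP":
            return tissue.joint_segments[key][t]
        return tissue.transverse_segments[key][0][t]

    events, positions = [], {}
    occupied: dict = {}
    live_pos: dict[int, list] = {t: [] for t in range(T)}
    attempts = 0
    eid = 0
    # classes are quota-sampled (exactly round(polarity_fraction * n)
    # vertical events, shuffled) and kept through placement retries, so
    # the imposed polarity fraction is exact by construction rather than
    # subject to Bernoulli wobble or class-dependent placement rejection
    n_ap = int(round(polarity_fraction * n_events))
    class_seq = np.array([True] * n_ap + [False] * (n_events - n_ap))
    rng.shuffle(class_seq)
    while eid < n_events:
        is_ap = bool(class_seq[eid])
        attempts += 1
        if attempts > 200 * n_events:
            raise ParameterError(
                "could not place events: more concurrent spots than interfaces")
        if lifetime_law == "constant":
            L = max(3, int(round(lifetime_mean_s
                                 / tissue.metadata.frame_interval)))
        else:
            L = max(3, int(round(rng.exponential(lifetime_mean_s)
                                 / tissue.metadata.frame_interval)))
        if L >= T:
            continue
        t0 = int(rng.integers(0, T - L))
        t1 = t0 + L - 1
        if is_ap:
            key = vert[int(rng.integers(len(vert)))]
            iface = tissue.joint_pair[key]
            cls = "AP"
        else:
            key = trans[int(rng.integers(len(trans)))]
            iface = tissue.transverse_segments[key][1]
            cls = "transverse"
        # one event per interface at a time, with a refractory gap longer
        # than the tracker's gap-closing window so distinct events on one
        # interface remain distinguishable in principle
        span = occupied.setdefault(iface, [])
        m = refractory_frames
        if any(t0 <= e + m and t1 >= s - m for (s, e) in span):
            continue
        u = rng.uniform(0.3, 0.7)
        side = 1 if rng.random() < 0.5 else -1
        pos = np.empty((L, 3))
        ok = True
        for j, t in enumerate(range(t0, t1 + 1)):
            p1, p2 = seg_at(key, cls, t)
            p = p1 + u * (np.asarray(p2) - np.asarray(p1))
            if cls == "AP":
                off = np.array([0.0, -side_offset_px if side > 0
                                else side_offset_px])
            else:
                off = np.array([-side_offset_px if side > 0
                                else side_offset_px, 0.0])
            p = p + off
            for q in live_pos[t]:
                if np.hypot(p[0] - q[0], p[1] - q[1]) < min_sep:
                    ok = False
                    break
            if not ok:
                break
            pos[j] = (t, p[0], p[1])
        if not ok:
            continue
        span.append((t0, t1))
        for j in range(L):
            live_pos[int(pos[j, 0])].append(pos[j, 1:])
        events.append(dict(event=eid, cls=cls, interface=iface,
                           side=side, t0=t0, t1=t1,
                           lifetime_frames=L))
        positions[eid] = pos
        eid += 1

    movie = np.full((T, H, W), background, dtype=np.float64)
    amp0 = snr * np.sqrt(background + read_noise ** 2)
    for ev in events:
        pos = positions[ev["event"]]
        L = ev["lifetime_frames"]
        for j in range(L):
            t = int(pos[j, 0])
            frac = (j + 0.5) / L
            profile = 0.5 + 0.5 * (1.0 - abs(2 * frac - 1.0))  # 0.5->1->0.5
            _render_spot(movie[t], pos[j, 1], pos[j, 2],
                         amp0 * profile, sigma_px)
    movie = rng.poisson(np.maximum(movie, 0.0)).astype(np.float64)
    if read_noise > 0:
        movie += rng.normal(0.0, read_noise, size=movie.shape)
    truth = SpotTruth(pd.DataFrame(events), positions)
    return movie.astype(np.float32), truth


def synth_spot_frames(n_frames: int = 10, spots_per_frame: int = 20,
                      shape=(256, 256), snr: float = 5.0,
                      sigma_px: float = 1.2, background: float = 100.0,
                      read_noise: float = 3.0, min_sep: float = 12.0,
                      margin: int = 12, seed: int = 0):
    """Independent frames of well-separated static spots (detection truth).

    Photon noise model as in ``synth_spot_movie``.  Returns
    ``(movie, truth)`` with truth rows (frame, row, col).
    """
    rng = np.random.default_rng(seed)
    T = n_frames
    movie = np.full((T,) + tuple(shape), background, dtype=np.float64)
    amp = snr * np.sqrt(background + read_noise ** 2)
    rows = []
    for t in range(T):
        placed = []
        tries = 0
        while len(placed) < spots_per_frame and tries < 5000:
            tries += 1
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            if all(np.hypot(r - pr, c - pc) >= min_sep for pr, pc in placed):
                placed.append((r, c))
        for (r, c) in placed:
            _render_spot(movie[t], r, c, amp, sigma_px)
            rows.append(dict(frame=t, row=r, col=c))
    movie = rng.poisson(np.maximum(movie, 0.0)).astype(np.float64)
    if read_noise > 0:
        movie += rng.normal(0.0, read_noise, size=movie.shape)
    return movie.astype(np.float32), pd.DataFrame(rows)


def synth_gap_stubs(n_pairs: int = 20, frame_interval: float = 1.0,
                    stub_len: int = 5, seed: int = 0):
    """Designed track stubs for exercising the gap-closing rules.

    Each pair is two stubs of a nominal single particle separated by a
    number of missing frames and a spatial offset; the four design
    kinds cycle through satisfying/violating the two closing rules.
    The temporal gap the tracker tests is the time between the stub
    endpoints, (missing + 1) * frame_interval.  Stub pairs are laid out
    far apart so the only decision is whether to close the designed
    gap.  Returns ``(detections_per_frame, designs)`` with columns
    (pair, missing_frames, offset_px, should_close).
    """
    from .particles import ParticleDetection

    rng = np.random.default_rng(seed)
    designs = []
    n_frames = 2 * stub_len + 6
    dets: list[list] = [[] for _ in range(n_frames)]
    for i in range(n_pairs):
        kind = i % 4
        if kind == 0:
            miss, off = int(rng.integers(1, 3)), float(rng.uniform(0.5, 3.5))
        elif kind == 1:
            miss, off = int(rng.integers(1, 3)), float(rng.uniform(4.5, 8.0))
        elif kind == 2:
            miss, off = int(rng.integers(3, 5)), float(rng.uniform(0.5, 3.5))
        else:
            miss, off = int(rng.integers(3, 5)), float(rng.uniform(4.5, 8.0))
        should = (miss + 1) * frame_interval <= 3.0 and off <= 4.0
        base = np.array([40.0 + 60.0 * (i // 8), 40.0 + 60.0 * (i % 8)])
        ang = rng.uniform(0, 2 * np.pi)
        p2 = base + off * np.array([np.sin(ang), np.cos(ang)])
        t_resume = stub_len + miss
        for t in range(stub_len):
            dets[t].append(ParticleDetection(
                t, (base[0], base[1]), np.zeros((0, 2), int), 1, 1.0))
        for t in range(t_resume, min(t_resume + stub_len, n_frames)):
            dets[t].append(ParticleDetection(
                t, (p2[0], p2[1]), np.zeros((0, 2), int), 1, 1.0))
        designs.append(dict(pair=i, missing_frames=miss, offset_px=off,
                            should_close=should,
                            end_pos=(base[0], base[1]),
                            start_pos=(p2[0], p2[1])))
    return dets, pd.DataFrame(designs)


def synth_association_events(n: int = 200, pairing_fraction: float = 0.07,
                             n_interfaces: int = 60, n_frames: int = 300,
                             lifetime_mean: float = 20.0,
                             seed: int = 0):
    """Association records with a known paired-event fraction.

    Exactly ``round(pairing_fraction * n / 2)`` synchronous
    opposite-side pairs are embedded among ``n`` events (quota
    sampling), so the fraction of events that are paired equals the
    requested fraction up to rounding; unpaired events are placed so no
    accidental opposite-side overlap occurs.  Returns
    ``(records, truth_paired_fraction)``.
    """
    from .association import AssociationRecord

    rng = np.random.default_rng(seed)
    n_pairs = int(round(pairing_fraction * n / 2.0))
    want_pair_seq = np.zeros(n - n_pairs, dtype=bool)
    want_pair_seq[:n_pairs] = True
    rng.shuffle(want_pair_seq)
    records = []
    occupied: dict[int, list] = {}
    tid = 0
    placed = paired_n = 0
    i_event = 0
    tries = 0
    while placed < n and i_event < want_pair_seq.size:
        tries += 1
        if tries > 100 * n:
            raise ParameterError("could not place association events")
        iface = int(rng.integers(n_interfaces))
        L = max(2, int(round(rng.exponential(lifetime_mean))))
        if L >= n_frames:
            continue
        t0 = int(rng.integers(0, n_frames - L))
        t1 = t0 + L - 1
        spans = occupied.setdefault(iface, [])
        if any(t0 <= e + 2 and t1 >= s - 2 for (s, e) in spans):
            continue
        side = 1 if rng.random() < 0.5 else -1
        records.append(AssociationRecord(tid, f"i{iface}", side, t0, t1))
        tid += 1
        if want_pair_seq[i_event]:
            records.append(AssociationRecord(tid, f"i{iface}", -side, t0, t1))
            tid += 1
            paired_n += 2
            placed += 2
        else:
            placed += 1
        i_event += 1
        spans.append((t0, t1))
    return records, paired_n / placed
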