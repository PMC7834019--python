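"""Synthetic-data generators with known ground truth.

Worm simulator
    An agent-based biased random walk implementing the two-strategy
    navigation model.  Each second a worm either runs -- heading drifts
    by Gaussian noise plus a klinotaxis steering term proportional to
    the normal gradient dC/dn -- or pirouettes, a bout of large random
    reorientations entered with probability

        p = clip(p0 * dt - g_kk * dC/dt * dt, 0, 1)

    so that falling salt concentration raises the turning rate
    (klinokinesis) when the gain g_kk is positive.  dC/dt is the
    trailing-window mean of the concentration derivative along the
    path, the same quantity the analysis pipeline estimates; the
    modulation switches on once the window has filled.  Bout durations
    are exponential; position advances at constant speed with specular
    reflection at the plate rim.  With both gains at zero the worm is
    an unbiased persistent random walk -- the null condition for index
    calibration.

Trace simulator
    A latent first-order response relaxes toward a per-epoch target
    level; two channels move in opposite directions around their
    baselines (ratiometric coupling), optionally bleach with a common
    exponential, and carry Gaussian noise.  Ground-truth step metrics
    are computed from the noiseless latent ratio, so at zero noise the
    analysis pipeline must reproduce them exactly.

Velocity simulator
    Piecewise-constant signed velocity with reversal episodes at
    33 frames/s, for exercising the reversal-classification rule.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plate import PlateGeometry
from .gradient import ConcentrationField, concentration_at, gradient_at
from .trajectory import (PIROUETTE, RUN, UNDEFINED, StateTrack, Trajectory)
from .traces import (NormalizedTrace, ReversalCall, StepMetrics,
                     StimulusProtocol, TwoChannelTrace, classify_reversal,
                     normalize, scl_delta, yc_step_metrics)


# ---------------------------------------------------------------------------
# worm simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimWormParams:
    """Generative parameters of one simulated worm cohort.

    Defaults describe a fed wild-type-like animal: crawling speed
    0.12 mm/s, mild heading wander (8 deg per 1-s step), a baseline
    pirouette initiation rate of 0.03 /s, and strategy gains that
    produce a clear migration bias toward high salt -- klinotaxis gain
    2 (deg/mm)/(mM/mm) and klinokinesis gain 0.1 per (mM/s), which
    spans initiation rates of roughly 0.01-0.05 /s over the useful
    |dC/dt| range on the default plate.
    """

    speed: float = 0.12                         # mm/s
    run_turn_sd: float = 8.0                    # deg per step
    base_pirouette_rate: float = 0.03           # 1/s
    klinokinesis_gain: float = 0.1              # 1 per (mM/s)
    klinotaxis_gain: float = 2.0                # (deg/mm) per (mM/mm)
    dcdt_window: float = 10.0                   # s
    pirouette_duration_mean: float = 3.0        # s
    pirouette_reorientation: tuple[float, float] = (90.0, 180.0)  # deg, random sign

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0 <= self.base_pirouette_rate <= 1:
            raise ValueError("base_pirouette_rate must be in [0, 1]")
        if self.pirouette_duration_mean <= 0:
            raise ValueError("pirouette_duration_mean must be positive")
        if self.run_turn_sd < 0 or self.dcdt_window <= 0:
            raise ValueError("run_turn_sd must be >= 0 and dcdt_window > 0")
        lo, hi = self.pirouette_reorientation
        if not 0 < lo <= hi:
            raise ValueError("pirouette_reorientation range must be positive")


@dataclass
class SimConfig:
    """Assay-level configuration: cohort size, duration and arena."""

    geometry: PlateGeometry
    field: ConcentrationField
    n_worms: int = 40
    duration: float = 900.0
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_worms < 1 or self.duration <= 0 or self.dt <= 0:
            raise ValueError("invalid simulation config")


@dataclass
class SimResult:
    tracks: list[Trajectory]
    states: list[StateTrack]
    dcdt: list[np.ndarray]          # ground-truth sensed dC/dt per sample
    dcdn: list[np.ndarray]          # ground-truth sensed dC/dn per sample
    params: SimWormParams
    config: SimConfig

    def final_positions(self) -> np.ndarray:
        return np.array([tr.positions[-1] for tr in self.tracks])


def _sample_start_positions(geometry: PlateGeometry, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the start ellipse (major axis along A--B)."""
    ra, rb = geometry.start_ellipse_radii
    r = np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * math.pi, n)
    u = ra * r * np.cos(phi)
    v = rb * r * np.sin(phi)
    ex, ey = geometry.ab_axis()
    return np.column_stack([u * ex - v * ey, u * ey + v * ex])


def _labels_to_bouts(labels: np.ndarray, times: np.ndarray) -> list:
    bouts = []
    in_bout = False
    for i, lab in enumerate(labels):
        if lab == PIROUETTE and not in_bout:
            start = times[i]
            in_bout = True
        elif lab != PIROUETTE and in_bout:
            bouts.append((float(start), float(times[i - 1])))
            in_bout = False
    if in_bout:
        bouts.append((float(start), float(times[-1])))
    return bouts


def simulate_worms(config: SimConfig, params: SimWormParams) -> SimResult:
    """Run the cohort and record trajectories plus full ground truth.

    Per step and worm, the sensed dC/dt (trailing window) and dC/dn
    (gradient projected on the left normal of the current heading) are
    recorded exactly as used by the update rules, along with the
    run/pirouette state, so analysis-side estimates can be validated
    against the generative truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_worms
    dt = config.dt
    n_samples = int(round(config.duration / dt))
    w = int(round(params.dcdt_window / dt))
    fld, geom = config.field, config.geometry
    R = geom.plate_radius

    pos = _sample_start_positions(geom, n, rng)
    theta = rng.uniform(0.0, 360.0, n)
    in_bout = np.zeros(n, dtype=bool)
    remaining = np.zeros(n)

    positions = np.empty((n_samples, n, 2))
    conc = np.empty((n_samples, n))
    labels = np.empty((n_samples, n), dtype=np.int8)
    dcdt_rec = np.full((n_samples, n), np.nan)
    dcdn_rec = np.full((n_samples, n), np.nan)

    lo_reo, hi_reo = params.pirouette_reorientation
    for t in range(n_samples):
        positions[t] = pos
        conc[t] = concentration_at(fld, pos[:, 0], pos[:, 1])
        if t >= w:
            dcdt = (conc[t] - conc[t - w]) / (w * dt)
            dcdt_rec[t] = dcdt
        else:
            dcdt = None
        grad = gradient_at(fld, pos[:, 0], pos[:, 1])
        th = np.radians(theta)
        dcdn = -np.sin(th) * grad[:, 0] + np.cos(th) * grad[:, 1]
        dcdn_rec[t] = dcdn

        # draw all randomness unconditionally: determinism is then
        # independent of which branch each worm takes
        u_entry = rng.uniform(0, 1, n)
        run_noise = rng.normal(0.0, params.run_turn_sd, n) \
            if params.run_turn_sd > 0 else np.zeros(n)
        reo = rng.uniform(lo_reo, hi_reo, n) * rng.choice([-1.0, 1.0], n)
        durations = rng.exponential(params.pirouette_duration_mean, n)

        p = np.full(n, params.base_pirouette_rate * dt)
        if dcdt is not None:
            p -= params.klinokinesis_gain * dcdt * dt
        np.clip(p, 0.0, 1.0, out=p)
        entering = (~in_bout) & (u_entry < p)
        remaining[entering] = durations[entering]
        in_bout |= entering

        labels[t] = np.where(in_bout, PIROUETTE, RUN)
        theta = np.where(
            in_bout,
            theta + reo,
            theta + run_noise
            + params.klinotaxis_gain * dcdn * (params.speed * dt))

        remaining[in_bout] -= dt
        in_bout &= remaining > 0

        step = params.speed * dt
        nxt = pos + step * np.column_stack([np.cos(np.radians(theta)),
                                            np.sin(np.radians(theta))])
        r = np.hypot(nxt[:, 0], nxt[:, 1])
        out = r > R
        if out.any():
            nhat = nxt[out] / r[out, None]
            nxt[out] -= 2 * (r[out] - R)[:, None] * nhat
            v = np.column_stack([np.cos(np.radians(theta[out])),
                                 np.sin(np.radians(theta[out]))])
            v -= 2 * (v * nhat).sum(axis=1)[:, None] * nhat
            theta[out] = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
        pos = nxt

    times = np.arange(n_samples) * dt
    tracks, states, dcdt_list, dcdn_list = [], [], [], []
    for i in range(n):
        tracks.append(Trajectory(f"worm_{i:03d}", times.copy(),
                                 positions[:, i, :].copy()))
        lab = labels[:, i].copy()
        states.append(StateTrack(lab, _labels_to_bouts(lab, times)))
        dcdt_list.append(dcdt_rec[:, i].copy())
        dcdn_list.append(dcdn_rec[:, i].copy())
    return SimResult(tracks, states, dcdt_list, dcdn_list, params, config)


# ---------------------------------------------------------------------------
# trace simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSimParams:
    """Generative parameters for a two-channel sensor recording.

    ``amplitudes`` gives the latent response target per protocol epoch
    (dimensionless); the channels read
    baseline * (1 + coupling * response) * bleach + background + noise,
    with opposite coupling signs emulating a FRET pair.  A common
    bleach factor cancels in the ratio, so ground truth is exact even
    with bleaching on.
    """

    protocol: StimulusProtocol
    duration_s: float
    amplitudes: tuple
    baseline_1: float = 200.0
    baseline_2: float = 100.0
    coupling: tuple[float, float] = (0.5, -0.5)
    rise_tau: float = 2.0
    decay_tau: float = 20.0
    noise_sd: float = 0.0
    bleach_tau: float | None = None
    background: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_1 <= 0 or self.baseline_2 <= 0:
            raise ValueError("channel baselines must be positive")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if len(self.amplitudes) != len(self.protocol.epochs):
            raise ValueError("need one amplitude per protocol epoch")
        for c, a in ((c, a) for c in self.coupling for a in self.amplitudes):
            if abs(c * a) >= 1:
                raise ValueError("coupling * amplitude must stay below 1 "
                                 "(channels must remain positive)")


def _latent_response(params: TraceSimParams, times: np.ndarray) -> np.ndarray:
    """Closed-form piecewise first-order relaxation at the frame times."""
    r = np.empty_like(times)
    starts = [t for t, _ in params.protocol.epochs] + [params.duration_s]
    level = float(params.amplitudes[0])      # start at equilibrium
    for e in range(len(params.protocol.epochs)):
        t0, t1 = starts[e], starts[e + 1]
        target = float(params.amplitudes[e])
        tau = params.rise_tau if target > level else params.decay_tau
        sel = (times >= t0) & (times < t1)
        r[sel] = target + (level - target) * np.exp(-(times[sel] - t0) / tau)
        level = target + (level - target) * math.exp(-(t1 - t0) / tau)
    return r


def simulate_ratio_trace(params: TraceSimParams):
    """Generate a two-channel trace plus ground-truth step metrics.

    Returns ``(trace, ground_truth)`` where ``ground_truth`` holds the
    noiseless normalised ratio and the step metrics computed from it:
    the plain across-step delta if the protocol has exactly one
    down-step, and per-down-step peak/decay metrics.
    """
    rate = params.protocol.frame_rate
    n_frames = int(round(params.duration_s * rate))
    times = np.arange(n_frames) / rate
    resp = _latent_response(params, times)
    c1, c2 = params.coupling
    b1, b2 = params.baseline_1, params.baseline_2
    bleach = (np.exp(-times / params.bleach_tau)
              if params.bleach_tau else np.ones_like(times))
    rng = np.random.default_rng(params.seed)
    bg1, bg2 = params.background
    ch1 = b1 * (1 + c1 * resp) * bleach + bg1 + rng.normal(0, params.noise_sd, n_frames)
    ch2 = b2 * (1 + c2 * resp) * bleach + bg2 + rng.normal(0, params.noise_sd, n_frames)
    trace = TwoChannelTrace(times, ch1, ch2, background_1=bg1, background_2=bg2)

    # ground truth from the noiseless latent ratio (bleach cancels)
    ratio_nl = (b1 * (1 + c1 * resp)) / (b2 * (1 + c2 * resp))
    onset_frame = params.protocol.epoch_frames(n_frames)[0][1]
    norm_nl = normalize(ratio_nl, onset_frame, times)
    downs = params.protocol.down_steps()
    truth = {"normalized": norm_nl, "baseline_frames": onset_frame}
    if len(downs) == 1:
        truth["scl_delta"] = scl_delta(norm_nl, params.protocol)
    truth["yc"] = [yc_step_metrics(norm_nl, params.protocol, k)
                   for k in range(1, len(downs) + 1)]
    return trace, truth


# ---------------------------------------------------------------------------
# velocity simulator
# ---------------------------------------------------------------------------

def simulate_velocity_trace(episodes: list[tuple[int, int, float]],
                            baseline_velocity: float = 150.0,
                            noise_sd: float = 0.0,
                            n_frames: int = 990,
                            stim_onset: int = 100,
                            frame_rate: float = 33.0,
                            seed: int = 0):
    """Piecewise-constant signed velocity with reversal episodes.

    ``episodes`` is a list of (start_frame, length_frames, velocity);
    outside episodes the animal moves forward at ``baseline_velocity``.
    Returns ``(velocity, ground_truth)`` where the ground-truth
    :class:`ReversalCall` applies the classification rule to the
    noiseless series.
    """
    v = np.full(n_frames, float(baseline_velocity))
    prev_end = -1
    for start, length, vel in sorted(episodes):
        if start <= prev_end:
            raise ValueError("episodes overlap")
        if start < 0 or start + length > n_frames:
            raise ValueError("episode outside trace span")
        v[start:start + length] = vel
        prev_end = start + length - 1
    truth = classify_reversal(v, stim_onset, frame_rate=frame_rate)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0, noise_sd, n_frames)
    return v, truth
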