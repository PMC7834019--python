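"""Single-animal trajectories and kinematic series.

Plates are imaged at one frame per second for 15 min, so a trajectory is
a uniformly sampled (x, y) track in mm.  From it we derive per-step
bearing and speed, the curving rate (bearing change per unit path
length, positive = leftward), and a run/pirouette state segmentation.

Index conventions for the derived series (all returned as arrays of the
same length as the track, NaN where undefined):

* ``bearing[i]``, ``speed[i]`` describe the step from sample i to i+1
  (undefined at the last sample).
* ``curving[i]`` is the wrapped bearing change between the steps ending
  and starting at sample i, divided by the length of the outgoing step
  (undefined at the first and last samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: per-sample state labels
RUN = 0
PIROUETTE = 1
UNDEFINED = 2

_STATE_NAMES = {RUN: "run", PIROUETTE: "pirouette", UNDEFINED: "undefined"}


@dataclass
class Trajectory:
    """One animal's positional track, uniformly sampled.

    ``times`` are in seconds with a constant step (1 s in the standard
    assay); ``positions`` is an (n, 2) array of mm coordinates.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    valid_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise ValueError("times must be 1-D and positions (n, 2)")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for a single-sample track")
        return float(self.times[1] - self.times[0])

    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class StateTrack:
    """Per-sample run/pirouette labels and the list of pirouette bouts."""

    labels: np.ndarray                      # int8 array of RUN/PIROUETTE/UNDEFINED
    bouts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        last_end = -np.inf
        for start, end in self.bouts:
            if end < start or start < last_end:
                raise ValueError("bouts must be ordered and non-overlapping")
            last_end = end

    def state_names(self) -> list[str]:
        return [_STATE_NAMES[int(s)] for s in self.labels]


def wrap_angle(deg):
    """Wrap angles to (-180, 180] degrees."""
    return -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)


def smooth_positions(track: Trajectory, window: int) -> Trajectory:
    """Centred moving-average smoothing of positions.

    ``window`` is an odd number of samples; near the track ends the
    window shrinks symmetrically so the average stays centred.  A window
    of 1 is the identity.  Smoothing suppresses head-swing jitter before
    bearing estimation; simulated worms have no such jitter and can be
    analysed unsmoothed.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd number of samples")
    if window > track.n:
        raise ValueError("smoothing window longer than track")
    if window == 1:
        return track
    half = window // 2
    n = track.n
    out = np.empty_like(track.positions)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = track.positions[i - k:i + k + 1].mean(axis=0)
    return Trajectory(track.track_id, track.times.copy(), out, track.valid_window)


def heading_and_speed(track: Trajectory, reversal_flags: np.ndarray | None = None):
    """Per-step bearing (deg CCW from +x), speed (um/s) and signed velocity.

    The worm outline gives no forward axis, so the sign of the velocity
    must come from an external reversal annotation: ``reversal_flags``
    marks steps moving backwards, which are reported with negative
    velocity.  Without flags the signed velocity equals the speed.

    Returns three arrays of length n; the entry for the last sample is
    NaN, as is the bearing of any zero-displacement step.
    """
    if track.n < 2:
        raise ValueError("need at least two samples")
    disp = np.diff(track.positions, axis=0)
    dt = track.dt
    dist = np.hypot(disp[:, 0], disp[:, 1])
    bearing = np.full(track.n, np.nan)
    speed = np.full(track.n, np.nan)
    moved = dist > 0
    bearing[:-1][moved] = np.degrees(np.arctan2(disp[moved, 1], disp[moved, 0]))
    speed[:-1] = dist / dt * 1000.0     # mm/s -> um/s
    signed = speed.copy()
    if reversal_flags is not None:
        flags = np.asarray(reversal_flags, dtype=bool)
        if flags.size != track.n:
            raise ValueError("reversal_flags must have one entry per sample")
        signed[flags] = -signed[flags]
    return bearing, speed, signed


def curving_rate(track: Trajectory) -> np.ndarray:
    """Bearing change per unit path length, deg/mm, positive = leftward.

    ``curving[i]`` is the wrapped change from the bearing of step i-1 to
    the bearing of step i, divided by the arc length of step i (the step
    over which the new bearing is held).  Samples adjacent to
    zero-length steps are NaN.
    """
    bearing, speed, _ = heading_and_speed(track)
    dt = track.dt
    n = track.n
    out = np.full(n, np.nan)
    dturn = wrap_angle(bearing[1:n - 1] - bearing[0:n - 2])
    steplen = speed[1:n - 1] * dt / 1000.0      # mm
    with np.errstate(invalid="ignore", divide="ignore"):
        out[1:n - 1] = np.where(steplen > 0, dturn / steplen, np.nan)
    return out


def segment_pirouettes(track: Trajectory,
                       turn_threshold: float = 90.0,
                       merge_gap: float = 8.0,
                       min_bout: float = 1.0) -> StateTrack:
    """Label each sample run or pirouette from sharp-turn detection.

    A sample is a sharp turn when the absolute wrapped bearing change at
    that sample is at least ``turn_threshold`` degrees per step.  Sharp
    turns closer than ``merge_gap`` seconds are merged into a single
    pirouette bout; bouts shorter than ``min_bout`` seconds are
    discarded.  The first and last samples, where no turn is defined,
    are labelled undefined.

    The defaults (90 deg per 1-s step, 8 s merge gap, 1 s minimum bout)
    are declared assumptions of this pipeline: the steep-turn criteria
    used on real recordings live in tracker-specific prior conventions
    and are configurable here.
    """
    dt = track.dt
    bearing, _, _ = heading_and_speed(track)
    n = track.n
    dturn = np.abs(wrap_angle(bearing[1:n - 1] - bearing[0:n - 2]))
    sharp_idx = np.nonzero(dturn >= turn_threshold * dt)[0] + 1   # sample index

    labels = np.full(n, RUN, dtype=np.int8)
    labels[0] = UNDEFINED
    labels[-1] = UNDEFINED
    bouts: list[tuple[float, float]] = []
    if sharp_idx.size:
        groups: list[list[int]] = [[int(sharp_idx[0])]]
        for i in sharp_idx[1:]:
            if (i - groups[-1][-1]) * dt < merge_gap:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for g in groups:
            start, end = g[0], g[-1]
            if (end - start + 1) * dt < min_bout:
                continue
            labels[start:end + 1] = PIROUETTE
            bouts.append((float(track.times[start]), float(track.times[end])))
    return StateTrack(labels, bouts)
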