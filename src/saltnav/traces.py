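"""Fluorescence-trace step-response metrics and reversal classification.

Ratiometric sensors (SuperClomeleon for chloride, Yellow Cameleon for
calcium) are read out as the background-corrected YFP/CFP ratio R,
normalised to the pre-stimulus baseline R0; single-fluorophore GCaMP
recordings are normalised the same way after division by a co-expressed
mCherry reference, giving F/F0.  All step-response metrics are means
over frame windows anchored to the stimulus protocol:

* SuperClomeleon delta: last 10 s of the low-salt epoch minus the 10 s
  just before the down-step.
* Yellow Cameleon, per down-step k: peak = highest 10-s moving average
  of R/R0 during the low-salt epoch; peak delta = peak minus the 10-s
  pre-step mean; decay1 = peak minus the last-10-s mean of the epoch;
  decay2 = last-10-s mean of the epoch minus the last-10-s mean of the
  following high-salt epoch.
* AIB delta: mean F/F0 over frames 125-175 minus frames 51-100
  (1-based inclusive, anchored to recording start; at 4 frames/s with
  the stimulus at 25 s this is a post-step window minus a pre-step
  window).

Reversals in the freely-moving preparation are scored from the signed
centroid velocity at 33 frames/s: an animal is "reversed" when a run of
more than 35 consecutive frames (1 s) below -100 um/s starts within 501
frames (15 s) of the salt up-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AIB_BASELINE_FRAMES = (51, 100)     # 1-based inclusive
AIB_PEAK_FRAMES = (125, 175)
REVERSAL_VELOCITY = -100.0          # um/s
REVERSAL_MIN_FRAMES = 35            # run must be strictly longer than this
REVERSAL_WINDOW_FRAMES = 501        # run must start within this many frames


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant stimulus: epochs of fixed NaCl concentration.

    ``epochs`` is a list of (start time s, concentration mM); the first
    epoch must start at 0 and epochs tile the recording.
    """

    frame_rate: float
    epochs: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs",
                           tuple((float(t), float(c)) for t, c in self.epochs))
        if not self.epochs or self.epochs[0][0] != 0:
            raise ValueError("first epoch must start at t = 0")
        starts = [t for t, _ in self.epochs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def epoch_frames(self, n_frames: int) -> list[tuple[int, int, float]]:
        """(start_frame, end_frame_exclusive, conc) for each epoch."""
        bounds = [int(round(t * self.frame_rate)) for t, _ in self.epochs]
        bounds.append(n_frames)
        return [(bounds[i], bounds[i + 1], self.epochs[i][1])
                for i in range(len(self.epochs))]

    def down_steps(self) -> list[int]:
        """Indices of epochs entered by a concentration decrease."""
        return [i for i in range(1, len(self.epochs))
                if self.epochs[i][1] < self.epochs[i - 1][1]]


@dataclass
class TwoChannelTrace:
    """Raw two-channel fluorescence recording with per-channel background."""

    times: np.ndarray
    channel_1: np.ndarray
    channel_2: np.ndarray
    background_1: float | np.ndarray = 0.0
    background_2: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channel_1 = np.asarray(self.channel_1, dtype=float)
        self.channel_2 = np.asarray(self.channel_2, dtype=float)
        if not (self.times.size == self.channel_1.size == self.channel_2.size):
            raise ValueError("times and both channels must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")


@dataclass
class NormalizedTrace:
    """Baseline-normalised readout (R/R0 or F/F0)."""

    times: np.ndarray
    values: np.ndarray
    baseline_frames: int
    reference: float         # R0 or F0 on the raw scale

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class StepMetrics:
    """Step-response summary for one stimulus presentation."""

    delta: float
    peak_delta: float | None = None
    decay1: float | None = None
    decay2: float | None = None
    peak_time: float | None = None


@dataclass
class ReversalCall:
    reversed: bool
    onset: float | None = None          # s from recording start
    run_length: int = 0                 # frames of the qualifying (or longest) run
    truncated: bool = False             # trace ended before the full window


def ratio_trace(trace: TwoChannelTrace) -> np.ndarray:
    """Background-corrected channel ratio per frame, (ch1-bg1)/(ch2-bg2)."""
    num = trace.channel_1 - trace.background_1
    den = trace.channel_2 - trace.background_2
    bad = den <= 0
    if np.any(bad):
        frame = int(np.argmax(bad))
        raise ValueError(
            f"non-positive corrected denominator at frame {frame}")
    return num / den


def normalize(values: np.ndarray, baseline_frames: int,
              times: np.ndarray | None = None) -> NormalizedTrace:
    """Divide by the mean of the first ``baseline_frames`` frames.

    The baseline window is the pre-stimulus period (e.g. 50 frames =
    25 s at 2 frames/s, or 12.5 s at 4 frames/s).  Normalising an
    already-normalised trace with the same window is the identity.
    """
    values = np.asarray(values, dtype=float)
    if baseline_frames <= 0 or baseline_frames >= values.size:
        raise ValueError("baseline_frames must be in (0, len(values))")
    r0 = float(values[:baseline_frames].mean())
    if r0 == 0:
        raise ValueError("baseline mean is zero")
    if times is None:
        times = np.arange(values.size, dtype=float)
    return NormalizedTrace(times=np.asarray(times, dtype=float),
                           values=values / r0,
                           baseline_frames=baseline_frames, reference=r0)


def _window_mean(values: np.ndarray, start: int, stop: int) -> float:
    if stop <= start or start < 0 or stop > values.size:
        raise ValueError(f"invalid frame window [{start}, {stop})")
    return float(values[start:stop].mean())


def _sliding_window_means(values: np.ndarray, start: int, stop: int,
                          w: int) -> np.ndarray:
    """Means of every length-``w`` contiguous window inside [start, stop).

    Each mean covers exactly the nominal averaging duration; the window
    never crosses an epoch boundary.  Entry j covers frames
    [start+j, start+j+w); its centre is frame start+j+w//2.
    """
    seg = values[start:stop]
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    return (cs[w:] - cs[:-w]) / w


def scl_delta(trace: NormalizedTrace, protocol: StimulusProtocol,
              window_s: float = 10.0) -> float:
    """SuperClomeleon R/R0 change across the single down-step.

    mean(R/R0, last ``window_s`` of the low-salt epoch) minus
    mean(R/R0, ``window_s`` immediately before the step).  Chloride
    entry quenches YFP, so a chloride rise gives a negative delta.
    """
    downs = protocol.down_steps()
    if len(downs) != 1:
        raise ValueError(f"protocol must contain exactly one down-step, "
                         f"found {len(downs)}")
    frames = protocol.epoch_frames(trace.values.size)
    start, stop, _ = frames[downs[0]]
    w = int(round(window_s * protocol.frame_rate))
    if stop - start < w or start < w:
        raise ValueError("epochs around the down-step are shorter than the "
                         "averaging window")
    return _window_mean(trace.values, stop - w, stop) - \
        _window_mean(trace.values, start - w, start)


def yc_step_metrics(trace: NormalizedTrace, protocol: StimulusProtocol,
                    k: int, window_s: float = 10.0) -> StepMetrics:
    """Yellow Cameleon metrics for the k-th down-step (k is 1-based).

    The peak is the highest 10-s moving average of R/R0 during the
    low-salt epoch, taken over every full 10-s window inside the epoch
    (so the last window -- the decayed level -- is always a candidate
    and decay1 = peak - last-10-s mean is non-negative).  Calcium rises
    on the down-step (ASE off-response), so peak_delta is normally
    positive; decay2 measures how much further the signal falls during
    the following high-salt epoch (undefined for the last stimulus of a
    recording).  The peak time is per animal: it shifts with response
    rise speed.
    """
    downs = protocol.down_steps()
    if not 1 <= k <= len(downs):
        raise ValueError(f"stimulus ordinal k={k} out of range (1..{len(downs)})")
    ei = downs[k - 1]
    frames = protocol.epoch_frames(trace.values.size)
    start, stop, _ = frames[ei]
    w = int(round(window_s * protocol.frame_rate))
    if stop - start < w or start < w:
        raise ValueError("epoch shorter than the averaging window")

    pre = _window_mean(trace.values, start - w, start)
    ma = _sliding_window_means(trace.values, start, stop, w)
    peak_j = int(np.argmax(ma))
    peak = float(ma[peak_j])
    last = _window_mean(trace.values, stop - w, stop)

    decay2 = None
    if ei + 1 < len(frames):
        nstart, nstop, _ = frames[ei + 1]
        if nstop - nstart >= w:
            decay2 = last - _window_mean(trace.values, nstop - w, nstop)
    return StepMetrics(delta=last - pre, peak_delta=peak - pre,
                       decay1=peak - last, decay2=decay2,
                       peak_time=float(trace.times[start + peak_j + w // 2]))


def aib_delta(trace: NormalizedTrace,
              frames_baseline: tuple[int, int] = AIB_BASELINE_FRAMES,
              frames_peak: tuple[int, int] = AIB_PEAK_FRAMES) -> float:
    """AIB F/F0 change: mean over the peak window minus the baseline window.

    Frame windows are 1-based inclusive and anchored to the recording
    start (with the up-step at 25 s and 4 frames/s, frames 51-100 sit
    just before and 125-175 just after the stimulus).
    """
    b0, b1 = frames_baseline
    p0, p1 = frames_peak
    if trace.values.size < max(b1, p1):
        raise ValueError(f"trace has {trace.values.size} frames; "
                         f"needs at least {max(b1, p1)}")
    return _window_mean(trace.values, p0 - 1, p1) - \
        _window_mean(trace.values, b0 - 1, b1)


def classify_reversal(velocity: np.ndarray, stim_onset: int,
                      threshold: float = REVERSAL_VELOCITY,
                      min_frames: int = REVERSAL_MIN_FRAMES,
                      window_frames: int = REVERSAL_WINDOW_FRAMES,
                      frame_rate: float = 33.0) -> ReversalCall:
    """Stimulus-evoked reversal call from a signed velocity trace.

    Reversed iff a run of strictly more than ``min_frames`` consecutive
    frames with velocity below ``threshold`` starts within
    ``window_frames`` after ``stim_onset`` (run start s satisfies
    stim_onset < s <= stim_onset + window_frames).  The strict run
    length excludes short spontaneous reversals.  If the trace ends
    before the full window the available span is used and the call is
    flagged truncated.
    """
    v = np.asarray(velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity trace")
    truncated = v.size < stim_onset + window_frames
    below = v < threshold
    # run starts and lengths
    padded = np.concatenate([[False], below, [False]])
    starts = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)[0]
    ends = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)[0]
    best_len = 0
    for s, e in zip(starts, ends):
        if stim_onset < s <= stim_onset + window_frames:
            length = e - s
            if length > min_frames:
                return ReversalCall(reversed=True, onset=s / frame_rate,
                                    run_length=int(length), truncated=truncated)
            best_len = max(best_len, length)
    return ReversalCall(reversed=False, onset=None, run_length=int(best_len),
                        truncated=truncated)


def reversal_fraction(calls: list[ReversalCall]) -> dict:
    """Proportion of animals scored as reversed, with counts."""
    if not calls:
        raise ValueError("need at least one animal")
    n_rev = sum(c.reversed for c in calls)
    return {"fraction": n_rev / len(calls), "n_reversed": n_rev,
            "n_animals": len(calls)}
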