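"""Navigation-strategy metrics.

Endpoint metrics
    chemotaxis index  (N_B - N_A) / (N_total - N_O): +1 means every
    scored animal reached the high-salt area, -1 the low-salt area, 0
    no preference.
    immobility index  fraction of animals that never left the start
    region, N_O / N_total (a strict mode reproduces the literal
    difference form N_O - N_total).

Strategy metrics, computed from 1-Hz tracks over a plate
    pirouette index   P(pirouette | dC/dt < 0) - P(pirouette | dC/dt > 0),
    the klinokinesis bias: positive values mean the animal turns more
    when salt is dropping, i.e. migrates up-gradient.
    weathervane index the OLS slope of curving rate (deg/mm) on the
    normal gradient dC/dn (mM/mm) over run-state samples, the
    klinotaxis bias: positive values mean steering towards higher salt.

Both strategy metrics use samples from 40-540 s of the recording (early
samples are discarded because tracks are unreliable right after
placement) and clip the sensory variable to |dC/dt| <= 0.3 mM/s or
|dC/dn| <= 2 mM/mm, where data are dense; outside those ranges samples
are sparse and noisy near the gradient peak.  Indices are computed per
plate and then averaged across plates (mean +/- s.e.m.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plate import PlateGeometry
from .trajectory import (PIROUETTE, RUN, StateTrack, Trajectory, curving_rate,
                         heading_and_speed, segment_pirouettes, smooth_positions)
from .gradient import ConcentrationField, experienced_dCdn, experienced_dCdt

ANALYSIS_WINDOW = (40.0, 540.0)     # s, standard strategy-metric window
DCDT_RANGE = 0.3                    # mM/s
DCDN_RANGE = 2.0                    # mM/mm
MIN_TRACK_SECONDS = 30.0            # tracks shorter than this in-window are dropped


@dataclass(frozen=True)
class AssayCounts:
    """Endpoint worm counts for one plate."""

    n_a: int
    n_b: int
    n_o: int
    n_total: int

    def __post_init__(self) -> None:
        for name in ("n_a", "n_b", "n_o", "n_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_a", "n_b", "n_o"):
            if getattr(self, name) > self.n_total:
                raise ValueError(f"{name} cannot exceed n_total")


@dataclass
class NavigationIndices:
    """Strategy-metric results for one plate."""

    pirouette_index: float | None = None
    p_pirouette_neg: float | None = None
    p_pirouette_pos: float | None = None
    n_neg: int = 0
    n_pos: int = 0
    weathervane_index: float | None = None
    weathervane_stderr: float | None = None
    weathervane_intercept: float | None = None
    n_weathervane: int = 0
    extras: dict = field(default_factory=dict)


def chemotaxis_index(counts: AssayCounts) -> float:
    """(N_B - N_A) / (N_total - N_O)."""
    denom = counts.n_total - counts.n_o
    if denom <= 0:
        raise ValueError("chemotaxis index undefined: no animals outside area O")
    return (counts.n_b - counts.n_a) / denom


def immobility_index(counts: AssayCounts, strict: bool = False) -> float:
    """Fraction of animals remaining in the start region, N_O / N_total.

    ``strict=True`` returns the literal difference N_O - N_total instead
    of the fraction.  The fraction is the default because "high
    immobility" should map to a high value in [0, 1]; the difference
    form is negative and unbounded.
    """
    if strict:
        return float(counts.n_o - counts.n_total)
    if counts.n_total == 0:
        raise ValueError("immobility index undefined for zero animals")
    return counts.n_o / counts.n_total


def count_endpoint_areas(final_positions, geometry: PlateGeometry) -> AssayCounts:
    """Score endpoint positions into areas A, B and O.

    Membership is the strict interior (distance < area radius; ellipse
    sum < 1), so a worm exactly on a boundary is not counted in the
    area.  Positions may fall in no area; every position counts towards
    n_total.
    """
    pos = np.asarray(final_positions, dtype=float).reshape(-1, 2)
    n_a = n_b = n_o = 0
    for x, y in pos:
        if not geometry.contains(x, y):
            raise ValueError(f"position ({x:.2f}, {y:.2f}) is off the plate")
        if geometry.in_area_a(x, y):
            n_a += 1
        if geometry.in_area_b(x, y):
            n_b += 1
        if geometry.in_start_ellipse(x, y):
            n_o += 1
    return AssayCounts(n_a=n_a, n_b=n_b, n_o=n_o, n_total=len(pos))


def attribute_dcdt_to_bout_onset(state: StateTrack, dcdt: np.ndarray,
                                 window_samples: int = 10) -> np.ndarray:
    """Re-attribute dC/dt so both states sample clean run progression.

    The trailing dC/dt window is meaningful only over forward
    progression: during a pirouette the worm's own jumbled motion
    generates concentration changes that cannot be the cause of the
    ongoing bout, and in a curved field that self-motion has a non-zero
    mean (proportional to the field Laplacian), which would bias the
    pirouette index away from zero even for a salt-blind animal.  Two
    corrections follow:

    * every sample of a bout inherits the dC/dt of the last pre-bout
      sample -- the stimulus history that could have triggered the bout;
    * run samples whose trailing window overlaps any bout are flagged
      NaN (their estimate mixes bout motion into "progression").

    Under the null (state independent of salt input) bout onsets are a
    uniform draw from run samples, so after this re-attribution both
    states draw their dC/dt from the same distribution and the index is
    centred on zero by construction.
    """
    dcdt = np.asarray(dcdt, dtype=float)
    out = dcdt.copy()
    pir = state.labels == PIROUETTE
    n = pir.size
    onset_val = np.nan
    in_bout = False
    for i in range(n):
        if pir[i]:
            if not in_bout:
                onset_val = dcdt[i - 1] if i > 0 else np.nan
                in_bout = True
            out[i] = onset_val
        else:
            in_bout = False
    # run sample i uses the diffs over (i - w, i]: contaminated if any
    # of samples i-w+1 .. i was a pirouette sample
    contaminated = np.convolve(pir.astype(float),
                               np.ones(window_samples),
                               mode="full")[:n] > 0
    out[(~pir) & contaminated] = np.nan
    return out


def _pooled(series_list, times_list, window):
    lo, hi = window
    chunks = []
    for s, t in zip(series_list, times_list):
        sel = (t >= lo) & (t <= hi)
        chunks.append(np.asarray(s)[sel])
    return np.concatenate(chunks) if chunks else np.array([])


def pirouette_index(state_tracks: list[StateTrack],
                    dcdt_series: list[np.ndarray],
                    times_list: list[np.ndarray],
                    range_limit: float = DCDT_RANGE,
                    window: tuple[float, float] = ANALYSIS_WINDOW) -> NavigationIndices:
    """Klinokinesis bias: pirouette-probability contrast by sign of dC/dt.

    Samples inside the analysis window with defined state and
    |dC/dt| <= range_limit are split by the sign of dC/dt (exact zeros
    are excluded); within each sign class the pirouette probability is
    the fraction of samples labelled pirouette.  The index is
    P(neg) - P(pos) and lies in [-1, 1].  An empty sign class makes the
    index undefined and raises.
    """
    labels = _pooled([st.labels for st in state_tracks], times_list, window)
    dcdt = _pooled(dcdt_series, times_list, window)
    ok = (~np.isnan(dcdt)) & (np.abs(dcdt) <= range_limit) & (labels != 2)
    neg = ok & (dcdt < 0)
    pos = ok & (dcdt > 0)
    if not neg.any() or not pos.any():
        raise ValueError("pirouette index undefined: empty dC/dt sign class")
    p_neg = float(np.mean(labels[neg] == PIROUETTE))
    p_pos = float(np.mean(labels[pos] == PIROUETTE))
    return NavigationIndices(
        pirouette_index=p_neg - p_pos, p_pirouette_neg=p_neg,
        p_pirouette_pos=p_pos, n_neg=int(neg.sum()), n_pos=int(pos.sum()))


def weathervane_index(curving_series: list[np.ndarray],
                      dcdn_series: list[np.ndarray],
                      state_tracks: list[StateTrack],
                      times_list: list[np.ndarray],
                      range_limit: float = DCDN_RANGE,
                      window: tuple[float, float] = ANALYSIS_WINDOW,
                      min_samples: int = 10) -> NavigationIndices:
    """Klinotaxis bias: regression slope of curving rate on dC/dn.

    Pairs the curving rate at sample i (the turn into step i) with the
    normal gradient of the preceding step i-1 -- the gradient the animal
    sensed while running into the turn.  Only run-state samples with
    |dC/dn| <= range_limit inside the analysis window enter the ordinary
    least-squares fit; pirouette reorientations are not steering.
    Returns the slope ((deg/mm) per (mM/mm)), its standard error and the
    intercept.
    """
    ys, xs = [], []
    lo, hi = window
    for curv, dcdn, st, t in zip(curving_series, dcdn_series,
                                 state_tracks, times_list):
        curv = np.asarray(curv, float)
        dcdn = np.asarray(dcdn, float)
        n = curv.size
        idx = np.arange(1, n)
        x = dcdn[idx - 1]
        y = curv[idx]
        sel = ((t[idx] >= lo) & (t[idx] <= hi)
               & (st.labels[idx] == RUN)
               & ~np.isnan(x) & ~np.isnan(y)
               & (np.abs(x) <= range_limit))
        xs.append(x[sel])
        ys.append(y[sel])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if x.size < min_samples:
        raise ValueError(f"weathervane index needs >= {min_samples} samples, "
                         f"got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("weathervane index undefined: dC/dn has zero variance")

    import statsmodels.api as sm
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return NavigationIndices(
        weathervane_index=float(model.params[1]),
        weathervane_stderr=float(model.bse[1]),
        weathervane_intercept=float(model.params[0]),
        n_weathervane=int(x.size))


def per_plate_aggregate(values) -> tuple[float, float]:
    """Mean and s.e.m. across plates; s.e.m. is NaN for a single plate."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one plate")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return mean, sem


def plate_navigation_indices(tracks: list[Trajectory],
                             field: ConcentrationField,
                             smoothing_window: int = 1,
                             turn_threshold: float = 90.0,
                             merge_gap: float = 8.0,
                             min_bout: float = 1.0,
                             dcdt_window: float = 10.0,
                             dcdt_range: float = DCDT_RANGE,
                             dcdn_range: float = DCDN_RANGE,
                             window: tuple[float, float] = ANALYSIS_WINDOW,
                             states: list[StateTrack] | None = None,
                             dcdt_attribution: str = "onset") -> NavigationIndices:
    """Full per-plate strategy analysis from raw tracks and the field.

    Smooths positions (``smoothing_window`` samples, odd; 1 = off, the
    right choice for simulated worms which have no head-swing jitter),
    segments pirouettes (unless ground-truth ``states`` are supplied),
    evaluates dC/dt and dC/dn along each track, and computes both
    strategy indices pooled over the plate's tracks.  Tracks covering
    less than 30 s of the analysis window are dropped as
    collision-interrupted fragments.

    ``dcdt_attribution="onset"`` (default) passes the dC/dt series
    through :func:`attribute_dcdt_to_bout_onset` so the pirouette index
    is unbiased in curved fields; ``"sample"`` uses each sample's own
    trailing estimate.
    """
    lo, hi = window
    kept_states, kept_tracks = [], []
    for i, tr in enumerate(tracks):
        in_win = (tr.times >= lo) & (tr.times <= hi)
        if in_win.sum() * tr.dt < MIN_TRACK_SECONDS:
            continue
        kept_tracks.append(tr)
        if states is not None:
            kept_states.append(states[i])
    if not kept_tracks:
        raise ValueError("no track covers enough of the analysis window")

    analysed = [smooth_positions(tr, smoothing_window) for tr in kept_tracks]
    if states is None:
        kept_states = [segment_pirouettes(tr, turn_threshold, merge_gap, min_bout)
                       for tr in analysed]
    dcdt = [experienced_dCdt(field, tr, dcdt_window) for tr in analysed]
    if dcdt_attribution == "onset":
        w = int(round(dcdt_window / analysed[0].dt))
        dcdt = [attribute_dcdt_to_bout_onset(st, d, w)
                for st, d in zip(kept_states, dcdt)]
    elif dcdt_attribution != "sample":
        raise ValueError("dcdt_attribution must be 'onset' or 'sample'")
    dcdn = [experienced_dCdn(field, tr) for tr in analysed]
    curv = [curving_rate(tr) for tr in analysed]
    times = [tr.times for tr in analysed]

    pir = pirouette_index(kept_states, dcdt, times, dcdt_range, window)
    wv = weathervane_index(curv, dcdn, kept_states, times, dcdn_range, window)
    return NavigationIndices(
        pirouette_index=pir.pirouette_index,
        p_pirouette_neg=pir.p_pirouette_neg,
        p_pirouette_pos=pir.p_pirouette_pos,
        n_neg=pir.n_neg, n_pos=pir.n_pos,
        weathervane_index=wv.weathervane_index,
        weathervane_stderr=wv.weathervane_stderr,
        weathervane_intercept=wv.weathervane_intercept,
        n_weathervane=wv.n_weathervane,
        extras={"n_tracks_used": len(kept_tracks),
                "n_tracks_total": len(tracks)})
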