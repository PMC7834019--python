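"""NaCl concentration field on the assay plate.

The salt gradient is established by letting the high-salt agar block act
as a constant-concentration (Dirichlet) source while NaCl diffuses
through the thin background agar layer for the overnight equilibration
period.  We model this as 2-D diffusion on the plate disk with a
no-flux (reflecting) rim, solved with an explicit finite-difference
scheme, and then treat the field as static during the 15-min tracking
assay -- the assay is two orders of magnitude shorter than the
equilibration, so further sharpening of the gradient is second order.

A block containing no NaCl is chemically inert on a salt-free
background plate, so only blocks with positive concentration are held
as sources; both block positions are still used for the endpoint
scoring areas.

Sampling helpers evaluate, along a worm's track, the concentration
change per unit time (dC/dt, averaged over a trailing window) and the
gradient normal to the heading (dC/dn, positive when salt increases to
the animal's left) -- the sensory inputs of klinokinesis and klinotaxis
respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .plate import PlateGeometry
from .trajectory import Trajectory, heading_and_speed

#: NaCl diffusion coefficient in dilute agar, mm^2/s (close to the
#: aqueous value; agar at 2% barely obstructs small ions).
DEFAULT_DIFFUSION = 1.5e-3


@dataclass
class ConcentrationField:
    """Gridded concentration C(x, y) in mM over the plate.

    ``values[i, j]`` is the concentration at
    ``(origin[0] + j * grid_spacing, origin[1] + i * grid_spacing)``;
    ``mask`` flags grid cells whose centre lies on the plate.
    """

    grid_spacing: float
    origin: tuple[float, float]
    values: np.ndarray
    mask: np.ndarray
    timestamp: float = 0.0
    plate_radius: float | None = None
    _interp: dict = dc_field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must be matching 2-D arrays")

    # -- coordinates ---------------------------------------------------------

    @property
    def xs(self) -> np.ndarray:
        return self.origin[0] + self.grid_spacing * np.arange(self.values.shape[1])

    @property
    def ys(self) -> np.ndarray:
        return self.origin[1] + self.grid_spacing * np.arange(self.values.shape[0])

    def _filled(self) -> np.ndarray:
        """Values with off-plate cells replaced by their nearest on-plate
        value, so interpolation near the rim never mixes in zeros."""
        if not self.mask.all():
            _, (ii, jj) = ndimage.distance_transform_edt(
                ~self.mask, return_indices=True)
            return self.values[ii, jj]
        return self.values

    def _interpolator(self, key: str):
        if key not in self._interp:
            filled = self._filled()
            h = self.grid_spacing
            if key == "c":
                data = filled
            else:
                gy, gx = np.gradient(filled, h)
                data = gx if key == "gx" else gy
            self._interp[key] = RegularGridInterpolator(
                (self.ys, self.xs), data, method="linear",
                bounds_error=False, fill_value=None)
        return self._interp[key]

    def _check_inside(self, x, y) -> None:
        if self.plate_radius is not None:
            r = np.hypot(np.asarray(x, float), np.asarray(y, float))
            if np.any(r > self.plate_radius + 1e-9):
                bad = float(np.max(r))
                raise ValueError(
                    f"point at radius {bad:.2f} mm lies outside the plate "
                    f"(radius {self.plate_radius} mm)")
        else:
            xs, ys = self.xs, self.ys
            if (np.any(np.asarray(x) < xs[0]) or np.any(np.asarray(x) > xs[-1])
                    or np.any(np.asarray(y) < ys[0]) or np.any(np.asarray(y) > ys[-1])):
                raise ValueError("point outside the field grid")


def field_from_function(func, extent: float, grid_spacing: float = 1.0,
                        plate_radius: float | None = None) -> ConcentrationField:
    """Build a field by evaluating ``func(x, y)`` on a square grid.

    Convenience for constructing analytic fields (uniform, planar,
    radial) in tests and examples.  ``extent`` is the half-width of the
    grid in mm; the mask is the disk of ``plate_radius`` (or the whole
    square if None).
    """
    xs = np.arange(-extent, extent + grid_spacing / 2, grid_spacing)
    xx, yy = np.meshgrid(xs, xs)
    values = np.asarray(func(xx, yy), dtype=float)
    if plate_radius is not None:
        mask = xx ** 2 + yy ** 2 <= plate_radius ** 2
    else:
        mask = np.ones_like(values, dtype=bool)
    values = np.where(mask, values, 0.0)
    return ConcentrationField(grid_spacing, (float(xs[0]), float(xs[0])),
                              values, mask, plate_radius=plate_radius)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def _diffuse(values: np.ndarray, mask: np.ndarray, h: float, diffusion_coeff: float,
             duration: float, dirichlet: np.ndarray | None = None,
             dirichlet_values: np.ndarray | None = None) -> np.ndarray:
    """Explicit FTCS diffusion on a masked grid with reflecting edges.

    Off-mask neighbours exchange nothing (zero flux), which makes the
    update a symmetric exchange between on-plate cells: total mass is
    conserved exactly when there are no Dirichlet cells.  The time step
    obeys dt <= h^2 / (4 D) for stability.
    """
    c = np.array(values, dtype=float)
    c[~mask] = 0.0
    dt_max = 0.9 * h * h / (4.0 * diffusion_coeff)
    n_steps = max(1, int(math.ceil(duration / dt_max)))
    dt = duration / n_steps
    alpha = diffusion_coeff * dt / (h * h)

    m = mask.astype(float)
    for _ in range(n_steps):
        lap = np.zeros_like(c)
        # four neighbours; an off-mask neighbour mirrors the centre (no flux)
        lap[1:, :] += m[:-1, :] * (c[:-1, :] - c[1:, :])
        lap[:-1, :] += m[1:, :] * (c[1:, :] - c[:-1, :])
        lap[:, 1:] += m[:, :-1] * (c[:, :-1] - c[:, 1:])
        lap[:, :-1] += m[:, 1:] * (c[:, 1:] - c[:, :-1])
        c += alpha * lap
        c[~mask] = 0.0
        if dirichlet is not None:
            c[dirichlet] = dirichlet_values[dirichlet]
    return c


def build_field(geometry: PlateGeometry,
                diffusion_coeff: float = DEFAULT_DIFFUSION,
                duration: float | None = None,
                grid_spacing: float = 0.5) -> ConcentrationField:
    """Diffuse salt from the block footprints for the equilibration period.

    Blocks with positive concentration are held at their concentration
    (Dirichlet disks); the plate rim is reflecting.  ``duration``
    defaults to the geometry's equilibration time (19 h).  Returns the
    field at the end of equilibration, which the assay then treats as
    static.  The default 0.5-mm grid resolves the steep rim of the
    source disk well enough that halving the spacing moves sampled
    concentrations by under 2%.
    """
    if diffusion_coeff <= 0:
        raise ValueError("diffusion_coeff must be positive")
    if duration is None:
        duration = geometry.equilibration_time
    if duration <= 0:
        raise ValueError("duration must be positive")

    h = grid_spacing
    r = geometry.plate_radius
    xs = np.arange(-r, r + h / 2, h)
    xx, yy = np.meshgrid(xs, xs)
    mask = xx ** 2 + yy ** 2 <= r ** 2

    dirichlet = np.zeros_like(mask)
    dval = np.zeros_like(xx)
    for (cx, cy), conc in ((geometry.block_center_a, geometry.conc_a),
                           (geometry.block_center_b, geometry.conc_b)):
        if conc <= 0:
            continue    # salt-free block is inert on a salt-free plate
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= geometry.block_radius ** 2
        dirichlet |= disk & mask
        dval[disk] = conc

    values = np.zeros_like(xx)
    values[dirichlet] = dval[dirichlet]
    if dirichlet.any():
        values = _diffuse(values, mask, h, diffusion_coeff, duration,
                          dirichlet, dval)
    return ConcentrationField(h, (float(xs[0]), float(xs[0])), values, mask,
                              timestamp=float(duration), plate_radius=r)


def evolve_field(field: ConcentrationField, diffusion_coeff: float,
                 duration: float) -> ConcentrationField:
    """Continue free diffusion with the sources removed (e.g. during the
    assay, after the blocks are lifted off)."""
    if diffusion_coeff <= 0 or duration <= 0:
        raise ValueError("diffusion_coeff and duration must be positive")
    values = _diffuse(field.values, field.mask, field.grid_spacing,
                      diffusion_coeff, duration)
    return ConcentrationField(field.grid_spacing, field.origin, values,
                              field.mask, field.timestamp + duration,
                              field.plate_radius)


def total_mass(field: ConcentrationField) -> float:
    """Spatial integral of C over the plate, mM * mm^2."""
    return float(field.values[field.mask].sum() * field.grid_spacing ** 2)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def concentration_at(field: ConcentrationField, x, y):
    """Bilinear interpolation of the field at (x, y); errors off-plate."""
    field._check_inside(x, y)
    pts = np.stack(np.broadcast_arrays(np.asarray(y, float),
                                       np.asarray(x, float)), axis=-1)
    out = field._interpolator("c")(pts)
    if np.isscalar(x) and np.isscalar(y):
        return float(np.asarray(out).item())
    return out


def gradient_at(field: ConcentrationField, x, y):
    """Central-difference spatial gradient (dC/dx, dC/dy), mM/mm."""
    field._check_inside(x, y)
    pts = np.stack(np.broadcast_arrays(np.asarray(y, float),
                                       np.asarray(x, float)), axis=-1)
    gx = field._interpolator("gx")(pts)
    gy = field._interpolator("gy")(pts)
    if np.isscalar(x) and np.isscalar(y):
        return float(np.asarray(gx).item()), float(np.asarray(gy).item())
    return np.stack([gx, gy], axis=-1)


def experienced_dCdt(field: ConcentrationField, track: Trajectory,
                     window: float = 10.0) -> np.ndarray:
    """Concentration change per second along the track, trailing-averaged.

    The instantaneous derivative (C_i - C_{i-1}) / dt is averaged over
    the preceding ``window`` seconds; samples before the window has
    filled are NaN.  This trailing average stands in for the cumulative
    concentration change that drives pirouette initiation.
    """
    if window < track.dt:
        raise ValueError("window must be at least one sampling interval")
    c = concentration_at(field, track.positions[:, 0], track.positions[:, 1])
    d = np.diff(c) / track.dt
    w = int(round(window / track.dt))
    out = np.full(track.n, np.nan)
    if d.size >= w:
        kernel = np.ones(w) / w
        out[w:] = np.convolve(d, kernel, mode="valid")
    return out


def experienced_dCdn(field: ConcentrationField, track: Trajectory) -> np.ndarray:
    """Signed gradient normal to the heading, mM/mm, per step.

    ``out[i]`` projects the gradient at sample i onto the left normal of
    the step i -> i+1; positive means concentration increases to the
    animal's left.  Zero-displacement steps and the final sample are NaN.
    """
    bearing, _, _ = heading_and_speed(track)
    grad = gradient_at(field, track.positions[:, 0], track.positions[:, 1])
    theta = np.radians(bearing)
    # left normal of (cos t, sin t) is (-sin t, cos t)
    with np.errstate(invalid="ignore"):
        out = -np.sin(theta) * grad[:, 0] + np.cos(theta) * grad[:, 1]
    return out
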