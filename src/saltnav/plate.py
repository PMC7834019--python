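"""Geometry of the two-spot salt-gradient chemotaxis assay plate.

The assay is run on a circular agar plate (8.5 cm diameter).  Two
cylindrical agar blocks -- one containing no NaCl (position A), one
containing 150 mM NaCl (position B) -- sit on the agar overnight and
establish a radial salt gradient around position B.  Animals are placed
at the plate centre and scored at the end of the assay by counting how
many sit within a 20-mm disk around each block position (areas A and B)
and how many never left an ellipse around the start point (area O).

All coordinates are in millimetres with the plate centre at the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field


@dataclass(frozen=True)
class PlateGeometry:
    """Physical layout of the assay plate and scoring regions.

    Parameters
    ----------
    plate_radius:
        Radius of the agar surface, mm (8.5-cm plate).
    agar_thickness:
        Thickness of the background agar layer, mm.
    block_radius, block_thickness:
        Radius and thickness of the two cylindrical salt blocks, mm
        (14.5 mm diameter cylinders).
    block_center_a, block_center_b:
        Positions of the block centres, mm.  The exact A--B separation is
        an assay-rig choice; the default places them symmetrically at
        +/-26 mm on the x axis.
    conc_a, conc_b:
        NaCl concentration of each block, mM.
    equilibration_time:
        How long the blocks sit on the plate before the assay, s
        (default 19 h).
    area_radius:
        Radius of the endpoint scoring disks around each block centre, mm.
    start_ellipse_radii:
        Semi-axes of the start region ellipse (major axis along the A--B
        axis), mm.
    """

    plate_radius: float = 42.5
    agar_thickness: float = 1.76
    block_radius: float = 7.25
    block_thickness: float = 5.3
    block_center_a: tuple[float, float] = (-26.0, 0.0)
    block_center_b: tuple[float, float] = (26.0, 0.0)
    conc_a: float = 0.0
    conc_b: float = 150.0
    equilibration_time: float = 68400.0
    area_radius: float = 20.0
    start_ellipse_radii: tuple[float, float] = (20.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("plate_radius", "agar_thickness", "block_radius",
                     "block_thickness", "area_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.conc_a < 0 or self.conc_b < 0:
            raise ValueError("block concentrations must be non-negative")
        if min(self.start_ellipse_radii) <= 0:
            raise ValueError("start_ellipse_radii must be positive")
        for label, (cx, cy) in (("A", self.block_center_a), ("B", self.block_center_b)):
            if math.hypot(cx, cy) + self.block_radius > self.plate_radius + 1e-9:
                raise ValueError(f"block {label} does not fit inside the plate")
        ax, ay = self.block_center_a
        bx, by = self.block_center_b
        if math.hypot(bx - ax, by - ay) < 2 * self.block_radius:
            raise ValueError("agar blocks overlap")

    # -- region membership (strict interior: inside means distance < radius) --

    def contains(self, x: float, y: float) -> bool:
        """True if (x, y) lies on the plate (closed disk)."""
        return math.hypot(x, y) <= self.plate_radius

    def in_area_a(self, x: float, y: float) -> bool:
        ax, ay = self.block_center_a
        return math.hypot(x - ax, y - ay) < self.area_radius

    def in_area_b(self, x: float, y: float) -> bool:
        bx, by = self.block_center_b
        return math.hypot(x - bx, y - by) < self.area_radius

    def ab_axis(self) -> tuple[float, float]:
        """Unit vector from block A towards block B."""
        ax, ay = self.block_center_a
        bx, by = self.block_center_b
        d = math.hypot(bx - ax, by - ay)
        return ((bx - ax) / d, (by - ay) / d)

    def in_start_ellipse(self, x: float, y: float) -> bool:
        """True inside the start-region ellipse centred on the plate origin.

        The major axis is aligned with the A--B axis; membership is the
        strict interior (u/ra)^2 + (v/rb)^2 < 1.
        """
        ex, ey = self.ab_axis()
        u = x * ex + y * ey          # along A--B axis
        v = -x * ey + y * ex         # perpendicular
        ra, rb = self.start_ellipse_radii
        return (u / ra) ** 2 + (v / rb) ** 2 < 1.0

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_center_a"] = list(self.block_center_a)
        d["block_center_b"] = list(self.block_center_b)
        d["start_ellipse_radii"] = list(self.start_ellipse_radii)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlateGeometry":
        d = dict(d)
        for key in ("block_center_a", "block_center_b", "start_ellipse_radii"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
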