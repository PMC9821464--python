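"""Simulation-cell descriptions: planar slab and cylinder-in-box.

The planar slab is periodic in x and y and bounded by repulsive walls at
``z = 0`` (the grafting surface) and ``z = Lz``.  The cylinder geometry places
an inside-grafted cylinder of radius ``R`` with its axis along x at the centre
of a fully periodic box; the cylinder surface repels monomers but is
transparent to nanoparticles (a smooth, species-selective stand-in for a
permeable atomistic wall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PLANAR = "planar_slab"
CYLINDER = "cylinder_in_box"


@dataclass(frozen=True)
class Geometry:
    kind: str
    box: tuple[float, float, float]
    sigma_g: float
    R: float | None = None
    wall_eps: float = 1.0

    def __post_init__(self):
        if self.kind not in (PLANAR, CYLINDER):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.kind == CYLINDER:
            if self.R is None or self.R <= 0:
                raise ValueError("cylinder geometry requires R > 0")
            if min(self.box[1], self.box[2]) <= 2 * self.R:
                raise ValueError("box cross-section must exceed the cylinder diameter")

    @property
    def periodic(self) -> np.ndarray:
        """Periodicity flags per Cartesian direction."""
        if self.kind == PLANAR:
            return np.array([True, True, False])
        return np.array([True, True, True])

    @property
    def L_cyl(self) -> float:
        """Cylinder length: the periodic box length along the axis (x)."""
        if self.kind != CYLINDER:
            raise AttributeError("L_cyl is only defined for cylinder geometry")
        return self.box[0]

    @property
    def axis_center(self) -> tuple[float, float]:
        """(y, z) coordinates of the cylinder axis."""
        if self.kind != CYLINDER:
            raise AttributeError("axis_center is only defined for cylinder geometry")
        return self.box[1] / 2.0, self.box[2] / 2.0

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def grafting_area(self) -> float:
        """Area of the surface chains are grafted to."""
        if self.kind == PLANAR:
            return self.box[0] * self.box[1]
        return 2.0 * np.pi * self.R * self.L_cyl

    def radial_distance(self, positions: np.ndarray) -> np.ndarray:
        """Distance from the cylinder axis for an (n, 3) position array."""
        cy, cz = self.axis_center
        return np.hypot(positions[..., 1] - cy, positions[..., 2] - cz)

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap coordinates into the primary cell along periodic directions."""
        out = np.array(positions, dtype=float, copy=True)
        box = np.asarray(self.box)
        for d in range(3):
            if self.periodic[d]:
                out[..., d] -= box[d] * np.floor(out[..., d] / box[d])
        return out

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied to displacement vectors."""
        out = np.array(dr, dtype=float, copy=True)
        box = np.asarray(self.box)
        for d in range(3):
            if self.periodic[d]:
                out[..., d] -= box[d] * np.round(out[..., d] / box[d])
        return out
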