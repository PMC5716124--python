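"""Voxelized attenuation phantoms for cone-beam CT image-quality studies.

Three phantom families are provided, mirroring the physical phantoms used in
megavoltage CBCT quality assurance:

* a cylindrical water phantom (default 22 cm diameter, 17 cm height) for
  uniformity and noise measurements;
* the same cylinder half filled with water, whose sharp water/air interface
  drives edge-spread-function resolution measurements;
* a pelvis-shaped slab phantom carrying cylindrical electron-density inserts
  arranged on a 12 cm diameter circle, for contrast-to-noise measurements.

At megavoltage energies attenuation is Compton dominated, so the linear
attenuation coefficient of a material is modelled as proportional to its
electron density relative to water (rED).  The water reference value is a
configurable constant (the physical value depends on the beam spectrum, which
is out of scope here).

Grid conventions: 2D transverse slices by default, row index -> y, column
index -> x, physical coordinates at voxel centres, the grid centre at the
isocentre, and half-open voxel membership (a voxel belongs to a region iff
its centre lies strictly inside).  Regeneration with identical parameters is
bit-identical; the generators use no randomness.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

#: Default linear attenuation of water, mm^-1.  Free model constant (order of
#: magnitude of the MV-range narrow-beam value); everything downstream is
#: relative to it.
DEFAULT_MU_WATER = 5.0e-3

AIR_LABEL = 0
WATER_LABEL = 1


class PhantomConfigurationError(ValueError):
    """Raised for geometrically impossible phantom requests."""


@dataclasses.dataclass(frozen=True)
class MaterialSpec:
    """A phantom material: name, relative electron density, attenuation.

    Parameters
    ----------
    name : str
        Region label used in the phantom label map.
    rED : float
        Electron density relative to water (water = 1, air = 0).
    mu : float
        Linear attenuation coefficient, mm^-1.
    """

    name: str
    rED: float
    mu: float

    def __post_init__(self) -> None:
        if self.rED < 0:
            raise ValueError(f"rED must be >= 0, got {self.rED}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if (self.mu == 0) != (self.rED == 0):
            raise ValueError(
                f"mu and rED must vanish together (got rED={self.rED}, mu={self.mu})"
            )


@dataclasses.dataclass(frozen=True)
class EdgeSpec:
    """A planar water/air interface inside a half-filled phantom.

    ``axis`` names the grid axis the interface is perpendicular to ('x' or
    'y'); ``position_mm`` is the coordinate of the interface plane.  Water
    occupies the side with coordinate below ``position_mm``.
    """

    axis: str = "y"
    position_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")


@dataclasses.dataclass
class VoxelPhantom:
    """A voxel grid of linear attenuation plus a ground-truth label map.

    Attributes
    ----------
    mu_grid : ndarray, shape (ny, nx)
        Linear attenuation, mm^-1.
    label_grid : ndarray of int, same shape
        Region identifiers; ``labels`` maps id -> region name.  Label 0 is
        always air and coincides exactly with mu == 0.
    spacing_mm : float
        Isotropic in-plane voxel size.
    origin_mm : tuple of float
        (x, y) coordinates of the centre of voxel (row 0, col 0).
    height_mm : float or None
        Physical axial extent the slice represents (metadata for extrusion).
    edge : EdgeSpec or None
        Present for half-filled phantoms.
    """

    mu_grid: np.ndarray
    label_grid: np.ndarray
    labels: dict[int, str]
    spacing_mm: float
    origin_mm: tuple[float, float]
    height_mm: float | None = None
    edge: EdgeSpec | None = None

    def __post_init__(self) -> None:
        self.mu_grid = np.asarray(self.mu_grid, dtype=float)
        self.label_grid = np.asarray(self.label_grid)
        if self.mu_grid.shape != self.label_grid.shape:
            raise ValueError("mu_grid and label_grid shapes differ")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        for lab_id in self.labels:
            if not np.any(self.label_grid == lab_id):
                raise ValueError(f"label {self.labels[lab_id]!r} has no voxels")
        air = self.label_grid == AIR_LABEL
        if not np.array_equal(air, self.mu_grid == 0):
            raise ValueError("air label must coincide exactly with mu == 0")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu_grid.shape

    def x_coords(self) -> np.ndarray:
        """x (mm) of each column centre."""
        return self.origin_mm[0] + self.spacing_mm * np.arange(self.shape[1])

    def y_coords(self) -> np.ndarray:
        """y (mm) of each row centre."""
        return self.origin_mm[1] + self.spacing_mm * np.arange(self.shape[0])

    def support_radius_mm(self) -> float:
        """Radius of the smallest iso-centred circle containing all non-air voxels."""
        rows, cols = np.nonzero(self.mu_grid > 0)
        if rows.size == 0:
            return 0.0
        x = self.origin_mm[0] + self.spacing_mm * cols
        y = self.origin_mm[1] + self.spacing_mm * rows
        return float(np.hypot(x, y).max() + self.spacing_mm / 2)

    def label_mask(self, name: str) -> np.ndarray:
        for lab_id, lab_name in self.labels.items():
            if lab_name == name:
                return self.label_grid == lab_id
        raise KeyError(name)

    def extrude(self, n_slices: int) -> np.ndarray:
        """Replicate the 2D slice into a (n_slices, ny, nx) stack."""
        if n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        return np.repeat(self.mu_grid[None, :, :], n_slices, axis=0)


# ---------------------------------------------------------------------------
# materials


def red_to_mu(red: float, mu_water: float = DEFAULT_MU_WATER) -> float:
    """Map relative electron density to linear attenuation (mm^-1).

    Compton-dominated proportionality: mu = rED * mu_water.
    """
    if red < 0:
        raise ValueError(f"rED must be >= 0, got {red}")
    if mu_water <= 0:
        raise ValueError(f"mu_water must be > 0, got {mu_water}")
    return red * mu_water


def default_insert_materials(mu_water: float = DEFAULT_MU_WATER) -> list[MaterialSpec]:
    """The four analysed pelvis-insert materials (muscle, trabecular bone,
    dense bone, lung at exhale) with their relative electron densities."""
    reds = {
        "muscle": 1.043,
        "trabecular_bone": 1.117,
        "dense_bone": 1.513,
        "lung_exhale": 0.459,
    }
    return [MaterialSpec(n, r, red_to_mu(r, mu_water)) for n, r in reds.items()]


# ---------------------------------------------------------------------------
# generators


def _centered_grid(extent_mm: float, spacing_mm: float) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Square grid of pixel-centre coordinates covering ±extent/2."""
    n = int(math.ceil(extent_mm / spacing_mm))
    idx = np.arange(n)
    coords = (idx - (n - 1) / 2.0) * spacing_mm
    x, y = np.meshgrid(coords, coords)  # row -> y, col -> x
    origin = (float(coords[0]), float(coords[0]))
    return x, y, origin


def make_cylinder_phantom(
    diameter_mm: float = 220.0,
    height_mm: float = 170.0,
    spacing_mm: float = 1.0,
    fill: str = "full",
    edge: EdgeSpec | None = None,
    mu_water: float = DEFAULT_MU_WATER,
    margin_mm: float = 10.0,
) -> VoxelPhantom:
    """Water cylinder phantom, optionally half filled.

    Parameters
    ----------
    fill : {'full', 'half'}
        'half' fills only the side of ``edge`` with coordinate below the
        interface position, producing a sharp water/air edge for resolution
        measurements.
    edge : EdgeSpec, optional
        Interface for the half fill; defaults to a plane through the centre,
        perpendicular to y.
    margin_mm : float
        Air margin around the cylinder in the generated grid.
    """
    if diameter_mm <= 0 or height_mm <= 0 or spacing_mm <= 0:
        raise ValueError("diameter, height and spacing must be positive")
    if spacing_mm > diameter_mm / 8:
        raise PhantomConfigurationError(
            f"spacing {spacing_mm} mm too coarse for a {diameter_mm} mm cylinder "
            "(need spacing <= diameter/8 to define ROIs)"
        )
    if fill not in ("full", "half"):
        raise ValueError(f"fill must be 'full' or 'half', got {fill!r}")

    x, y, origin = _centered_grid(diameter_mm + 2 * margin_mm, spacing_mm)
    radius = diameter_mm / 2.0
    inside = x**2 + y**2 < radius**2

    if fill == "half":
        if edge is None:
            edge = EdgeSpec(axis="y", position_mm=0.0)
        coord = y if edge.axis == "y" else x
        lo, hi = coord.min(), coord.max()
        if not (lo < edge.position_mm < hi):
            raise PhantomConfigurationError(
                f"edge position {edge.position_mm} mm outside grid extent [{lo}, {hi}]"
            )
        inside = inside & (coord < edge.position_mm)
    else:
        edge = None

    mu = np.where(inside, mu_water, 0.0)
    labels = np.where(inside, WATER_LABEL, AIR_LABEL).astype(np.int16)
    return VoxelPhantom(
        mu_grid=mu,
        label_grid=labels,
        labels={AIR_LABEL: "air", WATER_LABEL: "water"},
        spacing_mm=spacing_mm,
        origin_mm=origin,
        height_mm=height_mm,
        edge=edge,
    )


def make_pelvis_phantom(
    spacing_mm: float = 1.0,
    inserts: Sequence[MaterialSpec] | None = None,
    mu_water: float = DEFAULT_MU_WATER,
    semi_axes_mm: tuple[float, float] = (170.0, 120.0),
    thickness_mm: float = 50.0,
    pattern_diameter_mm: float = 120.0,
    insert_diameter_mm: float = 30.0,
    first_insert_angle_deg: float = 0.0,
    margin_mm: float = 10.0,
) -> VoxelPhantom:
    """Pelvis-shaped slab phantom with electron-density inserts.

    An elliptical water body (default semi-axes 170 x 120 mm, a simplified
    transverse pelvis outline) carries up to eight 3 cm diameter cylindrical
    inserts equally spaced on a circle of default diameter 12 cm around the
    centre.  ``inserts=None`` selects the four default materials; an empty
    list yields a uniform water slab.
    """
    if inserts is None:
        inserts = default_insert_materials(mu_water)
    if len(inserts) > 8:
        raise PhantomConfigurationError("at most 8 inserts fit the pattern")

    a, b = semi_axes_mm
    if a <= 0 or b <= 0 or spacing_mm <= 0:
        raise ValueError("semi-axes and spacing must be positive")

    x, y, origin = _centered_grid(2 * max(a, b) + 2 * margin_mm, spacing_mm)
    body = (x / a) ** 2 + (y / b) ** 2 < 1.0
    mu = np.where(body, mu_water, 0.0)
    labels = np.where(body, WATER_LABEL, AIR_LABEL).astype(np.int16)
    legend = {AIR_LABEL: "air", WATER_LABEL: "water"}

    n_ins = len(inserts)
    r_pat = pattern_diameter_mm / 2.0
    r_ins = insert_diameter_mm / 2.0
    centers = []
    for k in range(n_ins):
        ang = math.radians(first_insert_angle_deg + 360.0 * k / n_ins)
        centers.append((r_pat * math.cos(ang), r_pat * math.sin(ang)))
    for i in range(n_ins):
        for j in range(i + 1, n_ins):
            d = math.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < insert_diameter_mm:
                raise PhantomConfigurationError(
                    f"inserts {inserts[i].name!r} and {inserts[j].name!r} overlap "
                    f"(centre distance {d:.1f} mm < diameter {insert_diameter_mm} mm)"
                )

    for lab_id, (mat, (cx, cy)) in enumerate(zip(inserts, centers), start=2):
        disc = (x - cx) ** 2 + (y - cy) ** 2 < r_ins**2
        if not np.all(body[disc]):
            raise PhantomConfigurationError(
                f"insert {mat.name!r} extends outside the phantom body"
            )
        mu[disc] = mat.mu
        labels[disc] = lab_id
        legend[lab_id] = mat.name

    return VoxelPhantom(
        mu_grid=mu,
        label_grid=labels,
        labels=legend,
        spacing_mm=spacing_mm,
        origin_mm=origin,
        height_mm=thickness_mm,
    )


def insert_centers_mm(
    n_inserts: int,
    pattern_diameter_mm: float = 120.0,
    first_insert_angle_deg: float = 0.0,
) -> list[tuple[float, float]]:
    """Centre coordinates of the insert pattern (matches make_pelvis_phantom)."""
    r = pattern_diameter_mm / 2.0
    out = []
    for k in range(n_inserts):
        ang = math.radians(first_insert_angle_deg + 360.0 * k / n_inserts)
        out.append((r * math.cos(ang), r * math.sin(ang)))
    return out
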