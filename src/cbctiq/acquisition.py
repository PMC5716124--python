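"""Cone-beam acquisition simulation (desk scale: per-slice fan beam).

The simulator composes three steps per scan:

1. ``protocol_angles`` — the gantry positions at which the flat panel is
   triggered, from the protocol's arc and projection count;
2. ``forward_project`` — ideal line integrals of the phantom attenuation
   along each source-to-detector-pixel ray (sampled-ray rule with bilinear
   interpolation);
3. ``add_exposure_noise`` — Poisson photon-counting noise whose mean scales
   with the per-projection exposure (total MU / number of projections), plus
   optional zero-mean Gaussian electronic noise, clipped to the detector's
   bit-depth ceiling.

Angle conventions
-----------------
Gantry angles follow IEC 61217 (0 deg = source above the isocentre, i.e. on
the +y axis of the transverse slice).  The one conversion used everywhere is

    math_angle = 90 deg + gantry_angle

placing the source at ``SAD * (cos(math_angle), sin(math_angle))``; 'CW'
protocols increase the gantry angle.  The detector u axis points along
``(-sin(math_angle), cos(math_angle))``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

from .phantoms import VoxelPhantom

#: Zero-attenuation detector signal per pixel per MU.  Free detector-gain
#: calibration constant, set so that the 13.5 MU protocols reconstruct with
#: roughly 2% noise on the water phantom at desk scale (display-thickness
#: slabs) while the hottest per-projection exposure (0.135 MU) stays below
#: the 16-bit count ceiling.
DEFAULT_FLUENCE_PER_MU = 4.0e5


class TruncationError(ValueError):
    """Phantom extends beyond the detector's field of view."""


@dataclasses.dataclass(frozen=True)
class AcquisitionProtocol:
    """One scan protocol: arc, projection count, and total exposure."""

    name: str
    arc_start_deg: float
    arc_stop_deg: float
    arc_length_deg: float
    direction: str = "CW"
    n_projections: int = 200
    total_mu: float = 13.5
    inplane_field_cm: float = 27.4
    crossplane_field_cm: float = 27.4

    def __post_init__(self) -> None:
        if not 0 < self.arc_length_deg <= 360:
            raise ValueError(f"arc_length must be in (0, 360], got {self.arc_length_deg}")
        if self.direction not in ("CW", "CCW"):
            raise ValueError(f"direction must be CW or CCW, got {self.direction!r}")
        if self.n_projections < 2:
            raise ValueError("n_projections must be >= 2")
        if self.total_mu <= 0:
            raise ValueError("total_mu must be > 0")
        sign = 1.0 if self.direction == "CW" else -1.0
        stop = (self.arc_start_deg + sign * self.arc_length_deg) % 360.0
        if not np.isclose(stop, self.arc_stop_deg % 360.0, atol=1e-6):
            raise ValueError(
                f"inconsistent arc: start {self.arc_start_deg} + {self.direction} "
                f"{self.arc_length_deg} deg ends at {stop}, not {self.arc_stop_deg}"
            )

    @property
    def mu_per_projection(self) -> float:
        return self.total_mu / self.n_projections

    @property
    def sampling_rate_deg(self) -> float:
        return self.arc_length_deg / self.n_projections

    @property
    def is_short_scan(self) -> bool:
        return self.arc_length_deg < 360.0 - 1e-9


@dataclasses.dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam scan geometry with a flat detector.

    Defaults are the physical system values: 100 cm source-axis distance,
    1024 detector pixels at 0.4 mm pitch, 16-bit depth.  The source-detector
    distance is not published for this system; 1450 mm is a configurable
    stand-in.  Use :func:`desk_geometry` for the scaled-down defaults.
    """

    sad_mm: float = 1000.0
    sdd_mm: float = 1450.0
    detector_pixels: int = 1024
    pixel_pitch_mm: float = 0.4
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.sdd_mm > self.sad_mm > 0:
            raise ValueError("need sdd > sad > 0")
        if self.detector_pixels < 2 or self.pixel_pitch_mm <= 0:
            raise ValueError("invalid detector configuration")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    def u_coords_mm(self) -> np.ndarray:
        """Detector pixel-centre coordinates along the row, mm."""
        n = self.detector_pixels
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch_mm

    @property
    def u_half_mm(self) -> float:
        return self.detector_pixels * self.pixel_pitch_mm / 2.0

    @property
    def fan_angle_deg(self) -> float:
        """Full fan angle subtended by the detector row."""
        return float(2.0 * np.degrees(np.arctan(self.u_half_mm / self.sdd_mm)))

    @property
    def fov_radius_mm(self) -> float:
        """Radius at isocentre covered from every view (tangent criterion)."""
        return float(self.sad_mm * np.sin(np.arctan(self.u_half_mm / self.sdd_mm)))

    @property
    def count_ceiling(self) -> float:
        return float(2**self.bit_depth - 1)


def desk_geometry() -> ScanGeometry:
    """Scaled-down geometry: 512-pixel row at 1.0 mm pitch.

    The widened pitch keeps the isocentre field of view (~174 mm radius)
    large enough that the default pelvis phantom is not truncated.
    """
    return ScanGeometry(detector_pixels=512, pixel_pitch_mm=1.0)


@dataclasses.dataclass
class ProjectionSet:
    """A stack of detector frames with their gantry angles and exposure."""

    frames: np.ndarray  # (n_angles, n_det) detector counts (noisy or expected)
    angles_deg: np.ndarray
    mu_per_frame: float
    fluence_per_mu: float
    geometry: ScanGeometry
    protocol: AcquisitionProtocol | None = None
    seed: int | None = None
    noisy: bool = True

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.shape[0] != self.angles_deg.shape[0]:
            raise ValueError("frame count must match angle count")
        if np.any(self.frames < 0):
            raise ValueError("detector counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def total_mu(self) -> float:
        return self.mu_per_frame * self.n_frames

    def log_line_integrals(self, floor_counts: float = 0.5) -> np.ndarray:
        """Estimated line integrals ln(N0 / counts), zero counts floored.

        The floor (default 0.5 counts) avoids infinities behind heavy
        attenuation; for noiseless expected-count frames the transform is
        exact.
        """
        n0 = self.fluence_per_mu * self.mu_per_frame
        counts = np.maximum(self.frames, floor_counts)
        return np.log(n0 / counts)


# ---------------------------------------------------------------------------
# angles


def gantry_to_math_deg(gantry_deg):
    """IEC 61217 gantry angle -> math angle of the source position."""
    return 90.0 + np.asarray(gantry_deg, dtype=float)


def protocol_angles(protocol: AcquisitionProtocol) -> np.ndarray:
    """Equally spaced gantry angles spanning the protocol's arc.

    The first angle sits at the arc start; spacing is arc_length / n, so a
    full 360 deg scan does not duplicate its endpoint.  Short-scan arcs that
    would carry the gantry through the 180 deg line (blocked on a real couch)
    only warn — the simulator has no couch.
    """
    step = protocol.sampling_rate_deg
    sign = 1.0 if protocol.direction == "CW" else -1.0
    angles = protocol.arc_start_deg + sign * step * np.arange(protocol.n_projections)
    if protocol.is_short_scan:
        t0 = (sign * (180.0 - protocol.arc_start_deg)) % 360.0
        if 0.0 < t0 < protocol.arc_length_deg:
            warnings.warn(
                f"protocol {protocol.name!r}: arc crosses the gantry 180 deg line",
                stacklevel=2,
            )
    return angles


# ---------------------------------------------------------------------------
# forward projection


def _check_truncation(phantom: VoxelPhantom, geometry: ScanGeometry, allow: bool) -> None:
    r_sup = phantom.support_radius_mm()
    r_fov = geometry.fov_radius_mm
    if r_sup > r_fov:
        msg = (
            f"phantom support radius {r_sup:.1f} mm exceeds the detector field of "
            f"view ({r_fov:.1f} mm at isocentre); lateral truncation by "
            f"{r_sup - r_fov:.1f} mm"
        )
        if allow:
            warnings.warn(msg, stacklevel=3)
        else:
            raise TruncationError(msg)


def forward_project(
    phantom: VoxelPhantom,
    geometry: ScanGeometry,
    angle_deg: float,
    step_fraction: float = 0.5,
    allow_truncation: bool = False,
) -> np.ndarray:
    """Line integrals of mu along each source->detector-pixel ray at one angle.

    Rays are sampled at ``step_fraction * voxel spacing`` with bilinear
    interpolation of the attenuation grid; the result is dimensionless
    (mm^-1 times mm).
    """
    return project_angles(
        phantom, geometry, [angle_deg], step_fraction, allow_truncation
    )[0]


def project_angles(
    phantom: VoxelPhantom,
    geometry: ScanGeometry,
    angles_deg: Sequence[float],
    step_fraction: float = 0.5,
    allow_truncation: bool = False,
) -> np.ndarray:
    """Ideal projections for a list of gantry angles, shape (n_angles, n_det)."""
    _check_truncation(phantom, geometry, allow_truncation)
    sad, sdd = geometry.sad_mm, geometry.sdd_mm
    u = geometry.u_coords_mm()
    spacing = phantom.spacing_mm
    ny, nx = phantom.shape

    # sampling window: fixed chord around the closest approach to isocentre,
    # long enough to cover the grid's circumscribed circle from any direction
    half_x = max(abs(phantom.origin_mm[0]), abs(phantom.origin_mm[0] + spacing * (nx - 1)))
    half_y = max(abs(phantom.origin_mm[1]), abs(phantom.origin_mm[1] + spacing * (ny - 1)))
    r_grid = float(np.hypot(half_x, half_y)) + spacing
    step = step_fraction * spacing
    n_steps = int(np.ceil(2 * r_grid / step))
    step = 2 * r_grid / n_steps

    out = np.empty((len(angles_deg), u.size), dtype=float)
    mu = np.ascontiguousarray(phantom.mu_grid)
    for i, g in enumerate(angles_deg):
        phi = np.radians(gantry_to_math_deg(g))
        c, s = np.cos(phi), np.sin(phi)
        src = np.array([sad * c, sad * s])
        det_center = np.array([(sad - sdd) * c, (sad - sdd) * s])
        e = np.array([-s, c])
        pix = det_center[None, :] + u[:, None] * e[None, :]  # (n_det, 2)
        d = pix - src[None, :]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        # distance along each ray to the closest approach to the origin
        t_mid = -(src[None, :] * d).sum(axis=1)
        t = t_mid[None, :] + (np.arange(n_steps) + 0.5)[:, None] * step - r_grid
        px = src[0] + t * d[None, :, 0]  # (n_steps, n_det)
        py = src[1] + t * d[None, :, 1]
        rows = (py - phantom.origin_mm[1]) / spacing
        cols = (px - phantom.origin_mm[0]) / spacing
        vals = ndimage.map_coordinates(
            mu, [rows.ravel(), cols.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(n_steps, -1)
        out[i] = vals.sum(axis=0) * step
    np.clip(out, 0.0, None, out=out)
    return out


# ---------------------------------------------------------------------------
# noise


def apply_detector_blur(
    expected_counts: np.ndarray, geometry: ScanGeometry, sigma_mm: float
) -> np.ndarray:
    """Gaussian detector point-spread function along the detector row.

    Models the optical spread of the scintillator/photodiode panel (glare),
    which dominates the spatial resolution of megavoltage flat-panel
    imaging.  Acts on the expected fluence, before photon counting.
    ``sigma_mm`` is measured at the detector plane.
    """
    if sigma_mm < 0:
        raise ValueError("blur sigma must be >= 0")
    if sigma_mm == 0:
        return expected_counts
    return ndimage.gaussian_filter1d(
        expected_counts, sigma_mm / geometry.pixel_pitch_mm, axis=-1, mode="nearest"
    )


def add_exposure_noise(
    ideal: np.ndarray,
    protocol: AcquisitionProtocol,
    geometry: ScanGeometry,
    angles_deg: np.ndarray,
    fluence_per_mu: float = DEFAULT_FLUENCE_PER_MU,
    seed: int | None = 0,
    electronic_noise_sd: float = 0.0,
    detector_blur_sigma_mm: float = 0.0,
) -> ProjectionSet:
    """Draw noisy detector counts for ideal line-integral profiles.

    Expected counts per pixel are ``fluence_per_mu * mu_per_projection *
    exp(-line integral)``, optionally spread by the detector PSF; realised
    counts are Poisson with that mean, plus optional zero-mean Gaussian
    electronic noise, clipped to the detector's bit-depth ceiling (with a
    saturation warning when the mean itself exceeds the ceiling).
    """
    if fluence_per_mu <= 0:
        raise ValueError("fluence_per_mu must be > 0")
    ideal = np.asarray(ideal, dtype=float)
    expected = fluence_per_mu * protocol.mu_per_projection * np.exp(-ideal)
    expected = apply_detector_blur(expected, geometry, detector_blur_sigma_mm)
    ceiling = geometry.count_ceiling
    n_sat = int(np.count_nonzero(expected > ceiling))
    if n_sat:
        warnings.warn(
            f"detector saturation: {n_sat} pixels with expected counts above "
            f"the {geometry.bit_depth}-bit ceiling were clipped",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    if electronic_noise_sd > 0:
        counts += rng.normal(0.0, electronic_noise_sd, size=counts.shape)
    np.clip(counts, 0.0, ceiling, out=counts)
    return ProjectionSet(
        frames=counts,
        angles_deg=np.asarray(angles_deg, dtype=float),
        mu_per_frame=protocol.mu_per_projection,
        fluence_per_mu=fluence_per_mu,
        geometry=geometry,
        protocol=protocol,
        seed=seed,
        noisy=True,
    )


def simulate_scan(
    phantom: VoxelPhantom,
    protocol: AcquisitionProtocol,
    geometry: ScanGeometry | None = None,
    fluence_per_mu: float = DEFAULT_FLUENCE_PER_MU,
    seed: int | None = 0,
    noiseless: bool = False,
    step_fraction: float = 0.5,
    electronic_noise_sd: float = 0.0,
    detector_blur_sigma_mm: float = 0.0,
    allow_truncation: bool = False,
    ideal: np.ndarray | None = None,
) -> ProjectionSet:
    """Full scan simulation: angles -> forward projection -> exposure noise.

    ``noiseless=True`` returns the expected counts exactly.  ``ideal`` allows
    reusing precomputed line integrals (e.g. across noise realisations).
    Deterministic given ``seed``.
    """
    if geometry is None:
        geometry = desk_geometry()
    angles = protocol_angles(protocol)
    if ideal is None:
        ideal = project_angles(phantom, geometry, angles, step_fraction, allow_truncation)
    if noiseless:
        expected = fluence_per_mu * protocol.mu_per_projection * np.exp(-ideal)
        expected = apply_detector_blur(expected, geometry, detector_blur_sigma_mm)
        return ProjectionSet(
            frames=expected,
            angles_deg=angles,
            mu_per_frame=protocol.mu_per_projection,
            fluence_per_mu=fluence_per_mu,
            geometry=geometry,
            protocol=protocol,
            seed=None,
            noisy=False,
        )
    return add_exposure_noise(
        ideal, protocol, geometry, angles, fluence_per_mu, seed,
        electronic_noise_sd, detector_blur_sigma_mm,
    )


# ---------------------------------------------------------------------------
# protocol table I/O


def load_protocols(path=None) -> list[AcquisitionProtocol]:
    """Load acquisition protocols from YAML (default: the packaged table of
    the nine study protocols)."""
    if path is None:
        ref = importlib.resources.files("cbctiq.data") / "protocols.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [AcquisitionProtocol(**{**row, "name": str(row["name"])}) for row in raw["protocols"]]


def study_protocols() -> list[AcquisitionProtocol]:
    """The nine packaged study protocols."""
    return load_protocols()
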