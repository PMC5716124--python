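"""ROI-based image-quality metrics: uniformity, noise, and CNR.

The three metrics operate on reconstructed transverse slices with circular
and ring-shaped regions of interest placed from ground-truth phantom
geometry (no segmentation step):

* uniformity  = [1 - |mean(centre) - mean(periphery)| /
                     (mean(water) - mean(air))] x 100       (percent)
* noise       = stdev(water) / (mean(water) - mean(air)) x 100  (percent)
* CNR         = |mean(insert) - mean(background)| /
                (0.5 * (stdev(insert) + stdev(background)))  (dimensionless)

Standard deviations are sample (n-1) throughout.  Metrics are aggregated
over consecutive slices (default six) as mean and sample SD.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

MIN_ROI_PIXELS = 25


@dataclasses.dataclass(frozen=True)
class CircleROI:
    center_mm: tuple[float, float]  # (x, y)
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")

    @property
    def max_radius_mm(self) -> float:
        return float(np.hypot(*self.center_mm) + self.diameter_mm / 2)


@dataclasses.dataclass(frozen=True)
class RingROI:
    center_mm: tuple[float, float]
    inner_diameter_mm: float
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("ring thickness must be positive")
        if self.inner_diameter_mm < 0:
            raise ValueError("inner diameter must be >= 0")

    @property
    def max_radius_mm(self) -> float:
        return float(np.hypot(*self.center_mm) + self.inner_diameter_mm / 2 + self.thickness_mm)


@dataclasses.dataclass(frozen=True)
class ROIStats:
    mean: float
    stdev: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < MIN_ROI_PIXELS:
            raise ValueError(
                f"ROI has {self.n_pixels} pixels; need >= {MIN_ROI_PIXELS} for "
                "meaningful statistics"
            )
        if self.stdev < 0:
            raise ValueError("stdev must be >= 0")


@dataclasses.dataclass(frozen=True)
class SliceMetric:
    """A metric evaluated per slice with its across-slice mean and SD."""

    per_slice: tuple[float, ...]
    mean: float
    sd: float


def pixel_center_coords(shape: tuple[int, int], pixel_size_mm: float):
    """(X, Y) mm coordinate grids for an iso-centred image (row -> y)."""
    ny, nx = shape
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_mm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size_mm
    return np.meshgrid(xs, ys)


def roi_mask(
    roi: CircleROI | RingROI,
    shape: tuple[int, int],
    pixel_size_mm: float,
    check_inside: bool = True,
) -> np.ndarray:
    """Boolean pixel mask of an ROI (centre-in-region rule).

    With ``check_inside`` the ROI must fit inside the grid's inscribed
    circle — the region the reconstruction actually fills.
    """
    if check_inside:
        grid_radius = min(shape) * pixel_size_mm / 2.0
        if roi.max_radius_mm > grid_radius + 1e-9:
            raise ValueError(
                f"ROI extends to {roi.max_radius_mm:.1f} mm, outside the "
                f"{grid_radius:.1f} mm reconstruction circle"
            )
    X, Y = pixel_center_coords(shape, pixel_size_mm)
    cx, cy = roi.center_mm
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    if isinstance(roi, CircleROI):
        mask = r2 <= (roi.diameter_mm / 2.0) ** 2
    else:
        r_in = roi.inner_diameter_mm / 2.0
        r_out = r_in + roi.thickness_mm
        mask = (r2 > r_in**2) & (r2 <= r_out**2)
    if not mask.any():
        raise ValueError("ROI mask is empty at this grid resolution")
    return mask


def roi_stats(image: np.ndarray, mask: np.ndarray) -> ROIStats:
    """Mean and sample standard deviation of the pixels under a mask."""
    vals = np.asarray(image, dtype=float)[mask]
    return ROIStats(
        mean=float(vals.mean()),
        stdev=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_pixels=int(vals.size),
    )


def _water_air_denominator(image, water_mask, air_mask) -> tuple[float, float]:
    mw = float(np.asarray(image, dtype=float)[water_mask].mean())
    ma = float(np.asarray(image, dtype=float)[air_mask].mean())
    denom = mw - ma
    if denom <= 0:
        raise ValueError(
            f"water-air contrast is non-positive ({denom:.3g}): inverted or "
            "broken reconstruction"
        )
    return mw, ma


def uniformity(
    image: np.ndarray,
    center_mask: np.ndarray,
    periphery_mask: np.ndarray,
    water_mask: np.ndarray,
    air_mask: np.ndarray,
) -> float:
    """Percent uniformity: centre-vs-periphery flatness normalised by the
    water-air contrast."""
    mw, ma = _water_air_denominator(image, water_mask, air_mask)
    image = np.asarray(image, dtype=float)
    mc = float(image[center_mask].mean())
    mp = float(image[periphery_mask].mean())
    return (1.0 - abs(mc - mp) / (mw - ma)) * 100.0


def noise_metric(image: np.ndarray, water_mask: np.ndarray, air_mask: np.ndarray) -> float:
    """Percent noise: water-ROI standard deviation normalised by the
    water-air contrast.  Invariant under linear rescaling of the image."""
    mw, ma = _water_air_denominator(image, water_mask, air_mask)
    sd = float(np.asarray(image, dtype=float)[water_mask].std(ddof=1))
    return sd / (mw - ma) * 100.0


def cnr(image: np.ndarray, insert_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio with the averaged-SD denominator."""
    ins = roi_stats(image, insert_mask)
    bkg = roi_stats(image, background_mask)
    denom = 0.5 * (ins.stdev + bkg.stdev)
    if denom == 0:
        if ins.mean != bkg.mean:
            raise ValueError("noiseless input: both ROI standard deviations are zero")
        return 0.0
    return abs(ins.mean - bkg.mean) / denom


def aggregate_slices(values: Sequence[float], n_slices: int = 6) -> SliceMetric:
    """Mean and sample SD of a metric over consecutive slices."""
    vals = [float(v) for v in values]
    if len(vals) < n_slices:
        raise ValueError(f"need {n_slices} slices, got {len(vals)}")
    vals = vals[:n_slices]
    arr = np.array(vals)
    if n_slices == 1:
        warnings.warn("single-slice aggregate: SD undefined, reported as 0", stacklevel=2)
        return SliceMetric(per_slice=tuple(vals), mean=float(arr[0]), sd=0.0)
    return SliceMetric(per_slice=tuple(vals), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


# ---------------------------------------------------------------------------
# standard ROI sets


def standard_water_rois(phantom_diameter_mm: float = 220.0) -> dict[str, CircleROI | RingROI]:
    """The four-ROI set for the uniformity/noise water cylinder.

    Centre 2.5 cm circle, 2 cm thick peripheral ring (kept 5 mm clear of the
    phantom edge to avoid edge blur), 19 cm water circle, and a 2 cm thick
    air ring outside the phantom (5 mm clearance from the surface).
    """
    d = phantom_diameter_mm
    return {
        "center": CircleROI((0.0, 0.0), 25.0),
        "periphery": RingROI((0.0, 0.0), inner_diameter_mm=d - 50.0, thickness_mm=20.0),
        "water": CircleROI((0.0, 0.0), d - 30.0),
        "air": RingROI((0.0, 0.0), inner_diameter_mm=d + 10.0, thickness_mm=20.0),
    }


def insert_rois(
    center_mm: tuple[float, float],
    insert_name: str,
    insert_diameter_mm: float = 30.0,
) -> tuple[CircleROI, RingROI]:
    """Signal circle and concentric background ring for a CNR insert.

    The signal ROI is 2.5 cm in diameter (0.8 cm for the dense-bone insert,
    which is effectively smaller); the 1 cm thick background ring starts at
    the physical insert boundary.
    """
    signal_d = 8.0 if insert_name == "dense_bone" else 25.0
    return (
        CircleROI(center_mm, signal_d),
        RingROI(center_mm, inner_diameter_mm=insert_diameter_mm, thickness_mm=10.0),
    )


def water_roi_masks(shape, pixel_size_mm, phantom_diameter_mm: float = 220.0):
    """Masks for the standard water-phantom ROI set."""
    rois = standard_water_rois(phantom_diameter_mm)
    return {k: roi_mask(r, shape, pixel_size_mm) for k, r in rois.items()}
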