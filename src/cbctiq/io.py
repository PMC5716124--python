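"""File interchange: phantoms and volumes as TIFF + YAML sidecars,
projection sets as HDF5, and a DICOM CT series reader for the metrics-only
path on real scanner exports."""

from __future__ import annotations

import dataclasses
import os

import h5py
import numpy as np
import tifffile
import yaml

from .acquisition import AcquisitionProtocol, ProjectionSet, ScanGeometry
from .phantoms import EdgeSpec, VoxelPhantom
from .reconstruction import ReconVolume

# ---------------------------------------------------------------------------
# phantoms: multi-page TIFF (mu, labels) + YAML sidecar


def save_phantom(phantom: VoxelPhantom, base_path: str) -> tuple[str, str]:
    tif_path = base_path + ".tif"
    yaml_path = base_path + ".yaml"
    tifffile.imwrite(
        tif_path,
        [phantom.mu_grid.astype(np.float32), phantom.label_grid.astype(np.int16)],
        photometric="minisblack",
    )
    meta = {
        "spacing_mm": float(phantom.spacing_mm),
        "origin_mm": [float(v) for v in phantom.origin_mm],
        "height_mm": None if phantom.height_mm is None else float(phantom.height_mm),
        "labels": {int(k): v for k, v in phantom.labels.items()},
        "edge": None
        if phantom.edge is None
        else {"axis": phantom.edge.axis, "position_mm": float(phantom.edge.position_mm)},
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    return tif_path, yaml_path


def load_phantom(base_path: str) -> VoxelPhantom:
    with tifffile.TiffFile(base_path + ".tif") as tf:
        mu = tf.pages[0].asarray().astype(float)
        labels = tf.pages[1].asarray().astype(np.int16)
    with open(base_path + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    edge = None
    if meta.get("edge"):
        edge = EdgeSpec(axis=meta["edge"]["axis"], position_mm=meta["edge"]["position_mm"])
    return VoxelPhantom(
        mu_grid=mu,
        label_grid=labels,
        labels={int(k): v for k, v in meta["labels"].items()},
        spacing_mm=meta["spacing_mm"],
        origin_mm=tuple(meta["origin_mm"]),
        height_mm=meta.get("height_mm"),
        edge=edge,
    )


# ---------------------------------------------------------------------------
# projection sets: HDF5


def save_projections(scan: ProjectionSet, path: str) -> str:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frames", data=scan.frames)
        fh.create_dataset("angles_deg", data=scan.angles_deg)
        fh.attrs["mu_per_frame"] = scan.mu_per_frame
        fh.attrs["fluence_per_mu"] = scan.fluence_per_mu
        fh.attrs["noisy"] = scan.noisy
        if scan.seed is not None:
            fh.attrs["seed"] = scan.seed
        for k, v in dataclasses.asdict(scan.geometry).items():
            fh.attrs[f"geometry_{k}"] = v
        if scan.protocol is not None:
            for k, v in dataclasses.asdict(scan.protocol).items():
                fh.attrs[f"protocol_{k}"] = v
    return path


def load_projections(path: str) -> ProjectionSet:
    with h5py.File(path, "r") as fh:
        frames = fh["frames"][...]
        angles = fh["angles_deg"][...]
        geom_kwargs = {
            k[len("geometry_"):]: v.item() if hasattr(v, "item") else v
            for k, v in fh.attrs.items()
            if k.startswith("geometry_")
        }
        geom_kwargs["detector_pixels"] = int(geom_kwargs["detector_pixels"])
        geom_kwargs["bit_depth"] = int(geom_kwargs["bit_depth"])
        proto = None
        if any(k.startswith("protocol_") for k in fh.attrs):
            pk = {
                k[len("protocol_"):]: v.item() if hasattr(v, "item") else v
                for k, v in fh.attrs.items()
                if k.startswith("protocol_")
            }
            pk["name"] = str(pk["name"])
            pk["direction"] = str(pk["direction"])
            pk["n_projections"] = int(pk["n_projections"])
            proto = AcquisitionProtocol(**pk)
        return ProjectionSet(
            frames=frames,
            angles_deg=angles,
            mu_per_frame=float(fh.attrs["mu_per_frame"]),
            fluence_per_mu=float(fh.attrs["fluence_per_mu"]),
            geometry=ScanGeometry(**geom_kwargs),
            protocol=proto,
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
            noisy=bool(fh.attrs["noisy"]),
        )


# ---------------------------------------------------------------------------
# volumes: multi-page TIFF + YAML provenance sidecar


def save_volume(volume: ReconVolume, base_path: str) -> tuple[str, str]:
    tif_path = base_path + ".tif"
    yaml_path = base_path + ".yaml"
    tifffile.imwrite(tif_path, volume.slices.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_mm": float(volume.pixel_size_mm),
        "slice_thickness_mm": float(volume.slice_thickness_mm),
        "provenance": _plain(volume.provenance),
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    return tif_path, yaml_path


def load_volume(base_path: str) -> ReconVolume:
    slices = tifffile.imread(base_path + ".tif").astype(float)
    with open(base_path + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    return ReconVolume(
        slices=slices,
        pixel_size_mm=meta["pixel_size_mm"],
        slice_thickness_mm=meta["slice_thickness_mm"],
        provenance=meta.get("provenance") or {},
    )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# DICOM CT series (read-only, metrics path)


def read_dicom_series(directory: str) -> ReconVolume:
    """Read a directory of DICOM CT slices into a ReconVolume.

    Slices are ordered by InstanceNumber (falling back to file name) and the
    rescale slope/intercept is applied.  Intended for running the ROI and
    resolution metrics on real reconstructed phantom images.
    """
    import pydicom

    files = sorted(
        f for f in os.listdir(directory) if f.lower().endswith((".dcm", ".ima"))
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(os.path.join(directory, f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(float)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    first = datasets[0]
    pixel = float(first.PixelSpacing[0]) if hasattr(first, "PixelSpacing") else 1.0
    thickness = float(getattr(first, "SliceThickness", 1.0))
    return ReconVolume(
        slices=np.stack(slices),
        pixel_size_mm=pixel,
        slice_thickness_mm=thickness,
        provenance={"source": "dicom", "directory": str(directory)},
    )
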