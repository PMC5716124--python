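"""Protocol-sweep orchestration: simulate every acquisition protocol on the
three study phantoms, reconstruct, compute the image-quality report, and
render summary tables and figures.

Desk-scale study design
-----------------------
A single transverse slice of each phantom is simulated.  Analysis happens
on display-thickness slabs: each analysis slice averages
``round(display_thickness / slice_thickness)`` (default 5) independent
noise realisations of the thin-slice projections before reconstruction —
by linearity of filtered backprojection this equals reconstructing the thin
slices and bin-averaging them, since axial noise decorrelates between
slices on a real system.  Metrics averaged "over six consecutive slices"
use six such independent slabs; their mean and sample SD form the per-seed
SliceMetric.  The whole procedure is repeated over ``n_seeds`` independent
base realisations and reported as the seed-average.

Per-protocol seeds are derived by stable hashing of (base_seed, protocol,
phantom, seed index, slice index), so adding protocols or phantoms never
shifts existing results, and everything is deterministic given base_seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import roi_metrics
from .acquisition import (
    DEFAULT_FLUENCE_PER_MU,
    AcquisitionProtocol,
    ScanGeometry,
    add_exposure_noise,
    desk_geometry,
    project_angles,
    protocol_angles,
)
from .phantoms import (
    DEFAULT_MU_WATER,
    VoxelPhantom,
    insert_centers_mm,
    make_cylinder_phantom,
    make_pelvis_phantom,
)
from .reconstruction import ReconSettings, desk_settings, fbp_reconstruct
from .resolution import measure_f50
from .roi_metrics import SliceMetric, aggregate_slices, cnr, noise_metric, roi_mask, uniformity

DEFAULT_BASE_SEED = 20120105
DEFAULT_N_SEEDS = 10
DEFAULT_N_SLICES = 6

#: Detector point-spread sigma at the detector plane (mm).  About three
#: detector pixels, matching the broad optical spread (scintillator glare)
#: of megavoltage flat panels relative to their sampling pitch; this is the
#: mechanism that makes spatial resolution panel-limited rather than
#: view-sampling-limited.
DEFAULT_DETECTOR_BLUR_SIGMA_MM = 3.2


def derive_seed(*parts) -> int:
    """Stable sub-seed from arbitrary labelled parts (below 2^31)."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass(frozen=True)
class MetricSummary:
    """Seed-averaged metric: mean of per-seed six-slice means, the average
    six-slice SD, and the underlying per-seed values."""

    mean: float
    slice_sd: float
    per_seed_mean: tuple[float, ...]
    per_seed_sd: tuple[float, ...]

    @classmethod
    def from_slice_metrics(cls, metrics: Sequence[SliceMetric]) -> "MetricSummary":
        means = tuple(m.mean for m in metrics)
        sds = tuple(m.sd for m in metrics)
        return cls(
            mean=float(np.mean(means)),
            slice_sd=float(np.mean(sds)),
            per_seed_mean=means,
            per_seed_sd=sds,
        )


@dataclasses.dataclass
class IQReport:
    """Per-protocol image-quality report."""

    protocol: AcquisitionProtocol
    uniformity: MetricSummary | None = None
    noise: MetricSummary | None = None
    cnr_per_insert: dict[str, MetricSummary] = dataclasses.field(default_factory=dict)
    f50: MetricSummary | None = None
    n_seeds: int = 0
    n_slices: int = 0
    base_seed: int = 0
    fingerprint: str = ""
    error: str | None = None


def default_phantom_set(
    spacing_mm: float = 1.0, mu_water: float = DEFAULT_MU_WATER
) -> dict[str, VoxelPhantom]:
    """The three study phantoms: full water cylinder, half-filled cylinder,
    pelvis slab with four inserts."""
    return {
        "water": make_cylinder_phantom(spacing_mm=spacing_mm, mu_water=mu_water),
        "half": make_cylinder_phantom(spacing_mm=spacing_mm, fill="half", mu_water=mu_water),
        "pelvis": make_pelvis_phantom(spacing_mm=spacing_mm, mu_water=mu_water),
    }


def _fingerprint(*parts) -> str:
    return hashlib.sha256("|".join(str(p) for p in parts).encode()).hexdigest()[:16]


def _noisy_slices(
    ideal: np.ndarray,
    protocol: AcquisitionProtocol,
    geometry: ScanGeometry,
    angles: np.ndarray,
    settings: ReconSettings,
    fluence: float,
    seed_parts: tuple,
    n_slices: int,
    detector_blur_sigma_mm: float,
) -> list[np.ndarray]:
    """Reconstruct n_slices independent display-slab realisations.

    Each slab averages round(display/slice thickness) independent Poisson
    frame realisations before a single reconstruction (equivalent to thin-
    slice reconstruction followed by display binning, by FBP linearity).
    """
    bin_k = max(1, int(round(settings.display_thickness_mm / settings.slice_thickness_mm)))
    out = []
    for j in range(n_slices):
        frames = None
        scan = None
        for b in range(bin_k):
            scan = add_exposure_noise(
                ideal, protocol, geometry, angles, fluence,
                seed=derive_seed(*seed_parts, "slice", j, "thin", b),
                detector_blur_sigma_mm=detector_blur_sigma_mm,
            )
            frames = scan.frames if frames is None else frames + scan.frames
        scan.frames = frames / bin_k
        out.append(fbp_reconstruct(scan, settings).slices[0])
    return out


def run_protocol_sweep(
    protocols: Sequence[AcquisitionProtocol],
    phantoms: dict[str, VoxelPhantom] | None = None,
    geometry: ScanGeometry | None = None,
    settings: ReconSettings | None = None,
    n_seeds: int = DEFAULT_N_SEEDS,
    n_slices: int = DEFAULT_N_SLICES,
    base_seed: int = DEFAULT_BASE_SEED,
    fluence_per_mu: float = DEFAULT_FLUENCE_PER_MU,
    mu_water: float = DEFAULT_MU_WATER,
    detector_blur_sigma_mm: float = DEFAULT_DETECTOR_BLUR_SIGMA_MM,
) -> list[IQReport]:
    """Run the full image-quality study for a list of protocols.

    ``phantoms`` may contain any subset of the keys 'water' (uniformity and
    noise), 'half' (f50), and 'pelvis' (CNR per insert); metrics for missing
    phantoms are skipped.  A failure in one protocol is recorded in its
    report and does not abort the sweep.
    """
    if not protocols:
        raise ValueError("need at least one protocol")
    if phantoms is None:
        phantoms = default_phantom_set()
    if geometry is None:
        geometry = desk_geometry()
    if settings is None:
        settings = desk_settings()

    reports: list[IQReport] = []
    for proto in protocols:
        rep = IQReport(
            protocol=proto,
            n_seeds=n_seeds,
            n_slices=n_slices,
            base_seed=base_seed,
            fingerprint=_fingerprint(
                base_seed, n_seeds, n_slices, proto, geometry, settings, fluence_per_mu,
                detector_blur_sigma_mm, sorted(phantoms),
            ),
        )
        try:
            angles = protocol_angles(proto)
            if "water" in phantoms:
                ph = phantoms["water"]
                ideal = project_angles(ph, geometry, angles)
                masks = roi_metrics.water_roi_masks(
                    (settings.grid_size, settings.grid_size), settings.pixel_size_mm
                )
                uni_sm, noi_sm = [], []
                for si in range(n_seeds):
                    slices = _noisy_slices(
                        ideal, proto, geometry, angles, settings, fluence_per_mu,
                        (base_seed, proto.name, "water", si), n_slices,
                        detector_blur_sigma_mm,
                    )
                    uni_sm.append(aggregate_slices(
                        [uniformity(s, masks["center"], masks["periphery"],
                                    masks["water"], masks["air"]) for s in slices],
                        n_slices,
                    ))
                    noi_sm.append(aggregate_slices(
                        [noise_metric(s, masks["water"], masks["air"]) for s in slices],
                        n_slices,
                    ))
                rep.uniformity = MetricSummary.from_slice_metrics(uni_sm)
                rep.noise = MetricSummary.from_slice_metrics(noi_sm)

            if "half" in phantoms:
                ph = phantoms["half"]
                if ph.edge is None:
                    raise ValueError("'half' phantom carries no edge specification")
                ideal = project_angles(ph, geometry, angles)
                f50_sm = []
                for si in range(n_seeds):
                    slices = _noisy_slices(
                        ideal, proto, geometry, angles, settings, fluence_per_mu,
                        (base_seed, proto.name, "half", si), n_slices,
                        detector_blur_sigma_mm,
                    )
                    f50_sm.append(aggregate_slices(
                        [measure_f50(s, settings.pixel_size_mm, ph.edge) for s in slices],
                        n_slices,
                    ))
                rep.f50 = MetricSummary.from_slice_metrics(f50_sm)

            if "pelvis" in phantoms:
                ph = phantoms["pelvis"]
                ideal = project_angles(ph, geometry, angles)
                insert_names = [v for k, v in sorted(ph.labels.items()) if k >= 2]
                centers = insert_centers_mm(len(insert_names))
                shape = (settings.grid_size, settings.grid_size)
                masks = {}
                for name, ctr in zip(insert_names, centers):
                    sig, bkg = roi_metrics.insert_rois(ctr, name)
                    masks[name] = (
                        roi_mask(sig, shape, settings.pixel_size_mm),
                        roi_mask(bkg, shape, settings.pixel_size_mm),
                    )
                per_insert: dict[str, list[SliceMetric]] = {n: [] for n in insert_names}
                for si in range(n_seeds):
                    slices = _noisy_slices(
                        ideal, proto, geometry, angles, settings, fluence_per_mu,
                        (base_seed, proto.name, "pelvis", si), n_slices,
                        detector_blur_sigma_mm,
                    )
                    for name in insert_names:
                        sig_m, bkg_m = masks[name]
                        per_insert[name].append(aggregate_slices(
                            [cnr(s, sig_m, bkg_m) for s in slices], n_slices
                        ))
                rep.cnr_per_insert = {
                    n: MetricSummary.from_slice_metrics(v) for n, v in per_insert.items()
                }
        except Exception as exc:  # noqa: BLE001 - per-protocol isolation
            rep.error = f"{type(exc).__name__}: {exc}"
            warnings.warn(f"protocol {proto.name!r} failed: {rep.error}", stacklevel=2)
        reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# tables and figures


def reports_to_frame(reports: Sequence[IQReport]) -> pd.DataFrame:
    """Tidy per-protocol summary: one row per (protocol, metric, roi)."""
    rows = []
    for rep in reports:
        p = rep.protocol
        base = {
            "protocol": p.name,
            "arc_length_deg": p.arc_length_deg,
            "n_projections": p.n_projections,
            "total_mu": p.total_mu,
            "mu_per_projection": p.mu_per_projection,
            "sampling_rate_deg": p.sampling_rate_deg,
            "error": rep.error or "",
        }
        for metric, summary in (("uniformity", rep.uniformity), ("noise", rep.noise), ("f50", rep.f50)):
            if summary is not None:
                rows.append({**base, "metric": metric, "roi": "", "mean": summary.mean,
                             "slice_sd": summary.slice_sd})
        for name, summary in rep.cnr_per_insert.items():
            rows.append({**base, "metric": "cnr", "roi": name, "mean": summary.mean,
                         "slice_sd": summary.slice_sd})
        if rep.error and rep.uniformity is None and rep.f50 is None and not rep.cnr_per_insert:
            rows.append({**base, "metric": "", "roi": "", "mean": np.nan, "slice_sd": np.nan})
    return pd.DataFrame(rows)


def per_seed_frame(reports: Sequence[IQReport]) -> pd.DataFrame:
    """Per-seed metric values (for reproducibility checks)."""
    rows = []
    for rep in reports:
        items = [("uniformity", "", rep.uniformity), ("noise", "", rep.noise), ("f50", "", rep.f50)]
        items += [("cnr", n, s) for n, s in rep.cnr_per_insert.items()]
        for metric, roi, summary in items:
            if summary is None:
                continue
            for si, (m, sd) in enumerate(zip(summary.per_seed_mean, summary.per_seed_sd)):
                rows.append({"protocol": rep.protocol.name, "metric": metric, "roi": roi,
                             "seed_index": si, "mean": m, "slice_sd": sd})
    return pd.DataFrame(rows)


def render_report(reports: Sequence[IQReport], out_dir: str) -> dict[str, str]:
    """Write summary tables (CSV + JSON) and the three study figures.

    Figures: uniformity and noise vs total projections; CNR vs MU/projection
    (full-arc open markers, short-arc filled); f50 vs sampling rate.  Error
    bars are the six-slice SD.  Each figure gets a companion CSV holding
    exactly the plotted values.  Returns a name -> path map.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    df = reports_to_frame(reports)
    summary_csv = os.path.join(out_dir, "iq_summary.csv")
    df.to_csv(summary_csv, index=False, float_format="%.10g")
    paths["summary_csv"] = summary_csv

    seed_df = per_seed_frame(reports)
    seed_csv = os.path.join(out_dir, "iq_per_seed.csv")
    seed_df.to_csv(seed_csv, index=False, float_format="%.10g")
    paths["per_seed_csv"] = seed_csv

    summary_json = os.path.join(out_dir, "iq_summary.json")
    with open(summary_json, "w") as fh:
        json.dump(
            [
                {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in row.items()}
                for row in df.to_dict(orient="records")
            ],
            fh, indent=2,
        )
    paths["summary_json"] = summary_json

    ok = [r for r in reports if r.error is None]

    # uniformity / noise vs number of projections
    with_noise = [r for r in ok if r.noise is not None]
    if with_noise:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, metric in zip(axes, ("uniformity", "noise")):
            for r in with_noise:
                s = getattr(r, metric)
                marker = "o" if not r.protocol.is_short_scan else "s"
                ax.errorbar(r.protocol.n_projections, s.mean, yerr=s.slice_sd,
                            fmt=marker, capsize=3,
                            color="tab:blue" if not r.protocol.is_short_scan else "tab:red")
            ax.set_xlabel("total projections")
            ax.set_ylabel(f"{metric} (%)")
        fig.suptitle("full arc: circles, short arc: squares")
        fig.tight_layout()
        p = os.path.join(out_dir, "uniformity_noise_vs_projections.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["uniformity_noise_png"] = p
        rows = [
            {"protocol": r.protocol.name, "n_projections": r.protocol.n_projections,
             "metric": metric, "mean": getattr(r, metric).mean,
             "slice_sd": getattr(r, metric).slice_sd}
            for r in with_noise for metric in ("uniformity", "noise")
        ]
        p = os.path.join(out_dir, "uniformity_noise_vs_projections.csv")
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        paths["uniformity_noise_csv"] = p

    # CNR vs MU/projection
    with_cnr = [r for r in ok if r.cnr_per_insert]
    if with_cnr:
        inserts = sorted({n for r in with_cnr for n in r.cnr_per_insert})
        fig, ax = plt.subplots(figsize=(6, 4.5))
        colors = dict(zip(inserts, plt.rcParams["axes.prop_cycle"].by_key()["color"]))
        for r in with_cnr:
            short = r.protocol.is_short_scan
            for name in inserts:
                s = r.cnr_per_insert.get(name)
                if s is None:
                    continue
                ax.errorbar(
                    r.protocol.mu_per_projection, s.mean, yerr=s.slice_sd,
                    fmt="s" if short else "o", capsize=3, color=colors[name],
                    markerfacecolor=colors[name] if short else "none",
                )
        for name in inserts:
            ax.plot([], [], "o", color=colors[name], label=name)
        ax.set_xlabel("MU per projection")
        ax.set_ylabel("CNR")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = os.path.join(out_dir, "cnr_vs_mu_per_projection.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["cnr_png"] = p
        rows = [
            {"protocol": r.protocol.name,
             "mu_per_projection": r.protocol.mu_per_projection,
             "short_scan": r.protocol.is_short_scan, "insert": name,
             "mean": s_.mean, "slice_sd": s_.slice_sd}
            for r in with_cnr for name, s_ in r.cnr_per_insert.items()
        ]
        p = os.path.join(out_dir, "cnr_vs_mu_per_projection.csv")
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        paths["cnr_csv"] = p
    else:
        warnings.warn("no CNR results; CNR figure skipped", stacklevel=2)

    # f50 vs sampling rate
    with_f50 = [r for r in ok if r.f50 is not None]
    if with_f50:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for r in with_f50:
            ax.errorbar(r.protocol.sampling_rate_deg, r.f50.mean, yerr=r.f50.slice_sd,
                        fmt="s" if r.protocol.is_short_scan else "o", capsize=3,
                        color="tab:red" if r.protocol.is_short_scan else "tab:blue")
        ax.set_xlabel("sampling rate (deg/projection)")
        ax.set_ylabel("f50 (mm$^{-1}$)")
        fig.tight_layout()
        p = os.path.join(out_dir, "f50_vs_sampling_rate.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["f50_png"] = p
        rows = [
            {"protocol": r.protocol.name,
             "sampling_rate_deg": r.protocol.sampling_rate_deg,
             "mean": r.f50.mean, "slice_sd": r.f50.slice_sd}
            for r in with_f50
        ]
        p = os.path.join(out_dir, "f50_vs_sampling_rate.csv")
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        paths["f50_csv"] = p

    return paths
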