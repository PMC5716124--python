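"""Protocol-practicality arithmetic: per-projection exposure, sampling rate,
acquisition time, and projection-file storage.

These are the bookkeeping quantities a physicist weighs when choosing an
acquisition protocol besides reconstructed image quality.  Gantry speed is an
input, never derived: on the real system it is set by the control system to
accommodate detector readout and is not computable from first principles
here.

Storage uses MB = 10^6 bytes with truncation to an integer — the convention
consistent with the published file sizes for 100 and 200 projections (204 and
409 MB; note the published 360-projection figure of 738 MB appears rounded
up, this arithmetic gives 737).
"""

from __future__ import annotations

import dataclasses

import pandas as pd

#: Active pixels per detector side used for storage arithmetic (the flat
#: panel has 1024x1024 photodiodes of which 1012x1012 are active).
ACTIVE_PIXELS_PER_SIDE = 1012


@dataclasses.dataclass(frozen=True)
class LogisticsReport:
    protocol_name: str
    mu_per_projection: float
    sampling_rate_deg: float
    acquisition_time_s: float | None
    storage_mb: int

    def __post_init__(self) -> None:
        if self.mu_per_projection < 0 or self.sampling_rate_deg < 0 or self.storage_mb < 0:
            raise ValueError("logistics quantities must be nonnegative")
        if self.acquisition_time_s is not None and self.acquisition_time_s < 0:
            raise ValueError("acquisition time must be nonnegative")


def mu_per_projection(total_mu: float, n_projections: int) -> float:
    """Exposure per projection (MU) at fixed total scan exposure."""
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    if total_mu <= 0:
        raise ValueError("total_mu must be > 0")
    return total_mu / n_projections


def sampling_rate(arc_length_deg: float, n_projections: int) -> float:
    """Gantry degrees per projection."""
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    return arc_length_deg / n_projections


def acquisition_time(arc_length_deg: float, gantry_speed_deg_per_min: float) -> float:
    """Scan duration in seconds, reported to 0.1 s."""
    if gantry_speed_deg_per_min <= 0:
        raise ValueError("gantry speed must be > 0")
    return round(arc_length_deg / gantry_speed_deg_per_min * 60.0, 1)


def projection_storage_mb(
    n_projections: int,
    active_pixels_per_side: int = ACTIVE_PIXELS_PER_SIDE,
    bit_depth: int = 16,
) -> int:
    """Projection-set file size in MB (10^6 bytes, truncated)."""
    if n_projections < 0 or active_pixels_per_side <= 0 or bit_depth <= 0:
        raise ValueError("arguments must be positive (n_projections >= 0)")
    n_bytes = n_projections * active_pixels_per_side**2 * (bit_depth // 8)
    return int(n_bytes // 10**6)


def protocol_logistics(protocol, gantry_speed_deg_per_min: float | None = None) -> LogisticsReport:
    """Full logistics summary for one acquisition protocol."""
    return LogisticsReport(
        protocol_name=protocol.name,
        mu_per_projection=mu_per_projection(protocol.total_mu, protocol.n_projections),
        sampling_rate_deg=sampling_rate(protocol.arc_length_deg, protocol.n_projections),
        acquisition_time_s=(
            acquisition_time(protocol.arc_length_deg, gantry_speed_deg_per_min)
            if gantry_speed_deg_per_min is not None
            else None
        ),
        storage_mb=projection_storage_mb(protocol.n_projections),
    )


def logistics_table(protocols, gantry_speed_deg_per_min: float | None = None) -> pd.DataFrame:
    """Tidy table of logistics quantities for a list of protocols."""
    rows = []
    for p in protocols:
        rep = protocol_logistics(p, gantry_speed_deg_per_min)
        rows.append(
            {
                "protocol": rep.protocol_name,
                "arc_length_deg": p.arc_length_deg,
                "n_projections": p.n_projections,
                "total_mu": p.total_mu,
                "mu_per_projection": rep.mu_per_projection,
                "sampling_rate_deg": rep.sampling_rate_deg,
                "acquisition_time_s": rep.acquisition_time_s,
                "storage_mb": rep.storage_mb,
            }
        )
    return pd.DataFrame(rows)
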