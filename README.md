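# cbctiq

Simulation and image-quality analysis of megavoltage cone-beam CT
(MV-CBCT) acquisition protocols.

MV-CBCT images patients on the treatment couch with the linac's own
megavoltage beam and flat-panel imager. Its contrast is intrinsically
poor, so the question of whether the user-selectable acquisition
parameters — gantry arc length (360° full scan vs 200° short scan),
number of projections (100–600), and total exposure (13.5 vs 7.2 MU) —
buy any image quality matters for choosing a clinical protocol. This
package rebuilds that question as a reproducible synthetic study: it
simulates fan-beam scans of the standard quality-assurance phantoms under
nine acquisition protocols, reconstructs them with short-scan-aware
filtered backprojection, and computes the four phantom metrics

* **uniformity** `[1 − |m_centre − m_periphery| / (m_water − m_air)] × 100` (%),
* **noise** `s_water / (m_water − m_air) × 100` (%),
* **CNR** `|m_insert − m_background| / (½[s_insert + s_background])`,
* **f50**, the frequency at 50% modulation of the MTF, obtained from the
  edge spread function of a half-filled water phantom via
  ESF → LSF → Gaussian fit → `MTF(f) = exp(−2π²σ²f²)`,

where `m`/`s` are ROI means and sample standard deviations, each averaged
over six display slices — plus the protocol-logistics arithmetic
(MU/projection, sampling rate, acquisition time, projection storage) that
ends up deciding the protocol choice, since image quality turns out to be
essentially protocol-independent.

## Layout

```
src/cbctiq/        the library
  phantoms.py        voxel phantoms (water cylinder, half-filled, pelvis)
  acquisition.py     protocols, fan-beam forward projection, Poisson noise
  reconstruction.py  FBP with short-scan (sin² redundancy) weighting
  roi_metrics.py     uniformity / noise / CNR with the study's ROI geometry
  resolution.py      ESF → LSF → Gaussian → MTF → f50
  logistics.py       protocol practicality arithmetic
  driver.py          the nine-protocol sweep and report rendering
  io.py              TIFF/YAML, HDF5, DICOM-series reading
analysis/          numbered study scripts (each writes under results/)
scripts/acceptance.py  recomputes the headline numbers as JSON
docs/methods.md    the model, assumptions, and design choices
```

## Worked example

Simulate one full-scan protocol on the water cylinder and measure it:

```python
from cbctiq import (desk_geometry, desk_settings, fbp_reconstruct,
                    make_cylinder_phantom, simulate_scan, study_protocols,
                    noise_metric, uniformity)
from cbctiq.roi_metrics import water_roi_masks

protocol = study_protocols()[1]          # 360 projections, 13.5 MU, full arc
phantom  = make_cylinder_phantom()       # 22 cm water cylinder
scan     = simulate_scan(phantom, protocol, desk_geometry(), seed=1,
                         detector_blur_sigma_mm=3.2)
img      = fbp_reconstruct(scan, desk_settings()).slices[0]
masks    = water_roi_masks(img.shape, desk_settings().pixel_size_mm)
print(uniformity(img, masks["center"], masks["periphery"],
                 masks["water"], masks["air"]))
print(noise_metric(img, masks["water"], masks["air"]))
```

Running this (it is `analysis/02_single_scan_demo.py`) prints

```
protocol 2: 360 projections over 360 deg, 0.0375 MU each
uniformity: 99.97 %   noise: 3.66 % (single 1 mm slice)
```

— a uniformity within a tenth of a percent of ideal, and single-thin-slice
noise of 3.7% that drops to ~1.6% on the 4.8 mm display slabs the study
analyses (5 thin slices averaged, √5 noise reduction).
`analysis/04_resolution_chain.py` runs the resolution chain on the
half-filled phantom and prints

```
fitted LSF sigma: 2.416 mm
f50 (analytic Gaussian transform): 0.0776 mm^-1  = 0.776 lp/cm
f50 (numerical FFT cross-check):   0.0776 mm^-1
```

`analysis/03_protocol_sweep.py` runs the whole study (all nine protocols,
three phantoms) and writes tidy CSVs plus the three summary figures —
noise/uniformity vs projections, CNR vs MU/projection, f50 vs sampling
rate — under `results/sweep/`. With the default three repetitions it
prints (excerpt):

```
protocol  2 (360 deg, 360 proj, 13.5 MU): uniformity 99.85%, noise 1.63%, f50 0.0777/mm,
    CNR [muscle=1.91, trabecular_bone=4.80, dense_bone=11.35, lung_exhale=9.90]
protocol  6 (200 deg, 100 proj, 13.5 MU): uniformity 99.85%, noise 1.69%, f50 0.0775/mm,
    CNR [muscle=1.89, trabecular_bone=4.44, dense_bone=10.94, lung_exhale=9.60]
protocol  9 (360 deg, 360 proj,  7.2 MU): uniformity 99.85%, noise 2.23%, f50 0.0775/mm,
    CNR [muscle=1.44, trabecular_bone=3.69, dense_bone=10.01, lung_exhale=9.24]
```

The picture across all nine rows: uniformity and f50 are flat (the null
result — acquisition parameters barely matter), noise at fixed 13.5 MU
spans only 1.62–1.69% between 600 and 100 projections, the 7.2 MU scan is
noisier than its 13.5 MU twin by 2.23/1.63 ≈ √(13.5/7.2) ≈ 1.37, and CNR
tracks electron-density contrast. Logistics then favour the coarse short
scan: `analysis/01_protocol_logistics.py` tabulates 204 MB and 54.3 s for
the 100-projection short scan against 1228 MB for the 600-projection full
scan.

## Scope

Per-slice fan beam (no cone angle), monoenergetic Compton-proportional
attenuation, no scatter or beam hardening, and a configurable apodized
ramp in place of the vendor's unpublished kernel: absolute metric values
are not scanner-comparable; protocol-to-protocol comparisons are the
object of study. See `docs/methods.md` for the full model and its
assumptions.
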