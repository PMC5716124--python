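#!/usr/bin/env python
"""Protocol logistics: the practicality arithmetic behind choosing an
acquisition protocol.

For each of the nine study protocols this tabulates the exposure per
projection, the sampling rate, the acquisition time at the published gantry
speeds, and the projection-file storage.  The short scan with coarse
sampling wins on every logistic axis (fastest, smallest files, hottest
individual projections), which is the study's practical recommendation
given that image quality turned out protocol-independent.

Writes results/logistics.csv.
"""

import os

from cbctiq.acquisition import study_protocols
from cbctiq.logistics import acquisition_time, logistics_table

OUT_DIR = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    protocols = study_protocols()
    # gantry speed is measured on the machine, not derived; the published
    # values are 166 deg/min at 1 deg/projection and 221 deg/min at 2
    df = logistics_table(protocols)
    os.makedirs(OUT_DIR, exist_ok=True)
    path = os.path.join(OUT_DIR, "logistics.csv")
    df.to_csv(path, index=False, float_format="%.10g")

    print(df.to_string(index=False))
    print()
    print(f"short-scan acquisition time at 166 deg/min: {acquisition_time(200, 166)} s")
    print(f"short-scan acquisition time at 221 deg/min: {acquisition_time(200, 221)} s")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
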