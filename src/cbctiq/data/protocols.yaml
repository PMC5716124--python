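# The nine MV-CBCT acquisition protocols studied: arc geometry (gantry
# degrees, IEC 61217), number of projections, and total exposure (MU).
# Full scans run 180 -> 180 over 360 deg; short scans 270 -> 110 over 200 deg.
protocols:
  - {name: "1", arc_start_deg: 180, arc_stop_deg: 180, arc_length_deg: 360, direction: CW, n_projections: 180, total_mu: 13.5}
  - {name: "2", arc_start_deg: 180, arc_stop_deg: 180, arc_length_deg: 360, direction: CW, n_projections: 360, total_mu: 13.5}
  - {name: "3", arc_start_deg: 180, arc_stop_deg: 180, arc_length_deg: 360, direction: CW, n_projections: 400, total_mu: 13.5}
  - {name: "4", arc_start_deg: 180, arc_stop_deg: 180, arc_length_deg: 360, direction: CW, n_projections: 450, total_mu: 13.5}
  - {name: "5", arc_start_deg: 180, arc_stop_deg: 180, arc_length_deg: 360, direction: CW, n_projections: 600, total_mu: 13.5}
  - {name: "6", arc_start_deg: 270, arc_stop_deg: 110, arc_length_deg: 200, direction: CW, n_projections: 100, total_mu: 13.5}
  - {name: "7", arc_start_deg: 270, arc_stop_deg: 110, arc_length_deg: 200, direction: CW, n_projections: 200, total_mu: 13.5}
  - {name: "8", arc_start_deg: 270, arc_stop_deg: 110, arc_length_deg: 200, direction: CW, n_projections: 400, total_mu: 13.5}
  - {name: "9", arc_start_deg: 180, arc_stop_deg: 180, arc_length_deg: 360, direction: CW, n_projections: 360, total_mu: 7.2}
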