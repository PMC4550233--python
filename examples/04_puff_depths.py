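"""Interleaved TIRF/widefield imaging of Ca2+ puffs at known depths.

Simulates release sites 0-500 nm below the membrane imaged in
alternating 5 ms TIRF and widefield frames, runs the full pipeline
(black subtraction, de-interleave, dF/F0, linked-ROI traces), and
classifies each site from its TIRF/WF amplitude ratio.
"""

import spintirf as st
from spintirf.puff_analysis import analyze_interleaved, sites_table
from spintirf.sim_camera import PUFF_SCAN_RADIUS, puff_event_windows

optics, camera = st.OpticalConfig(), st.CameraModel()

depths = [0.0, 100.0, 200.0, 300.0, 400.0, 500.0]
specimen, schedule = st.make_scenario(
    "puff_depths", seed=5, depths_nm=depths, n_events=6
)
stack = st.render_stack(specimen, schedule, optics, camera, seed=5)
print(f"rendered {stack.n_frames} interleaved frames "
      f"({stack.exposure_time_s * 1000:.0f} ms each)")

# 3x3 pixel (~1x1 um) ROIs centered on each site, linked across modes.
px, (ny, nx) = camera.pixel_size_um, camera.frame_shape
rois, events = [], {}
for i, site in enumerate(specimen.puff_sites):
    cx = int(round(site.x_um / px + (nx - 1) / 2))
    cy = int(round(site.y_um / px + (ny - 1) / 2))
    roi = st.ROI.centered(f"site{i}", cx, cy, 3, group=f"g{i}")
    rois.append(roi)
    events[roi.label] = puff_event_windows(site)

d_nm = st.depth_for_scan_radius(PUFF_SCAN_RADIUS, optics)
result = analyze_interleaved(stack, rois, events,
                             baseline_range=(0, 100), depth_nm=d_nm)
print(f"TIRF penetration depth d = {d_nm:.0f} nm; "
      f"calibration k = F0_wf/F0_tirf = {result['k']:.2f}")
print(f"{len(result['events'])} events measured\n")

table = sites_table(result["sites"], result["depths_nm"])
table["true_z_nm"] = depths
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nmean_ratio = k exp(-z/d): ratios > 1.1 mark superficial sites, "
      "< 0.9 deep ones; depth_nm inverts the model.")
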