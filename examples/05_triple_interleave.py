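"""Three-preset, two-laser interleaving and stack IO.

Cycles spinning TIRF at 488 nm, spinning TIRF at 532 nm and
skimming-plane at 532 nm on successive frames — the acquisition pattern
used to watch membrane-proximal and deeper structures near-
simultaneously — then round-trips the stack through TIFF + sidecar.
"""

import tempfile
from pathlib import Path

import numpy as np

import spintirf as st
from spintirf.cli_io import read_stack, write_stack

optics, camera = st.OpticalConfig(), st.CameraModel()
specimen, schedule = st.make_scenario("triple_interleave", seed=7, n_frames=9)
print("frame cycle:", " -> ".join(schedule.frame_mode_tags[:3]), "(repeats)")
print("beads at z =", [f"{b.z_nm:.0f} nm" for b in specimen.beads])

stack = st.render_stack(specimen, schedule, optics, camera, seed=7)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "triple.tif"
    write_stack(stack, path)
    back = read_stack(path)
    print(f"TIFF round trip: {back.n_frames} frames, "
          f"lossless = {np.array_equal(back.frames, stack.frames)}")

subs = st.deinterleave(st.subtract_black(stack, camera.black_level), 3)
for sub in subs:
    print(f"  {sub.mode_tags[0]:<14} {sub.n_frames} frames, "
          f"mean {sub.frames.mean():7.1f} counts")
print("the deep bead (1500 nm) is visible in skimming but dark in TIRF "
      "frames; the shallow beads appear in all three.")
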