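"""Annihilation maps and edge CNR for radioactive vs stable beams.

Simulates a spill-gated treatment (20 spills of 1.9 s on / 1.4 s off)
for a C10 beam and its stable C12 counterpart, bins the positron
annihilations recorded during the first beam-off interval into 1.5 mm
voxels, blurs with the 3.5 mm scanner PSF, and scores the
contrast-to-noise ratio at the SOBP edges.
"""

import numpy as np

from ribpet import (SPECIES, SpillSchedule, bin_events, blur_map,
                    interspill_window, load_config, simulate_treatment,
                    skull_phantom)
from ribpet.image_metrics import cnr, sobp_edge_regions
from ribpet.sobp import map_weights_to_radioactive
from ribpet.study import _design_sobp

config = load_config()
phantom, plan, schedule = skull_phantom(), config.plan(), SpillSchedule()
_, c12_beam = _design_sobp(config, "C12", phantom, plan)
beams = {"C12": c12_beam,
         "C10": map_weights_to_radioactive(c12_beam, SPECIES["C10"], plan,
                                           phantom=phantom)}

window = interspill_window(schedule, 1)
bounds = ((-35.0, 35.0), (-35.0, 35.0), (0.0, phantom.thickness))
print(f"first inter-spill window: {window[0]:.1f}-{window[1]:.1f} s")
for name, beam in beams.items():
    events = simulate_treatment(beam, phantom, schedule, 1_000_000, seed=202)
    amap = blur_map(bin_events(events, window, 1.5, bounds), fwhm=3.5)
    pairs = sobp_edge_regions(amap, plan, transverse_extent=50.0)
    cnrs = {edge: cnr(amap, p) for edge, p in pairs.items()}
    prof = amap.depth_profile()
    z_peak = amap.voxel_centres(2)[int(np.argmax(prof))]
    print(f"{name}: {amap.total:8.0f} counts, depth-profile peak at "
          f"{z_peak:5.1f} mm, CNR "
          + ", ".join(f"{e}={v:.2f}" for e, v in cnrs.items()))
# The short-lived C10 primaries decay at their stopping point inside the
# target, so the SOBP edges stand out within a single spill; the stable
# beam only shows diffuse fragment signal along the entrance path.
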