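#!/usr/bin/env python
"""One-time kidney-model calibration, then freeze.

The nephron segment table (flows, pH) is fixed from physiology; the only
free quantity is the global exchange-area scale.  It is tuned by 1-D root
finding so the morphine reference inputs (permeability 26.3e-6 cm/s,
secretion 13.1 L/h per proximal subsegment, fu_p 0.64, B/P 1.08, pKa 7.9)
reproduce a renal clearance of 8.24 L/h at GFR 120 mL/min.  Every other
prediction in this repository uses the frozen result.

Writes results/kidney_calibration.json.
"""

import json
from pathlib import Path

import renal_mps_pbpk as r
from renal_mps_pbpk import parameters as P

morphine = r.drug_from_sheet(P.MORPHINE)
scale = r.calibrate_exchange_areas(morphine, 8.24)
phys = r.default_kidney_physiology(area_scale_cm2=scale)

out = {
    "area_scale_cm2": scale,
    "frozen_value_in_package": P.KIDNEY_PHYSIOLOGY["area_scale_cm2"],
    "anchor_clr_L_h": r.simulate_renal_clearance(morphine, phys, "ode"),
    "segment_areas_cm2": {s.name: s.exchange_area_cm2 for s in phys.segments},
}
Path("results").mkdir(exist_ok=True)
Path("results/kidney_calibration.json").write_text(json.dumps(out, indent=1))
print(json.dumps(out, indent=1))
print("\nfrozen-physiology M6G prediction:",
      f"{r.simulate_renal_clearance(r.drug_from_sheet(P.M6G), phys, 'ode'):.2f}",
      "L/h (reference 10.84)")
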