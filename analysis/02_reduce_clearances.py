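#!/usr/bin/env python
"""Reduce the effluent tables to per-donor clearances and permeability.

For each donor the steady-state (>= 6 h) tubular efflux gives the apparent
transport clearance (control) and passive-diffusion clearance (inhibitor);
their depletion-corrected intrinsic counterparts give the active secretion
clearance and, via the tubule surface area, the transcellular permeability.
A pooled two-sided t test confirms the inhibitor effect per donor.

Reads results/mps/, writes results/mps/donor_clearances.csv.
"""

from pathlib import Path

import pandas as pd

import renal_mps_pbpk as r

OUT = Path("results/mps")
geometry = r.DeviceGeometry()
rows = []
for compound in ("morphine", "M6G"):
    loaded = r.load_effluent_csv(OUT / f"effluent_{compound}.csv")
    for donor in sorted({s.donor for s in loaded}):
        ds = [s for s in loaded if s.donor == donor]
        cs = r.reduce_donor([s for s in ds if s.condition == "control"],
                            [s for s in ds if s.condition == "inhibitor"],
                            geometry)
        ctrl = next(s for s in ds if s.condition == "control"
                    and s.channel == "tubular").window(6.0)
        inhib = next(s for s in ds if s.condition == "inhibitor"
                     and s.channel == "tubular").window(6.0)
        t, p = r.inhibitor_effect_test(ctrl.conc[~ctrl.censored],
                                       inhib.conc[~inhib.censored])
        rows.append({
            "compound": compound, "donor": donor,
            "cl_app_transport_ul_h": cs.cl_app_transport,
            "cl_app_passive_ul_h": cs.cl_app_passive,
            "cl_int_active_ul_h": cs.cl_int_active,
            "papp_1e6_cm_s": cs.papp_1e6_cm_s,
            "pct_inhibition": 100 * cs.cl_int_active / cs.cl_int_transport,
            "t_stat": t, "p_value": p, "significant": p < 0.05,
        })

df = pd.DataFrame(rows)
df.to_csv(OUT / "donor_clearances.csv", index=False)
print(df.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nall inhibitor effects significant:", bool(df["significant"].all()))
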