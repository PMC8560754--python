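#!/usr/bin/env python
"""Renal clearance across chronic-kidney-disease stages.

Under the intact-nephron hypothesis GFR, tubular flows, kidney blood flow
and transporter-mediated secretion all decline proportionally with nephron
mass; this script sweeps GFR from 3 (end-stage disease) to 120 mL/min
(healthy) for both compounds with the frozen physiology.

Writes results/ckd_clr_sweep.csv and, if matplotlib is importable,
results/ckd_clr_sweep.png.
"""

from pathlib import Path

import numpy as np

import renal_mps_pbpk as r
from renal_mps_pbpk import parameters as P

phys = r.default_kidney_physiology()
grid = np.arange(3.0, 121.0, 3.0)
df = r.clr_vs_gfr_profile(
    [r.drug_from_sheet(P.MORPHINE), r.drug_from_sheet(P.M6G)], phys, grid)

Path("results").mkdir(exist_ok=True)
df.to_csv("results/ckd_clr_sweep.csv", index=False)

mor = df[df.compound == "morphine"].clr_L_per_h.to_numpy()
m6g = df[df.compound == "M6G"].clr_L_per_h.to_numpy()
excess = 100 * (m6g / mor - 1)
print(f"GFR 3 mL/min:   morphine {mor[0]:.3f}, M6G {m6g[0]:.3f} L/h")
print(f"GFR 120 mL/min: morphine {mor[-1]:.2f}, M6G {m6g[-1]:.2f} L/h")
print(f"M6G excess over morphine: {excess.min():.1f}% (min) to "
      f"{excess.max():.1f}% (max); monotone increase: "
      f"{bool(np.all(np.diff(mor) > 0) and np.all(np.diff(m6g) > 0))}")

try:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, mor / 0.06 / 1000, "r-", label="morphine")
    ax.plot(grid, m6g / 0.06 / 1000, "r--", label="M6G")
    ax.set_xlabel("GFR (mL/min)")
    ax.set_ylabel("CL$_r$ (L/min)")
    ax.legend()
    fig.tight_layout()
    fig.savefig("results/ckd_clr_sweep.png", dpi=150)
except ImportError:
    pass
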