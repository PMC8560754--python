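"""Reference parameter sets: drug sheets, device geometry, physiologies.

These are the package's shipped inputs — compiled morphine and
morphine-6-glucuronide (M6G) physicochemical/pharmacokinetic constants, the
per-donor microphysiological-system (MPS) measurement summaries they were
derived from, and default reference-human body and kidney physiology tables.
All are plain dictionaries/dataclass factories so analyses can override any
entry.
"""

from __future__ import annotations

from typing import Dict

# ---------------------------------------------------------------------------
# Drug parameter sheets
# ---------------------------------------------------------------------------

#: Morphine whole-body model parameters.
MORPHINE: Dict = {
    "name": "morphine",
    "mol_weight": 285.34,          # g/mol
    "pka_base": 7.9,
    "fu_p": 0.64,                  # fraction unbound in plasma
    "blood_plasma_ratio": 1.08,
    "papp_1e6_cm_s": 26.3,         # MPS-derived transcellular permeability
    "cl_secretion_total_L_per_h": 39.3,   # unbound intrinsic tubular secretion
    "n_proximal_subsegments": 3,          # 39.3 = 13.1 x 3
    "cl_total_iv_L_per_h": 83.5,
    "fm_m6g": 0.1,                 # fraction of hepatic elimination forming M6G
    "kp": {                        # optimized tissue:plasma partition coefficients
        "adipose": 0.50,
        "bone": 2.07,
        "brain": 1.97,
        "gut": 5.49,
        "heart": 6.79,
        "kidney": 5.54,
        "liver": 11.19,
        "lung": 1.77,
        "muscle": 2.50,
        "pancreas": 4.19,
        "skin": 0.50,
        "spleen": 6.27,
    },
}

#: M6G whole-body model parameters. Distribution limited to extracellular
#: water (Kp = 0.3 in every tissue); hepatic clearance negligible.
M6G: Dict = {
    "name": "M6G",
    "mol_weight": 461.46,
    "pka_base": 9.12,
    "fu_p": 0.89,
    "blood_plasma_ratio": 0.55,
    "papp_1e6_cm_s": 23.8,
    "cl_secretion_total_L_per_h": 43.5,   # 14.5 x 3
    "n_proximal_subsegments": 3,
    "cl_total_iv_L_per_h": None,
    "fm_m6g": 0.0,
    "kp": {t: 0.3 for t in MORPHINE["kp"]},
}

#: Per-donor MPS reductions: intrinsic active-secretion clearance
#: (µL/h per device) and apparent transcellular permeability (1e-6 cm/s)
#: for the three proximal-tubule cell donors.
DONOR_PANEL: Dict[str, Dict[str, Dict[str, float]]] = {
    "morphine": {
        "donor1": {"cl_int_active_ul_h": 14.1, "papp_1e6_cm_s": 27.8},
        "donor2": {"cl_int_active_ul_h": 1.33, "papp_1e6_cm_s": 13.9},
        "donor3": {"cl_int_active_ul_h": 20.87, "papp_1e6_cm_s": 42.7},
    },
    "M6G": {
        "donor1": {"cl_int_active_ul_h": 15.6, "papp_1e6_cm_s": 25.9},
        "donor2": {"cl_int_active_ul_h": 1.29, "papp_1e6_cm_s": 9.74},
        "donor3": {"cl_int_active_ul_h": 22.9, "papp_1e6_cm_s": 41.8},
    },
}

#: Observed (clinical) renal clearance ranges, L/h, for model qualification.
OBSERVED_CLR_RANGE = {"morphine": (6.8, 9.62), "M6G": (9.20, 14.3)}

# ---------------------------------------------------------------------------
# Device geometry and in-vitro -> in-vivo scaling
# ---------------------------------------------------------------------------

#: Dual-channel perfused device: both channels run at 1 µL/min; the epithelial
#: tubule is a ~120 µm channel whose lateral surface is the exchange area.
DEVICE_GEOMETRY: Dict = {
    "flow_endothelial_ul_h": 60.0,
    "flow_tubular_ul_h": 60.0,
    "tubule_diameter_um": 120.0,
    "tubule_length_cm": 1.31,
    "cells_per_mps": 5000,
}

#: Cell-number scaling of device intrinsic secretion to whole kidney.
SCALING_FACTORS: Dict = {
    "cells_per_mps": 5000,
    "cells_per_g_kidney": 60.0e6,
    "kidney_mass_g": 300.0,
}

# ---------------------------------------------------------------------------
# Reference-human body physiology (70-kg adult)
# ---------------------------------------------------------------------------

#: Tissue volumes (L) and arterial blood flows (L/h). Liver receives hepatic
#: arterial flow plus the venous outflow of gut, pancreas and spleen
#: (total hepatic blood flow 99.7 L/h). Cardiac output is the sum of the
#: arterial flows (361 L/h, ~6 L/min).
BODY_PHYSIOLOGY: Dict = {
    "tissues": {
        #            volume_L  flow_L_h
        "adipose":  {"volume": 13.5, "flow": 19.5},
        "bone":     {"volume": 10.5, "flow": 19.5},
        "brain":    {"volume": 1.45, "flow": 46.8},
        "gut":      {"volume": 1.65, "flow": 58.5},
        "heart":    {"volume": 0.33, "flow": 15.6},
        "kidney":   {"volume": 0.31, "flow": 74.1},
        "liver":    {"volume": 1.80, "flow": 25.6},   # hepatic artery only
        "lung":     {"volume": 0.53, "flow": None},   # in series, sees cardiac output
        "muscle":   {"volume": 26.0, "flow": 66.3},
        "pancreas": {"volume": 0.14, "flow": 3.9},
        "skin":     {"volume": 3.40, "flow": 19.5},
        "spleen":   {"volume": 0.19, "flow": 11.7},
    },
    "volume_plasma_L": 3.0,        # venous 2/3, arterial 1/3
    "volume_erythrocyte_L": 2.0,
    "hematocrit": 0.40,
    "sampling_site": "arm_vein",
    #: arm-vein sample = flow-weighted mix of these tissues' venous effluents
    "arm_vein_tissues": ("muscle", "skin", "adipose"),
}

# ---------------------------------------------------------------------------
# Kidney physiology: nephron-in-series segment table
# ---------------------------------------------------------------------------

#: Single-pathway nephron cascade at whole-kidney aggregate scale.
#: Filtrate flows (mL/min) step down with water reabsorption; filtrate pH
#: acidifies along the proximal tubule and collecting duct.  Exchange areas
#: are expressed as a fixed relative profile times a global scale (cm²) that
#: is set once by calibration (see kidney_model.calibrate_exchange_areas).
KIDNEY_PHYSIOLOGY: Dict = {
    "gfr_ml_min": 120.0,
    "q_kidney_L_h": 74.1,          # kidney blood flow, matches body table
    "plasma_ph": 7.4,
    "segments": [
        # name, filtrate flow out (mL/min), pH, relative exchange area, secreting
        {"name": "S1", "flow_out_ml_min": 93.3, "ph": 7.23, "rel_area": 1.00, "secreting": True},
        {"name": "S2", "flow_out_ml_min": 66.7, "ph": 7.07, "rel_area": 1.00, "secreting": True},
        {"name": "S3", "flow_out_ml_min": 40.0, "ph": 6.90, "rel_area": 1.00, "secreting": True},
        {"name": "LoH", "flow_out_ml_min": 24.0, "ph": 7.40, "rel_area": 0.15, "secreting": False},
        {"name": "DT", "flow_out_ml_min": 12.0, "ph": 6.80, "rel_area": 0.10, "secreting": False},
        {"name": "CD", "flow_out_ml_min": 1.2, "ph": 6.30, "rel_area": 0.06, "secreting": False},
    ],
    #: global exchange-area scale, cm² per unit rel_area; frozen after the
    #: one-time morphine calibration (kidney_model.calibrate_exchange_areas
    #: reproduces it from scratch).
    "area_scale_cm2": 31559.1206,
}
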