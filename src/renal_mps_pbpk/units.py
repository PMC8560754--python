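"""Centralized unit conversions.

Internal conventions:

* in-vitro clearances and flows: µL/h per device
* whole-body clearances and flows: L/h
* permeability: reported in 1e-6 cm/s
* concentrations: nM (nmol/L); amounts: nmol
"""

from __future__ import annotations

UL_PER_L = 1.0e6
S_PER_H = 3600.0


def ul_per_h_to_l_per_h(x: float) -> float:
    return x / UL_PER_L


def l_per_h_to_ul_per_h(x: float) -> float:
    return x * UL_PER_L


def ul_per_h_to_cm3_per_s(x: float) -> float:
    """µL/h -> cm³/s (1 µL = 1e-3 cm³)."""
    return x * 1.0e-3 / S_PER_H


def permeability_flow(papp_1e6_cm_s: float, area_cm2: float) -> float:
    """Permeability (1e-6 cm/s) x area (cm²) -> equivalent flow in L/h.

    1 cm³/s = 3.6 L/h.
    """
    return papp_1e6_cm_s * 1.0e-6 * area_cm2 * 3.6


def nm_to_ng_per_ml(conc_nm: float, mol_weight: float) -> float:
    """nmol/L -> ng/mL given molecular weight in g/mol."""
    return conc_nm * mol_weight * 1.0e-3


def ng_per_ml_to_nm(conc_ng_ml: float, mol_weight: float) -> float:
    return conc_ng_ml / (mol_weight * 1.0e-3)


def mg_to_nmol(dose_mg: float, mol_weight: float) -> float:
    """mg -> nmol given molecular weight in g/mol."""
    return dose_mg / mol_weight * 1.0e6
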