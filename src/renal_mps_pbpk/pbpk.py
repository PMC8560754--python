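"""Whole-body parent-metabolite PBPK model.

Twelve perfusion-limited tissues (adipose, bone, brain, gut, heart, kidney,
liver, lung, muscle, pancreas, skin, spleen) plus arterial and venous blood
pools.  Lung sits in series with cardiac output; gut, pancreas and spleen
drain through the liver (portal inflow).  The liver is well-stirred: parent
drug is eliminated at rate fu_b * CL_int * C_liver,out, and a fixed molar
fraction f_m of that elimination appears in the liver compartment as the
glucuronide metabolite.  Urinary elimination of each analyte is governed by
the renal clearance delivered by the mechanistic kidney submodel, referenced
to arterial plasma (the same reference the submodel uses to define CL_r).

Circulatory transport carries plasma concentration at nominal organ blood
flows; the blood-to-plasma ratio enters through the well-stirred unbound
blood fraction fu_b = fu_p/(B/P), the erythrocyte term of V_ss, and the
kidney submodel.  Under this convention a drug with hepatic plasma clearance
CL_h back-calculates to CL_int via CL_int = Q_h*CL_h/(fu_b*(Q_h - CL_h)) and
the simulated Dose/AUC equals CL_h + CL_r for linear kinetics.

Amounts are tracked in nmol and concentrations in nM, so parent-to-
metabolite conversion is a direct molar transfer; molecular weights enter
only when reporting mass-based concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .kidney_model import (KidneyPhysiology, RenalDrugParams,
                           default_kidney_physiology, drug_from_sheet,
                           simulate_renal_clearance)
from .units import mg_to_nmol
from . import parameters

__all__ = [
    "BodyPhysiology",
    "DrugModel",
    "DoseRegimen",
    "PKProfile",
    "compute_vss",
    "hepatic_clearance_from_total",
    "backcalc_intrinsic_hepatic",
    "well_stirred_hepatic",
    "simulate_parent_metabolite",
    "default_body_physiology",
    "build_drug_model",
]

_PORTAL = ("gut", "pancreas", "spleen")


@dataclass
class BodyPhysiology:
    """Reference-human tissue volumes (L) and blood flows (L/h)."""

    tissues: Dict[str, Dict[str, float]]
    volume_plasma_L: float = 3.0
    volume_erythrocyte_L: float = 2.0
    hematocrit: float = 0.40
    sampling_site: str = "arm_vein"
    arm_vein_tissues: Tuple[str, ...] = ("muscle", "skin", "adipose")

    def __post_init__(self) -> None:
        for t, row in self.tissues.items():
            if row["volume"] <= 0:
                raise ValueError(f"non-positive volume for {t}")

    @property
    def cardiac_output(self) -> float:
        return sum(row["flow"] for t, row in self.tissues.items() if t != "lung")

    @property
    def q_hepatic(self) -> float:
        """Total hepatic blood flow: hepatic artery + portal organs."""
        return self.tissues["liver"]["flow"] + sum(
            self.tissues[t]["flow"] for t in _PORTAL)


def default_body_physiology() -> BodyPhysiology:
    cfg = parameters.BODY_PHYSIOLOGY
    return BodyPhysiology(
        tissues={t: dict(v) for t, v in cfg["tissues"].items()},
        volume_plasma_L=cfg["volume_plasma_L"],
        volume_erythrocyte_L=cfg["volume_erythrocyte_L"],
        hematocrit=cfg["hematocrit"],
        sampling_site=cfg["sampling_site"],
        arm_vein_tissues=tuple(cfg["arm_vein_tissues"]),
    )


@dataclass
class DrugModel:
    """Whole-body model parameters for one analyte."""

    renal: RenalDrugParams
    kp: Dict[str, float]
    cl_r: float                    # L/h, plasma-referenced
    cl_int_hepatic: float = 0.0    # L/h
    fm_m6g: float = 0.0
    cl_total_iv: Optional[float] = None
    cl_h: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError("all Kp values must be positive")
        if not (0 <= self.fm_m6g <= 1):
            raise ValueError("fm must be a fraction")


@dataclass
class DoseRegimen:
    route: str                     # {iv_bolus, iv_infusion}
    amount_mg: float
    duration_h: float = 0.0
    subject_mass_kg: Optional[float] = None   # set if amount is mg/kg

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "iv_infusion"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.amount_mg <= 0:
            raise ValueError("dose must be positive")
        if self.route == "iv_infusion" and self.duration_h <= 0:
            raise ValueError("infusion requires positive duration")

    def total_mg(self) -> float:
        if self.subject_mass_kg is not None:
            return self.amount_mg * self.subject_mass_kg
        return self.amount_mg


@dataclass
class PKProfile:
    """Plasma concentration-time series for one analyte at one site."""

    analyte: str
    site: str
    times: np.ndarray              # h
    conc: np.ndarray               # nM
    censored: np.ndarray = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.conc < -1e-12):
            raise ValueError("negative concentrations")
        self.conc = np.clip(self.conc, 0.0, None)

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Log-linear interpolation of concentration onto times ``t``."""
        t = np.asarray(t, dtype=float)
        floor = 1e-300
        logc = np.log(np.clip(self.conc, floor, None))
        out = np.exp(np.interp(t, self.times, logc))
        return np.where(out <= 10 * floor, 0.0, out)


# ---------------------------------------------------------------------------
# Closed-form pieces
# ---------------------------------------------------------------------------

def kp_erythrocyte(blood_plasma_ratio: float, hematocrit: float) -> float:
    """Erythrocyte:plasma partitioning implied by B/P; clamped at zero when
    the compound is excluded from red cells (B/P below 1 - Hct)."""
    kp = (blood_plasma_ratio - (1.0 - hematocrit)) / hematocrit
    return max(kp, 0.0)


def compute_vss(drug: DrugModel, phys: BodyPhysiology) -> float:
    """Plasma-referenced steady-state volume of distribution (L):
    V_plasma + V_ery * Kp_ery + sum_t V_t * Kp_t."""
    missing = [t for t in phys.tissues if t not in drug.kp]
    if missing:
        raise ValueError(f"missing Kp for tissues: {missing}")
    v = phys.volume_plasma_L
    v += phys.volume_erythrocyte_L * kp_erythrocyte(
        drug.renal.blood_plasma_ratio, phys.hematocrit)
    v += sum(phys.tissues[t]["volume"] * drug.kp[t] for t in phys.tissues)
    return v


def hepatic_clearance_from_total(cl_total_iv: float, cl_r: float) -> float:
    """CL_h = systemic clearance minus renal clearance."""
    if not (cl_total_iv >= cl_r >= 0):
        raise ValueError("require cl_total_iv >= cl_r >= 0")
    return cl_total_iv - cl_r


def backcalc_intrinsic_hepatic(cl_h: float, fu_p: float, bp: float,
                               q_h: float) -> float:
    """Invert the well-stirred liver model for intrinsic clearance:
    CL_int = Q_h * CL_h / (fu_b * (Q_h - CL_h)) with fu_b = fu_p / (B/P)."""
    if cl_h >= q_h:
        raise ValueError("hepatic clearance at or above liver blood flow")
    if cl_h < 0:
        raise ValueError("hepatic clearance must be non-negative")
    fu_b = fu_p / bp
    return q_h * cl_h / (fu_b * (q_h - cl_h))


def well_stirred_hepatic(cl_int: float, fu_p: float, bp: float,
                         q_h: float) -> float:
    """Forward well-stirred model: CL_h = Q_h*fu_b*CL_int/(Q_h+fu_b*CL_int)."""
    fu_b = fu_p / bp
    return q_h * fu_b * cl_int / (q_h + fu_b * cl_int)


def build_drug_model(
    sheet: Dict,
    kidney_phys: Optional[KidneyPhysiology] = None,
    body: Optional[BodyPhysiology] = None,
    cl_r: Optional[float] = None,
) -> DrugModel:
    """Assemble a DrugModel from a parameter sheet.

    Renal clearance comes from the mechanistic kidney model unless given;
    hepatic clearance is back-calculated from the observed systemic
    clearance (when the sheet provides one) via CL_h = CL_total,iv - CL_r
    and the well-stirred inversion.
    """
    body = body or default_body_physiology()
    kidney_phys = kidney_phys or default_kidney_physiology()
    renal = drug_from_sheet(sheet)
    if cl_r is None:
        cl_r = simulate_renal_clearance(renal, kidney_phys, method="algebraic")
    cl_total = sheet.get("cl_total_iv_L_per_h")
    if cl_total is not None:
        cl_h = hepatic_clearance_from_total(cl_total, cl_r)
        cl_int = backcalc_intrinsic_hepatic(
            cl_h, sheet["fu_p"], sheet["blood_plasma_ratio"], body.q_hepatic)
    else:
        cl_h, cl_int = 0.0, 0.0
    return DrugModel(
        renal=renal, kp=dict(sheet["kp"]), cl_r=cl_r,
        cl_int_hepatic=cl_int, fm_m6g=sheet.get("fm_m6g", 0.0),
        cl_total_iv=cl_total, cl_h=cl_h, name=sheet.get("name", ""),
    )


# ---------------------------------------------------------------------------
# Coupled parent-metabolite simulation
# ---------------------------------------------------------------------------

_TISSUE_ORDER = ("adipose", "bone", "brain", "gut", "heart", "kidney",
                 "liver", "muscle", "pancreas", "skin", "spleen")


class _Layout:
    """State-vector layout per analyte: 11 tissues, lung, venous, arterial,
    cumulative urinary and cumulative hepatic elimination."""

    n_per = len(_TISSUE_ORDER) + 3 + 2

    def __init__(self, phys: BodyPhysiology):
        self.phys = phys
        self.idx = {t: i for i, t in enumerate(_TISSUE_ORDER)}
        self.i_lung = len(_TISSUE_ORDER)
        self.i_ven = self.i_lung + 1
        self.i_art = self.i_ven + 1
        self.i_urine = self.i_art + 1
        self.i_hep = self.i_urine + 1


def _analyte_rhs(x, lay: _Layout, drug: DrugModel, infusion_rate: float,
                 formation_rate: float = 0.0):
    """Time derivative for one analyte's sub-state; returns (dx, hepatic
    elimination rate) so the caller can route metabolite formation."""
    phys = lay.phys
    tis = phys.tissues
    kp_e = kp_erythrocyte(drug.renal.blood_plasma_ratio, phys.hematocrit)
    v_ven = (2.0 / 3.0) * (phys.volume_plasma_L + phys.volume_erythrocyte_L * kp_e)
    v_art = (1.0 / 3.0) * (phys.volume_plasma_L + phys.volume_erythrocyte_L * kp_e)
    co = phys.cardiac_output

    c_ven = x[lay.i_ven] / v_ven
    c_art = x[lay.i_art] / v_art
    c_out = {t: x[lay.idx[t]] / (tis[t]["volume"] * drug.kp[t])
             for t in _TISSUE_ORDER}
    c_lung = x[lay.i_lung] / (tis["lung"]["volume"] * drug.kp["lung"])

    dx = np.zeros(lay.n_per)
    ven_in = 0.0
    for t in _TISSUE_ORDER:
        q = tis[t]["flow"]
        if t in _PORTAL:
            dx[lay.idx[t]] = q * (c_art - c_out[t])     # drains to liver
        elif t == "liver":
            portal = sum(tis[p]["flow"] * c_out[p] for p in _PORTAL)
            q_out = phys.q_hepatic
            elim_hep = drug.renal.fu_b * drug.cl_int_hepatic * c_out["liver"]
            dx[lay.idx[t]] = (q * c_art + portal - q_out * c_out["liver"]
                              - elim_hep + formation_rate)
            ven_in += q_out * c_out["liver"]
        elif t == "kidney":
            elim_ren = drug.cl_r * c_art
            dx[lay.idx[t]] = q * (c_art - c_out[t]) - elim_ren
            ven_in += q * c_out[t]
        else:
            dx[lay.idx[t]] = q * (c_art - c_out[t])
            ven_in += q * c_out[t]
    dx[lay.i_ven] = ven_in - co * c_ven + infusion_rate
    dx[lay.i_lung] = co * (c_ven - c_lung)
    dx[lay.i_art] = co * (c_lung - c_art)
    dx[lay.i_urine] = drug.cl_r * c_art
    elim_hep = drug.renal.fu_b * drug.cl_int_hepatic * c_out["liver"]
    dx[lay.i_hep] = elim_hep
    return dx, elim_hep


def _sample_conc(x, lay: _Layout, drug: DrugModel, site: str) -> float:
    phys = lay.phys
    kp_e = kp_erythrocyte(drug.renal.blood_plasma_ratio, phys.hematocrit)
    if site == "central_venous":
        v_ven = (2.0 / 3.0) * (phys.volume_plasma_L
                               + phys.volume_erythrocyte_L * kp_e)
        return x[lay.i_ven] / v_ven
    if site == "arm_vein":
        num = den = 0.0
        for t in phys.arm_vein_tissues:
            q = phys.tissues[t]["flow"]
            c = x[lay.idx[t]] / (phys.tissues[t]["volume"] * drug.kp[t])
            num += q * c
            den += q
        return num / den
    raise ValueError(f"unknown sampling site {site!r}")


def simulate_parent_metabolite(
    parent: DrugModel,
    metabolite: Optional[DrugModel],
    dose: DoseRegimen,
    phys: Optional[BodyPhysiology] = None,
    horizon_h: float = 24.0,
    n_points: int = 481,
    rtol: float = 1.0e-8,
    atol: float = 1.0e-12,
    site: Optional[str] = None,
):
    """Simulate IV dosing of the parent and formation of its metabolite.

    Returns (parent PKProfile, metabolite PKProfile or None, diagnostics).
    Diagnostics include cumulative urinary and hepatic elimination and the
    worst-case mass-balance error over the output grid.
    """
    if horizon_h <= 0:
        raise ValueError("horizon must be positive")
    phys = phys or default_body_physiology()
    site = site or phys.sampling_site
    lay = _Layout(phys)
    n = lay.n_per
    two = metabolite is not None

    dose_nmol = mg_to_nmol(dose.total_mg(), parent.renal.mol_weight)

    def rhs(t, x, inf_rate):
        xp = x[:n]
        dxp, elim_hep = _analyte_rhs(xp, lay, parent, inf_rate)
        if not two:
            return dxp
        formation = parent.fm_m6g * elim_hep
        dxm, _ = _analyte_rhs(x[n:], lay, metabolite, 0.0, formation)
        return np.concatenate([dxp, dxm])

    x0 = np.zeros(n * (2 if two else 1))
    t_eval = np.linspace(0.0, horizon_h, n_points)
    if dose.route == "iv_bolus":
        x0[lay.i_ven] = dose_nmol
        sol = solve_ivp(rhs, (0.0, horizon_h), x0, args=(0.0,), method="BDF",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"PBPK solver failed: {sol.message}")
        ys, ts = sol.y, sol.t
    else:
        rate = dose_nmol / dose.duration_h
        te1 = t_eval[t_eval <= dose.duration_h]
        if te1.size == 0 or te1[-1] < dose.duration_h:
            te1 = np.append(te1, dose.duration_h)
        s1 = solve_ivp(rhs, (0.0, dose.duration_h), x0, args=(rate,),
                       method="BDF", t_eval=te1, rtol=rtol, atol=atol)
        if not s1.success:
            raise RuntimeError(f"PBPK solver failed: {s1.message}")
        te2 = t_eval[t_eval > dose.duration_h]
        te2 = np.concatenate([[dose.duration_h], te2])
        s2 = solve_ivp(rhs, (dose.duration_h, horizon_h), s1.y[:, -1],
                       args=(0.0,), method="BDF", t_eval=te2,
                       rtol=rtol, atol=atol)
        if not s2.success:
            raise RuntimeError(f"PBPK solver failed: {s2.message}")
        ts = np.concatenate([s1.t, s2.t[1:]])
        ys = np.concatenate([s1.y, s2.y[:, 1:]], axis=1)

    if np.any(ys[:n][[lay.idx[t] for t in _TISSUE_ORDER]
                     + [lay.i_lung, lay.i_ven, lay.i_art]] < -1e-6):
        raise RuntimeError("negative amounts in PBPK solution")

    # mass balance: body + urine + hepatically eliminated = administered
    body_idx = [lay.idx[t] for t in _TISSUE_ORDER] + [lay.i_lung, lay.i_ven,
                                                      lay.i_art]
    administered = np.minimum(
        ts / dose.duration_h if dose.route == "iv_infusion" else 1.0, 1.0
    ) * dose_nmol
    total = ys[body_idx].sum(axis=0) + ys[lay.i_urine] + ys[lay.i_hep]
    mb_err = float(np.max(np.abs(total - administered)) / dose_nmol)

    parent_conc = np.array([_sample_conc(ys[:n, k], lay, parent, site)
                            for k in range(ts.size)])
    p_prof = PKProfile(
        analyte=parent.name or "parent", site=site, times=ts[1:],
        conc=parent_conc[1:],
        metadata={"dose_mg": dose.total_mg(), "route": dose.route,
                  "duration_h": dose.duration_h,
                  "mol_weight": parent.renal.mol_weight},
    )
    diag = {
        "mass_balance_rel_error": mb_err,
        "urinary_nmol": float(ys[lay.i_urine, -1]),
        "hepatic_nmol": float(ys[lay.i_hep, -1]),
        "dose_nmol": dose_nmol,
    }
    m_prof = None
    if two:
        met_conc = np.array([_sample_conc(ys[n:, k], lay, metabolite, site)
                             for k in range(ts.size)])
        m_prof = PKProfile(
            analyte=metabolite.name or "metabolite", site=site, times=ts[1:],
            conc=met_conc[1:],
            metadata={"parent": parent.name, "fm": parent.fm_m6g,
                      "mol_weight": metabolite.renal.mol_weight},
        )
        formed = parent.fm_m6g * ys[lay.i_hep]
        met_total = (ys[n:][body_idx].sum(axis=0) + ys[n + lay.i_urine]
                     + ys[n + lay.i_hep])
        with np.errstate(invalid="ignore", divide="ignore"):
            met_err = np.abs(met_total - formed) / np.maximum(formed, 1e-12)
        diag["metabolite_mass_balance_rel_error"] = float(
            np.nanmax(np.where(formed > 1e-9 * dose_nmol, met_err, 0.0)))
        diag["metabolite_urinary_nmol"] = float(ys[n + lay.i_urine, -1])
    return p_prof, m_prof, diag
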