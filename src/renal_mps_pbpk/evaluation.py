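"""Model-performance metrics and non-compartmental utilities.

The headline metric is the absolute average fold error,

    AAFE = 10 ** ( (1/n) * sum |log10(simulated / observed)| ),

computed over observed points that are neither censored nor below the
assay quantification limit, with the simulation log-linearly interpolated
onto the observation times.  A simulation is accepted when AAFE <= 2
(the twofold criterion, boundary inclusive).

The NCA helper provides linear-up/log-down trapezoid AUC with log-linear
terminal extrapolation, mean residence time and moment-analysis V_ss; it is
used as an independent oracle against the PBPK simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .pbpk import DoseRegimen, PKProfile
from .units import mg_to_nmol

__all__ = ["AafeResult", "aafe", "twofold_check", "nca"]


@dataclass
class AafeResult:
    value: float
    n_points: int
    excluded_points: int

    def __post_init__(self) -> None:
        if self.value < 1.0 - 1e-12:
            raise ValueError("AAFE is >= 1 by construction")

    @property
    def passed_twofold(self) -> bool:
        return self.value <= 2.0


def aafe(simulated: PKProfile, observed: PKProfile,
         lloq: Optional[float] = None) -> AafeResult:
    """Absolute average fold error of a simulation against observations.

    Censored observations (and any below ``lloq`` when given) are excluded
    and counted.  Both series must be positive at the matched points.
    """
    usable = ~observed.censored
    if lloq is not None:
        usable &= observed.conc >= lloq
    t = observed.times[usable]
    obs = observed.conc[usable]
    if t.size == 0:
        raise ValueError("no usable observation points")
    sim = simulated.interp(t)
    if np.any(obs <= 0) or np.any(sim <= 0):
        raise ValueError("AAFE requires positive concentrations at matched points")
    value = 10.0 ** np.mean(np.abs(np.log10(sim / obs)))
    return AafeResult(value=float(value), n_points=int(t.size),
                      excluded_points=int((~usable).sum()))


def twofold_check(result: AafeResult) -> bool:
    """Twofold model-acceptance criterion, boundary inclusive."""
    return result.value <= 2.0


def _terminal_slope(times: np.ndarray, conc: np.ndarray, n_tail: int = 3):
    t = times[-n_tail:]
    c = conc[-n_tail:]
    if np.any(c <= 0):
        raise ValueError("terminal phase must be positive")
    k, b = np.polyfit(t, np.log(c), 1)
    if k >= 0:
        raise ValueError("non-decaying terminal phase")
    return -k


def nca(profile: PKProfile, dose: DoseRegimen, n_tail: int = 3) -> Dict[str, float]:
    """Non-compartmental analysis of a concentration-time profile.

    AUC by linear-up/log-down trapezoids with C/lambda_z extrapolation;
    AUMC analogously; CL = Dose/AUC; MRT = AUMC/AUC (minus half the infusion
    duration for infusions); Vss = CL * MRT.  Dose is converted to nmol so
    clearance comes out in L/h against nM concentrations.
    """
    t, c = profile.times, profile.conc
    if t.size < n_tail + 1:
        raise ValueError("profile too short for terminal-phase fit")
    lam = _terminal_slope(t, c, n_tail)
    # initial segment: back-extrapolate C(0) for a bolus, linear-up from
    # zero otherwise (the profile starts after dosing begins)
    if t[0] > 0:
        if dose.route == "iv_bolus" and c[0] > c[1] > 0:
            k0 = np.log(c[0] / c[1]) / (t[1] - t[0])
            c0 = c[0] * np.exp(k0 * t[0])
            auc0 = (c0 - c[0]) / k0
            aumc0 = -t[0] * c[0] / k0 + (c0 - c[0]) / k0**2
        else:
            auc0 = 0.5 * t[0] * c[0]
            aumc0 = 0.5 * t[0] ** 2 * c[0]
    else:
        auc0 = aumc0 = 0.0
    auc, aumc = auc0, aumc0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:      # log-down
            k = np.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            # moment of the exponential segment
            aumc += (t[i] * c1 - t[i + 1] * c2) / k + (c1 - c2) / k**2
        else:                                   # linear-up
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t[i] * c1 + t[i + 1] * c2) * dt
    c_last, t_last = c[-1], t[-1]
    auc_inf = auc + c_last / lam
    aumc_inf = aumc + c_last * t_last / lam + c_last / lam**2
    mw = profile.metadata.get("mol_weight")
    dose_nmol = mg_to_nmol(dose.total_mg(), mw) if mw else dose.total_mg()
    cl = dose_nmol / auc_inf
    mrt = aumc_inf / auc_inf
    if dose.route == "iv_infusion":
        mrt -= dose.duration_h / 2.0
    return {"auc_0_inf": float(auc_inf), "aumc_0_inf": float(aumc_inf),
            "cl": float(cl), "mrt": float(mrt), "vss": float(cl * mrt),
            "lambda_z": float(lam)}
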