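"""Reduction of dual-channel MPS effluent time courses to clearances.

The perfused device measures net basolateral-to-apical transport: drug is
infused through the endothelial (vascular) channel, and the rate at which it
appears in the epithelial (tubular) channel effluent at steady state, divided
by the vascular concentration, gives an apparent clearance per device.
Running the same device under a transporter-inhibitor cocktail isolates the
passive-diffusion component; the difference is transporter-mediated active
secretion.  Apparent clearances are corrected for depletion along the
endothelial channel to intrinsic clearances, and the intrinsic passive
clearance over the tubule surface area gives the transcellular permeability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "EffluentSeries",
    "DeviceGeometry",
    "ClearanceSet",
    "steady_state_efflux",
    "apparent_clearance",
    "active_from_apparent",
    "intrinsicize",
    "apparentize",
    "papp_from_intrinsic",
    "reduce_donor",
    "inhibitor_effect_test",
]


@dataclass
class EffluentSeries:
    """One channel's concentration-time record for one device/condition."""

    donor: str
    compound: str
    condition: str                 # {control, inhibitor}
    channel: str                   # {vascular, tubular}
    times: np.ndarray              # h
    conc: np.ndarray               # nM
    censored: np.ndarray           # bool, below-LLOQ flags
    flow_out: float                # µL/h
    nominal_inflow_conc: Optional[float] = None   # nM, dosing solution

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.condition not in ("control", "inhibitor"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.channel not in ("vascular", "tubular"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.flow_out <= 0:
            raise ValueError("flow_out must be positive")

    def window(self, start: float) -> "EffluentSeries":
        m = self.times >= start
        return EffluentSeries(self.donor, self.compound, self.condition,
                              self.channel, self.times[m], self.conc[m],
                              self.censored[m], self.flow_out,
                              self.nominal_inflow_conc)


@dataclass
class DeviceGeometry:
    """Perfused dual-channel device geometry.

    The tubule exchange surface defaults to the lateral area of a cylinder,
    pi * diameter * length; pass ``surface_area_cm2`` to override.
    """

    flow_endothelial: float = 60.0     # µL/h
    flow_tubular: float = 60.0         # µL/h
    tubule_diameter_um: float = 120.0
    tubule_length_cm: float = 1.31
    surface_area_cm2: Optional[float] = None
    cells_per_mps: int = 5000

    def __post_init__(self) -> None:
        if self.flow_endothelial <= 0 or self.flow_tubular <= 0:
            raise ValueError("flows must be positive")
        if self.surface_area_cm2 is None:
            self.surface_area_cm2 = (
                math.pi * self.tubule_diameter_um * 1.0e-4 * self.tubule_length_cm
            )


@dataclass
class ClearanceSet:
    """Apparent and intrinsic clearances plus permeability for one donor."""

    donor: str
    compound: str
    cl_app_transport: float        # µL/h per device
    cl_app_passive: float
    cl_app_active: float
    cl_int_transport: float
    cl_int_passive: float
    cl_int_active: float
    papp_1e6_cm_s: float
    steady_state_window: Tuple[float, float]
    sd: Dict[str, float] = field(default_factory=dict)


def steady_state_efflux(
    series: EffluentSeries,
    window_start: float = 6.0,
    vascular: Optional[EffluentSeries] = None,
    vascular_ref: str = "nominal",
) -> Tuple[float, float]:
    """Steady-state efflux rate (nmol-scale: nM*µL/h) and vascular conc (nM).

    The efflux rate is the mean non-censored tubular-effluent concentration
    in the steady-state window times the tubular outflow.  The reference
    vascular concentration defaults to the nominal dosing concentration:
    the depletion of the endothelial channel is accounted for by the
    apparent-to-intrinsic correction, so referencing the depleted effluent
    would double-count it.  ``vascular_ref='measured'`` uses the windowed
    mean of the vascular effluent instead (also the fallback when no
    nominal concentration is recorded).
    """
    if series.channel != "tubular":
        raise ValueError("steady_state_efflux expects the tubular series")
    win = series.window(window_start)
    usable = ~win.censored
    if win.times.size == 0:
        raise ValueError("no samples at or after window start")
    if usable.sum() < 2:
        # below-quantification plateaus are a real outcome: all-censored
        # windows mean efflux indistinguishable from the assay floor
        if win.times.size >= 2 and win.censored.all():
            raise ValueError("all steady-state samples censored (below LLOQ)")
        raise ValueError("need >= 2 non-censored samples in the window")
    rate = float(win.conc[usable].mean() * series.flow_out)
    use_measured = vascular_ref == "measured" or series.nominal_inflow_conc is None
    if use_measured and vascular is not None:
        vwin = vascular.window(window_start)
        vu = ~vwin.censored
        if vu.sum() == 0:
            raise ValueError("vascular window entirely censored")
        vconc = float(vwin.conc[vu].mean())
    elif series.nominal_inflow_conc is not None:
        vconc = float(series.nominal_inflow_conc)
    else:
        raise ValueError("no vascular reference concentration available")
    return rate, vconc


def apparent_clearance(efflux_rate: float, vascular_conc: float) -> float:
    """Apparent device clearance, µL/h: efflux rate / vascular concentration."""
    if vascular_conc <= 0:
        raise ValueError("vascular concentration must be positive")
    return efflux_rate / vascular_conc


def active_from_apparent(cl_transport: float, cl_passive: float) -> float:
    """Active secretion = transport - passive, clamped at zero.

    A negative difference (inhibited device clearing faster than control)
    carries no mechanistic meaning; it is clamped with a warning.
    """
    if cl_transport < 0 or cl_passive < 0:
        raise ValueError("clearances must be non-negative")
    diff = cl_transport - cl_passive
    if diff < 0:
        warnings.warn(
            "passive clearance exceeds transport clearance; "
            "active secretion clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return diff


def intrinsicize(cl_app: float, flow_endothelial: float) -> float:
    """Correct an apparent clearance for endothelial-channel depletion.

    CL_int = Q * CL_app / (Q - CL_app).  Undefined (flow-limited) as
    CL_app -> Q.
    """
    if cl_app < 0:
        raise ValueError("cl_app must be non-negative")
    if cl_app >= flow_endothelial:
        raise ValueError("apparent clearance at or above channel flow: "
                         "intrinsic clearance undefined (flow-limited)")
    return flow_endothelial * cl_app / (flow_endothelial - cl_app)


def apparentize(cl_int: float, flow_endothelial: float) -> float:
    """Inverse of :func:`intrinsicize`: CL_app = Q*CL_int/(Q + CL_int)."""
    if cl_int < 0:
        raise ValueError("cl_int must be non-negative")
    return flow_endothelial * cl_int / (flow_endothelial + cl_int)


def papp_from_intrinsic(cl_int_passive: float, geometry: DeviceGeometry) -> float:
    """Transcellular permeability (1e-6 cm/s) from intrinsic passive clearance.

    µL/h is converted to cm³/s and divided by the tubule surface area.
    """
    if geometry.surface_area_cm2 is None or geometry.surface_area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    cm3_s = cl_int_passive * 1.0e-3 / 3600.0
    return cm3_s / geometry.surface_area_cm2 / 1.0e-6


def _pick(series: Sequence[EffluentSeries], condition: str, channel: str
          ) -> Optional[EffluentSeries]:
    for s in series:
        if s.condition == condition and s.channel == channel:
            return s
    return None


def reduce_donor(
    control: Sequence[EffluentSeries],
    inhibitor: Sequence[EffluentSeries],
    geometry: DeviceGeometry,
    window_start: float = 6.0,
) -> ClearanceSet:
    """Full reduction of one donor's control/inhibitor series pair.

    Produces apparent transport/passive/active clearances, their intrinsic
    counterparts, and the permeability.  The windowed sample SD of the
    tubular plateau is carried per condition.
    """
    sers = list(control) + list(inhibitor)
    donors = {s.donor for s in sers}
    compounds = {s.compound for s in sers}
    if len(donors) != 1 or len(compounds) != 1:
        raise ValueError("series must come from a single donor and compound")

    out: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    for cond, group in (("control", control), ("inhibitor", inhibitor)):
        tub = _pick(group, cond, "tubular")
        if tub is None:
            raise ValueError(f"missing tubular series for {cond}")
        vas = _pick(group, cond, "vascular")
        rate, vconc = steady_state_efflux(tub, window_start, vascular=vas)
        out[cond] = apparent_clearance(rate, vconc)
        win = tub.window(window_start)
        sd[f"plateau_sd_{cond}"] = float(win.conc[~win.censored].std(ddof=1))

    cl_app_t, cl_app_p = out["control"], out["inhibitor"]
    cl_app_a = active_from_apparent(cl_app_t, cl_app_p)
    q = geometry.flow_endothelial
    cl_int_t = intrinsicize(cl_app_t, q)
    cl_int_p = intrinsicize(cl_app_p, q)
    cl_int_a = active_from_apparent(cl_int_t, cl_int_p)
    papp = papp_from_intrinsic(cl_int_p, geometry)
    tmax = float(max(s.times.max() for s in sers))
    return ClearanceSet(
        donor=donors.pop(), compound=compounds.pop(),
        cl_app_transport=cl_app_t, cl_app_passive=cl_app_p,
        cl_app_active=cl_app_a,
        cl_int_transport=cl_int_t, cl_int_passive=cl_int_p,
        cl_int_active=cl_int_a,
        papp_1e6_cm_s=papp,
        steady_state_window=(window_start, tmax),
        sd=sd,
    )


def inhibitor_effect_test(
    control_plateau: Sequence[float], inhibitor_plateau: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided pooled-variance t test on plateau concentrations.

    Returns (t statistic, p value); significance threshold p < 0.05.
    """
    a = np.asarray(control_plateau, dtype=float)
    b = np.asarray(inhibitor_plateau, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per arm")
    if a.std() == 0 and b.std() == 0:   # degenerate: no within-arm variance
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) if a.mean() > b.mean() else float(-np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
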