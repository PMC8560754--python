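# Methods

## Scope and data flow

The package converts dual-channel perfusion measurements (morphine and M6G
secreted from an endothelial vessel into a proximal-tubule epithelial
channel) into whole-kidney renal clearance and whole-body plasma
pharmacokinetics. The chain is: device clearance reduction → cell-number
scaling → mechanistic kidney model → parent–metabolite PBPK → fold-error
evaluation. No raw effluent or clinical concentration data are distributed;
the synthetic-data module generates both with known ground truth.

## Device reduction

The device is treated as well mixed on the vascular side. At steady state
the tubular efflux rate (windowed mean tubular effluent concentration ×
tubular flow, default window t ≥ 6 h, censored samples excluded) divided by
the vascular concentration gives the apparent clearance; control and
inhibitor arms give the transport and passive components and their
difference the active component, clamped at zero with a warning when the
inhibited device nominally clears faster (the subtraction has no meaning
below zero). Inhibition is treated as complete; inhibitor potency is not
modeled.

*Vascular reference concentration.* The apparent-to-intrinsic correction
`CL_int = Q·CL_app/(Q − CL_app)` is exactly the well-mixed depletion
correction, so `CL_app` must be referenced to the inlet (dosing)
concentration; referencing the depleted vascular effluent would count
depletion twice. The reduction therefore defaults to the nominal dosing
concentration (1 µM) and offers the measured effluent mean as an explicit
option.

*Geometry.* The tubule exchange surface defaults to a cylinder of diameter
120 µm and length 1.31 cm (0.0493 cm²), the combination that makes the
compiled per-donor intrinsic clearance and permeability columns mutually
consistent; both are overridable. 5000 epithelial cells per device.

*Inhibitor effect.* Two-sample pooled-variance two-sided t test on the
windowed plateau concentrations, significance at p < 0.05. Degenerate
zero-variance arms short-circuit to t = 0, p = 1 (equal means) or p = 0.

## Scaling

`CL_secretion = CL_int,active / 5000 cells × 60×10⁶ cells/g kidney × 300 g`,
i.e. 3.6 L/h per µL/h/device, allocated equally across S1–S3. Donor
aggregation is per-donor-then-summarize by default; scaling the donor mean
is provided as an alternative mode (the two differ only in reported
dispersion). Note the shipped compound sheets carry reference secretion
totals (39.3 and 43.5 L/h) that are close to but not identical with the
3.6-fold scaling of the mean per-donor values; the sheets are authoritative
for whole-body simulation, the per-donor route for donor-level prediction.

## Mechanistic kidney model

Structure: six filtrate compartments in series (S1, S2, S3, loop of Henle,
distal tubule, collecting duct) at whole-kidney aggregate scale, each
paired with a peritubular capillary blood compartment; the blood
compartments are themselves in series, fed by kidney blood flow (74.1 L/h)
after glomerular filtration removes unbound drug with the filtrate.

Default physiology (GFR 120 mL/min): filtrate flows 120 → 93.3 → 66.7 → 40
(end proximal tubule) → 24 (end loop) → 12 (end distal) → 1.2 mL/min urine;
filtrate pH 7.23, 7.07, 6.90 along the proximal tubule, 7.40 in the loop,
6.80 distal, 6.30 in the collecting duct; plasma pH 7.4.

Fluxes per segment (linear in concentrations):

* filtration entry: `GFR · fu_p · C_plasma` into S1;
* secretion (S1–S3): `(CL_secretion/3) · fu_b · C_blood,i`, driven by local
  unbound peritubular blood; because blood flow is finite, highly secreted
  donors are supply-limited — this is where the blood-to-plasma ratio acts
  (it sets the erythrocyte reservoir per unit plasma concentration);
* passive permeation, pH-partition: only the unionized fraction
  `f_un(pH) = 1/(1+10^(pKa−pH))` of a monoprotic base crosses, with neutral
  -species permeability `P_u = Papp/f_un(7.4)` — the measured Papp is a
  total-concentration permeability assayed at pH 7.4, so it is divided by
  the unionized fraction at the assay pH before being applied segment by
  segment. Flux = `P_u·A_i·(f_un(pH_i)·C_filtrate − f_un(7.4)·C_unbound,blood)`.

`CL_r = Q_urine·C_urine/C_plasma`. The cascade is linear, so the steady
state has an exact sequential solution; the default `method="ode"`
integrates the same mass balances with a stiff (BDF) solver to steady state
(verified d/dt below tolerance) and agrees with the algebraic route to
1e-6, which doubles as a solver cross-check. The algebraic route is the
fast path inside calibration and GFR sweeps.

*Calibration then freeze.* Exchange areas are the only quantity not fixed
by physiology. The relative profile is set a priori — equal thirds across
S1–S3 and 0.15/0.10/0.06 of that for loop/distal/collecting duct,
reflecting the dominance of the microvillar proximal surface — and one
global scale is tuned by monotone root finding so the morphine reference
inputs (Papp 26.3×10⁻⁶ cm/s, secretion 13.1 L/h per subsegment, fu_p 0.64,
B/P 1.08, pKa 7.9) give CL_r = 8.24 L/h. The result, 31 559 cm² per unit
relative area, is frozen in `parameters.py`; M6G, the six per-donor
predictions and the CKD sweep use it unchanged and are genuine predictions.

*CKD.* Intact-nephron proportionality: GFR, all filtrate flows, urine flow,
secretion, and (configurably, default on) kidney blood flow scale with
`GFR_target/120`. Exchange areas are held fixed by default with an opt-in
flag to scale them as well; with areas fixed, low-GFR tubules equilibrate
more deeply and clearance falls faster than proportionally.

## Whole-body PBPK

Twelve perfusion-limited tissues (adipose, bone, brain, gut, heart, kidney,
liver, lung, muscle, pancreas, skin, spleen) with lung in series at cardiac
output (361 L/h) and gut/pancreas/spleen draining through the liver (total
hepatic flow 99.7 L/h). The liver is well-stirred; the intrinsic metabolic
clearance is back-calculated from hepatic clearance (itself systemic minus
renal clearance) as `CL_int = Q_h·CL_h/(fu_b·(Q_h − CL_h))`. A fixed molar
fraction f_m = 0.1 of parent elimination enters the liver compartment as
M6G; M6G hepatic clearance is taken as negligible. Renal elimination for
each analyte is `CL_r·C_arterial plasma` with CL_r from the kidney model —
the same plasma reference used to define CL_r, which makes `Dose/AUC =
CL_h + CL_r` hold exactly for linear kinetics.

*Circulatory convention.* Transport fluxes carry plasma concentration at
nominal organ blood flows; B/P enters through fu_b, the erythrocyte term of
V_ss, and the kidney submodel. This is the convention under which the
reference hepatic values (CL_h 75.3, CL_int 520 L/h at Q_h 99.7) are
mutually consistent, and it leaves clearances, AUC and V_ss exact while
slightly approximating transient organ equilibration for compounds with
B/P far from 1.

*Distribution.* `V_ss = V_plasma + V_ery·Kp_ery + Σ V_t·Kp_t` with
`Kp_ery = (B/P − (1−Hct))/Hct` clamped at zero. The reference-human table
(Σ tissue volume ≈ 59.8 L, plasma 3 L, erythrocytes 2 L, Hct 0.40) was
chosen once, within physiological ranges for a 70-kg adult, to be
consistent with both reference distribution volumes (morphine 141 L with
its optimized Kp set, M6G 21 L with Kp = 0.3 everywhere); it reproduces
them to within 1.2% and 0.3%.

Amounts are integrated in nmol (concentrations nM) with BDF at rtol 1e-8 /
atol 1e-12; infusions are integrated piecewise at the on/off switch. Mass
balance (body + urine + hepatically eliminated vs administered) is reported
and holds to ~1e-10 of dose; metabolite accounting is molar, with molecular
weights used only at the mass-concentration reporting edge.

## Evaluation

`AAFE = 10^((1/n)Σ|log10(sim/obs)|)` over observed points that are neither
censored nor below the quantification limit, with the simulation
interpolated log-linearly (PK decays are exponential-like) onto observation
times; the twofold acceptance boundary is inclusive. The NCA oracle uses
linear-up/log-down trapezoids with log-linear terminal extrapolation,
bolus back-extrapolation of C(0), and `V_ss = CL·MRT` (infusion-corrected).

## Synthetic data

Effluent generation models the tubular outlet as a single-exponential
approach to the steady-state plateau `C_ss = CL_app·C_vessel/Q_tub` (time
constant 2 h, so the plateau is established within the 6-h steady-state
window; the device mixing time is not otherwise modeled), multiplicative
unit-median lognormal noise (default CV 15%), and censoring below 2 nM with
flags retained rather than samples dropped. Clinical-style observations are
simulated profiles resampled with proportional lognormal error and 3.5 nM
censoring. Donor panels draw active clearance lognormally (default
dispersion 1.0, spanning the order-of-magnitude inter-donor range seen in
primary proximal tubule cells), rejecting draws that would exceed channel
flow. Defaults were chosen for test power: real assay error structure,
device-to-device geometry variation, and time-correlated drift are not
emulated, so passing recovery tests demonstrates correctness of the
estimators, not robustness to every laboratory artifact.

## Numerical and design notes

* Steady-state estimator is a windowed mean, not a regression; with the
  2-h time constant the residual transient bias at a 6-h window start is
  under 1%, and tests that assert sub-0.1% recovery use a later window.
* Negative active clearances clamp to zero with a warning.
* `intrinsicize` raises in the flow-limited regime CL_app ≥ Q, where the
  intrinsic value is undefined.
* The CKD sweep returns per-GFR clearances by rescale-and-resolve; it is
  monotone increasing in GFR for both compounds. The predicted M6G excess
  over morphine (≈38% at GFR 120, growing toward low GFR) exceeds the
  10–30% band sometimes quoted for this ratio; note the reference renal
  clearances themselves (10.84 vs 8.24 L/h) already imply a 31.6% excess at
  baseline GFR.
* Determinism: every stochastic element takes an explicit seed; the
  pipeline manifest records config hash and per-artifact digests, and a
  rerun with the same configuration is bit-identical.

## Known limitations

Single-pathway nephron (no heterogeneity between superficial and
juxtamedullary nephrons); linear secretion (no transporter saturation or
inhibition kinetics in vivo); no megalin-mediated reabsorption; urine pH
fixed at the default profile; M6G biliary recycling absent; no oral
absorption or other metabolites; no inter-individual variability
simulation. The exchange-area calibration absorbs any structural error in
the segment table into one parameter, so the areas should be read as
effective, not anatomical, quantities.
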