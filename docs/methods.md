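# Methods

`hemocal` models a patient's circulation as a closed-loop hydraulic circuit
and tunes its boundary conditions until the simulated hemodynamics match a
clinical target table. This note records the model, its assumptions, the
numerical choices, and what the synthetic study design does and does not
establish.

## The circulation model

**Unit system.** All internal quantities are in g–mm–s units: pressure in
g/(mm·s²), which equals the pascal (1 mmHg = 133.322), flow in mm³/s,
resistance in g/(mm⁴·s), compliance in mm⁴·s²/g, inertance in g/mm⁴.
Clinical I/O (mmHg, L/min, mL) is converted at the boundary. Blood is
Newtonian with ρ = 1.06·10⁻³ g/mm³ and μ = 4·10⁻³ g/(mm·s).

**Heart.** Each side is an atrium → inflow valve (ideal diode + inertance)
→ ventricle → outflow valve (smoothly switched resistance + inertance) →
arterial root capacitor chain. Ventricles are time-varying elastance
chambers, P = E(t)·(V − V₀), with a shifted-cosine activation (C¹, peak at
mid-systole, systolic fraction 0.34 of the period by default). A dynamic
source resistance Rs(t) = k·E(t)·(V − V₀) (k = 4·10⁻⁷ s/mm³ by default,
i.e. 4·10⁻⁴ s/mL) is placed in series with the outflow valve; because no
other branch attaches between chamber and valve, it is folded into the
valve's on-resistance without changing the circuit. Atria are
constant-elastance chambers by default (no atrial kick; a time-varying
atrial shape can be configured through the same chamber parameters).
Valve numbers (inertances 7·10⁻⁶ g/mm⁴, on-resistances 4–6·10⁻⁴ g/(mm⁴·s),
off/on ratio 10⁸, 1 mmHg switching width) are this package's defaults from
common 0D practice — no published values back them.

**Arteries.** The large systemic (AAo → arch branch, DTA) and pulmonary
(MPA → LPA/RPA → two sub-branches each) arteries are thin-walled elastic
tubes lumped into RLC L-sections: per segment, R = 8μl/(πRi⁴),
L = ρl/(πRi²), C = 3πRi³l/(2Eh). The 3/2 factor matches the linearized
stiffness estimator below, so stiffness estimated from pressures and radii
round-trips exactly into segment compliance. Five sections per named
vessel (two for the small branches) trade wave fidelity for speed; the
foot-to-foot wave speed on this ladder converges toward the
Moens–Korteweg value from above as sections increase, with a residual
≈ √(4/3) − 1 ≈ 15 % inherent to the compliance-factor convention.

**Beds and veins.** Each arterial outlet carries a 3-element Windkessel
(Rp = 0.15 of the outlet resistance, Rd the rest, compliance split across
outlets by a Murray r³ rule). In the closed loop, the outlet drains feed
venous Windkessel pathways (small resistance, large compliance) returning
to the atria. Wall stiffness is estimated from systolic/diastolic pressure
and lumen radius as E = 1.5·ΔP·Ri²·Ro/((Ro² − Ri²)·ΔR) with
Ro = 1.15·Ri (15 % wall-thickness-to-radius ratio), linearly interpolated
along the centerline between measured sites; unmeasured branches take the
nearest measured segment's value.

## Solver

Backward-Euler companion models assembled by modified nodal analysis at a
fixed 0.1 ms step (the step is nudged to divide the heart period exactly).
Diodes switch between on/off resistance via an inner consistency
iteration; controlled valve resistances use a logistic transition over
1 mmHg evaluated semi-explicitly with one refinement pass. Series R–L
section pairs are merged into single companion branches internally (the
netlist keeps them as separate components). The implicit scheme is
L-stable, which the stiff valve transitions require; storage updates are
flow-consistent, so total stressed volume in a closed loop is conserved to
linear-solver round-off (verified ≤ 0.1 % per cycle). Each run integrates
until the cycle-to-cycle relative L∞ change of every monitored waveform
falls below 10⁻³ (default) or 20 cycles elapse; the tolerance and cap are
configuration, not physiology. A continuous-time right-hand-side view of
the assembled system is exposed for cross-checking against general-purpose
ODE integrators.

## Calibration

Stage 1 drives the open-loop arterial trees with the measured AAo and MPA
flow waveforms and tunes the Windkessel totals by fixed point:
R_T ← R_T + (P̄_target − P̄_sim)/Q̄_sim against mean pressure, and
C_T ← C_T·(PP_sim/PP_target) against pulse pressure (this orientation is
contractive for an RC bed: more compliance, less pulse). Outlet parameters
scale proportionally with the totals, preserving inter-outlet ratios
exactly. Gates: mean and pulse pressure at DTA and MPA. Stage 2 replaces
the imposed flows with the 0D heart (atria filled from preload
reservoirs) and additionally scales initial/source pressures by the mean
of the flow and mean-pressure target/simulated ratios (arithmetic by
default, geometric on request), gating also on mean flow at AAo and MPA.
Stage 3 closes the loop through the venous pathways; the initial nodal
pressures — which set the total stressed volume and hence the operating
point — are scaled side-wise by the same rule, and ventricular peak
elastance is tuned against imaging-style end-systolic volumes when the
target table carries them (systolic-pressure ratio otherwise). Measured
atrial filling pressures (wedge/right-atrial means), when present, anchor
the venous compartments so resistance totals are identifiable rather than
absorbed into an arbitrary atrial offset. Stage-3 gates: mean, systolic,
diastolic and pulse pressure plus mean flow at MPA and AAo, each as
|measured − simulated|/|measured| × 100 against a 10 % threshold.

All multiplicative updates are under-relaxed (0.7; 0.5 for elastance) to
prevent oscillation. Stages stop early once the worst gate sits below
0.65× the threshold, so the final verified errors are comfortably inside
it; the convergence flag itself is judged against the full threshold on a
fresh verification run of the calibrated model integrated to full
periodicity. The calibrated state (including the converged nodal
pressures) is stored with the model, making re-simulation start on the
limit cycle. Between 30 and 60 parameters are exposed per patient
(3 per arterial outlet and venous pathway, two peak elastances, preloads,
and the key-node initial pressures); the report counts them.

**Identifiability.** With the 10 % clinical gate the vascular totals are
recovered only as sharply as the gate: resistance to a few percent,
compliance more loosely because dPulse/dC is shallow when the peripheral
compliance sits behind its proximal resistance. The parameter-recovery
protocol therefore uses a tighter gate (1.5 %) with a higher stage-3
iteration cap; under it, total pulmonary resistance recovers within 2 %
and compliance within 10 % of ground truth on clean targets. Compliance
remains identifiable only up to waveform-shape effects, which is why its
tolerance is wider. During development a smaller proximal fraction
(rp ≈ 0.07) was tried to sharpen dPulse/dC; it instead produced a regime
where pulse pressure grows with compliance (the diastolic level collapses
into the fast-filling peripheral reservoir) and the fixed point diverges —
the 0.15 convention is kept for both the generator and the initial model.

## Synthetic study design

The virtual-patient generator emulates the measurement set of a pediatric
PAH imaging/catheterization study: per-site pressure and flow summaries at
AAo, DTA, MPA, LPA, RPA, inlet flow waveforms, wedge/right-atrial
pressures, MRI-style ventricular volumes, and a geometry table with
diastolic radii plus systolic radii consistent with the stiffness
estimator. Severity profiles (normal / moderate / severe) scale pulmonary
vascular resistance (×1/×3.2/×7), wall stiffness (×1/×2.2/×3.6, peripheral
compliance scaling inversely) and right-ventricular contractility
(×1/×2.6/×4.8) so mean PAP lands near 20, 45–60 and 80–100 mmHg — the
documented bands 14–30 / 33–65 / 70–115 mmHg — at maintained cardiac
output: the compensated phase of progressive PAH. Anatomy and physiology
are sampled per seed from pediatric-plausible ranges (MPA radius 8–14 mm,
heart rate 70–110 bpm, BSA 0.9–1.9 m², cardiac index 3.8 L/min/m²); a
damped fill-volume loop scales the initial pressures until cardiac output
matches the sampled target, emulating volume regulation. Longitudinal
pairs rescale stiffness, peripheral resistance and compliance (worsening
also raises RV contractility) and re-simulate. Measurement noise is
multiplicative Gaussian per metric with systolic/diastolic re-ordering and
pulse recomputation.

What passing tests show: the pipeline recovers parameters of circulations
drawn from its own model family, converges under its stated criterion, and
respects the physics invariants. What they do not show: robustness to
model mismatch (real vessels taper and are nonlinear, real valves leak,
real measurements are not Gaussian-perturbed model outputs), nor anything
about shunt physiologies (a patent ductus arteriosus, as in one study
patient, is outside the modeled topology and noted as an extension point).

## Numerical and protocol choices

* Time step 0.1 ms; periodicity tolerance 10⁻³ with max 20 cycles;
  calibration iterations simulate 8 cycles warm-started from the previous
  end state (the state is part of the calibrated parameter set).
* Extremum ties on pressure plateaus resolve to the first time index.
* Heart-valve off-resistance 10⁸× on-resistance (generic diodes default
  to 10⁶×); non-finite states abort with the offending node named. The
  smoothly switched outflow valves admit a brief inertial backflow while
  closing (a closing-regurgitation volume of ~1–3 % of stroke volume,
  consistent with the 1 mmHg transition width); the diode inflow valves
  are reverse-tight to 10⁻⁶ of peak flow.
* Percent errors and changes are undefined at a zero baseline and raise.
* Foot-to-foot PWV locates the wave foot by the intersecting-tangent
  method (tangent at maximum upslope intersected with the waveform
  minimum); non-positive transit times raise, negative raw delays wrap by
  one period. Both this estimator and the Moens–Korteweg form
  √(Eh/(2ρRi)) are reported, labelled by method.
* Stiffness is reported in the pressure unit of ΔP (the internal unit
  equals the pascal); printed-convention labels in the example dataset are
  carried through as-is rather than re-derived.
* The CLI and library are deterministic given a seed; reports serialize
  with sorted keys and keep timestamps in a separate field so reruns are
  comparable bit-for-bit.

## Problem sizes

The default study runs one moderate-severity virtual patient
(≈ 60-pressure-node closed loop, ≈ 6 700 steps per cycle at a typical
heart rate) through generation (≤ 5 fill-tuning simulations) and the
three-stage calibration (≈ 15–30 simulations of up to 8 cycles each);
end-to-end this is a couple of minutes on one core. Larger cohorts scale
linearly and are embarrassingly parallel across patients.

## Known limitations

* The reduced-order tree replaces a 3D fluid–structure domain; wave
  reflection detail, curvature, tapering and nonlinear wall laws are out
  of scope, and foot-to-foot PWV inherits the ladder's ~15 % convention
  bias.
* Compliance recovery degrades gracefully with measurement noise and gate
  width; it is the least identifiable of the tuned quantities.
* The heart model has no pericardial or septal interaction and no
  finite-element mechanics; contractility enters only through peak
  elastance and the source resistance.
* Venous parameters are fixed conventions, not calibrated per patient
  (only their stored volumes move, through the initial-pressure updates).
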