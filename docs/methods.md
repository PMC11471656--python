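# Methods

`dissectflow` simulates pulsatile blood flow through an idealized,
two-dimensional model of a dissected internal carotid artery and derives the
hemodynamic quantities and categorical risk assessments a clinician-facing
FSI study reports: shear strain rate, wall shear stress (WSS) and its
streamwise gradient (WSSG), intraluminal pressure and the true/false-lumen
pressure difference, wall deformation, shear-rate dwell times, and rules for
thrombosis, platelet activation, dissection extension, aneurysm formation and
functional occlusion.

## The synthetic geometry

No patient geometry is distributed with the package; the generator produces a
planar analog of a segmented dissected ICA and is first-class, tested code.
The default vessel is a 60 mm channel with a 6 mm parent lumen and a wall
whose thickness is one eighth of the outer diameter (1 mm), the value a
carotid wall shows on Doppler.  Onto this it places:

* a **dissection** over x = 15–35 mm: an intimal flap (0.6 mm thick, clamped
  at the proximal tear) splits the lumen into a stenotic **true lumen**
  (35 % of the parent width, adjacent to the lower wall) and a **false
  lumen** above it;
* a **blind false-lumen terminus** (default): the upper wall notches down to
  meet the flap plane distally and a seal segment closes the pocket, leaving
  it fed only through the proximal mouth.  A `reentry` topology leaves a
  distal slot instead.  Imaging rarely resolves which applies, so both are
  supported and neither is claimed to match any patient;
* an **intramural-hematoma bulge**: a 1 mm Gaussian thickening of the upper
  wall bulging into the lumen just upstream of the tear;
* a **distal kink**: a smooth 20-degree S-offset of the whole vessel in the
  C4-labelled interval.

Axial quartiles carry the radiological labels C1–C4; named probe sites mark
the true-lumen throat, the false-lumen terminus, the paired mid-dissection
stations used for the pressure difference, the bulge, the kink and the flap
tip.  A shoelace-audit invariant holds by construction: over the flap's span,
area(true) + area(false) + area(flap ribbon) equals the parent-lumen area.

Planar 2D was chosen over axisymmetry because a flap that splits the lumen
asymmetrically has no axisymmetric representation; all fluxes are per unit
depth.  The flap is modelled thicker than a real intima (0.6 mm) — thin
enough to move, thick enough that one default grid cell resolves the ribbon.

## Flow solver

Incompressible Newtonian flow (ρ = 1062 kg/m³, η = 0.0037 Pa·s, the
high-shear viscosity of blood) on a fixed uniform staggered (MAC) grid:

* the lumen is carved from the rectangle by masking cells outside the inner
  wall surfaces — a sharp staircase boundary that is exactly conservative;
* the flap and the terminus seal block the grid faces they cross, so the
  pressure jump between true and false lumen is supported exactly (this is
  what produces the Venturi deficit of the true lumen);
* explicit first-order upwind advection (CFL 0.4, adaptive dt), explicit
  central viscosity, and a pressure projection solved by a direct sparse
  factorization built once per geometry.  After every projection the discrete
  divergence (minus the prescribed interface sources) is at solver precision;
* boundary conditions are Dirichlet pressure on the inlet and outlet spans
  and no-slip (ghost-reflection) on every solid face.  The inlet follows the
  regime waveform; the outlet is held 10 mmHg below the regime diastolic.

Validation oracles (run by `run_validation_suite` and the test suite): the
plane-Poiseuille profile and its wall shear stress 6ηU/h at 64 cells across
the channel (errors ≈ 0.02 % and ≈ 1 %), steady mass conservation on the
dissected vessel (direct projection: machine precision), and the Venturi sign
p(throat) < p(bulge).

## Structures and coupling

**Outer wall.** Quasi-static spring-backed stations along both inner wall
surfaces: k = E·h_wall/((1−ν²)R²) (thin-wall relation, R the local reference
half-width), displacement (p − p_ref)/k smoothed along arclength, pinned at
the constrained vessel ends.  The reference pressure is the regime diastolic,
i.e. the generated geometry is the diastolic configuration; deformation
therefore scales with pulse pressure, which is what makes the hypertensive
regime deform the wall most and the stiff (4 MPa) wall deform least.

**Flap.** A filament clamped at the proximal tear, deflecting transversally
under the trans-flap pressure load q by a tension-corrected Euler–Bernoulli
equation B d'''' − T d'' = q with B = E h³/(12(1−ν²)).  With both ends held
(blind topology: the tip rests against the distal seal and is pinned) the
membrane tension T is resolved self-consistently from the elongation of the
deflected shape — the mechanism that keeps a 20 mm intimal sheet from
ballooning across the lumen under kilopascal loads.  The axial stiffness
carries a near-inextensibility penalty (×10) so the filament length changes
by well under 1 % per cycle.  A free tip (reentry) reduces exactly to the
cantilever, validated against qL⁴/(8EI) and its 1/E scaling.  The flap
relaxes toward its static equilibrium with a 20 ms time constant,
representing the added mass of the blood a thin sheet must drag (for this
geometry ρL ≈ 20 kg/m², giving a natural period of ~40 ms).

**Coupling.** Partitioned and serially staggered.  Within each time step the
advection/viscous predictor is computed once; then the pressure projection
and the structure updates are fixed-point sub-iterated on the interface
displacement with Aitken relaxation (tolerance 10⁻⁴ of the parent lumen
width, default 8 sub-iterations; non-convergence is recorded as a warning,
never a crash — in practice it occurs only during the first startup
transient).  Structure motion feeds back on the flow as interface volume
sources in the projection: a boundary receding from the fluid is a sink, an
advancing one a source.  This small-displacement linearization replaces
moving meshes or immersed-boundary force spreading; it is appropriate here
because wall displacements are a few hundredths of a millimetre and flap
excursions stay near one grid cell.  In the rigid limit (E → 10¹² Pa) the
loop converges in one sub-iteration with sub-nanometre displacement.

## Study protocol

The default study crosses three inlet regimes — hypotension 100/60,
normotension 120/80, hypertension 160/100 mmHg — with two wall stiffnesses —
normal 1.5 MPa and atherosclerotic 4 MPa (ν = 0.49) — on the same geometry:
six conditions.  The inlet waveform has a 0.86 s period (≈ 70 bpm), a
quarter-sine systolic upstroke over 35 % of the cycle and an exponential
diastolic decay, rescaled to hit the regime extrema exactly.  Each condition
runs three cycles and the third is analyzed, by which point successive-cycle
probe differences are below 1 % (the periodicity audit measures ~1.6 %
between cycles 2–3 and ~0.03 % between 3–4 on the default run).  Probe series
are recorded every step; field snapshots, wall shear series and structure
displacements at 256 phases per cycle.

Reported per condition, split at the systolic fraction into systole/diastole:
velocity, shear-rate, pressure and WSS extrema each with the probe/station
that produced it; ΔP(t) = P_true − P_false at paired mid-dissection stations
(probe placement is configurable; no exact coordinates exist to copy); wall
deformation maxima (total and per axis); flap-tip WSS; the maximum systolic
WSSG over the dissection wall; and dwell times against the shear-rate
threshold catalog (above 2 600 and 4 000 1/s at the throat; below 100, 50,
10, 5 1/s at the terminus), with percent-of-cycle rounded to one decimal,
half away from zero.

The scalar shear rate is γ = √(2 D:D) with D the symmetric velocity-gradient
tensor — consistent with the Newtonian wall relation τ = ηγ used throughout.
WSS is sampled 0.75 cells into the fluid along the station normal
(τ = η|u_t|/δ); WSSG is the signed streamwise derivative d(WSS)/ds in Pa/mm,
central differences at interior stations.

## Risk rules

All cut-offs live in `RiskThresholds` and are overridable; boundaries are
inclusive toward the higher risk level; every rule is monotone in its
evidence.

* **Low-shear thrombosis**: percent of cycle below 10 1/s at the terminus;
  high ≥ 35 %, moderate ≥ 15 %.  The literature flags ~40 % as significant
  and does not flag ~26 %; the defaults sit between and are declared, not
  inferred.
* **High-shear platelet activation**: any dwell above 4 000 1/s is high; any
  above 2 600 1/s is moderate.
* **Dissection extension**: systolic flap-tip WSS against the 2.5–4.5 Pa
  physiologic band; ≤ 4.5 Pa low, > 9 Pa high.
* **Aneurysm formation**: elevated when the max systolic WSSG over the
  dissection wall exceeds −0.32 Pa/mm.  The report carries a caveat: that
  published cut-off is permissive (almost any positive maximum exceeds it);
  the informative output is the *locus* of the maximum, which on the default
  geometry falls on the true-lumen wall at the proximal dissection (the
  C2-labelled interval).
* **Functional occlusion**: high when the flap excursion reaches half the
  throat width; moderate when a trans-flap pressure gradient exists without
  that much motion.

## What the synthetic model does and does not show

The generator reproduces the *mechanistic loci* of a dissected carotid — a
throat jet with the shear maximum, a stagnant blind pocket with the shear
minimum, a Venturi pressure deficit loading the flap, pressure-scaled wall
deformation — and the tests assert exactly those orderings and
localizations.  It does not reproduce any patient's numbers: magnitudes of
velocity, ΔP, WSS and deformation depend on the real 3D geometry.  Two
known departures from clinical observations of this lesion type: the 2D
blind pocket is far more stagnant than a real false lumen (its terminus
shear rate is ~0, so the below-10 1/s dwell saturates at 100 % in every
regime rather than separating regimes), and the thin 2D flap bows by about a
millimetre under the trans-flap gradient where a thick 3D flap attached
along its lateral edges barely moves — in this model the occlusion risk
rule therefore fires on flap motion, most strongly under hypertension.

## Numerical choices and limitations

* Grid: square cells, default 0.5 mm (120 × 24 for the default vessel, ~3–4
  cells across the throat); time step adaptive at CFL 0.4 with a 0.2 dx²/ν
  viscous bound and a 0.2 ms cap; ≥ 256 field samples per cycle.  These
  desk-scale sizes run a full six-condition study in minutes on one CPU.
* First-order upwind advection adds numerical diffusion; at this resolution
  the throat jet is steadier and more diffuse than a high-Re jet would be.
* The staircase wall is first-order near boundaries; quantitative WSS
  accuracy is validated only on the grid-aligned Poiseuille channel, and
  vessel-wall WSS should be read as trends, not calibrated magnitudes.
* No contact mechanics: a flap approaching a wall is reported (and the
  occlusion rule fires); penetration is prevented only by the membrane
  tension, not by contact forces.
* Newtonian rheology and isotropic linear-elastic walls; no non-Newtonian
  low-shear viscosity rise, no layered wall, no vessel tapering, no
  autoregulation, no heart-rate variability.
* Degenerate inputs raise: flap thinner than a grid cell (rasterizer),
  overlapping lumens, flap markers collapsing below half a cell.
* The cycle percentages in the dwell table use the cycle duration they were
  measured on; both 0.86 s and a 0.87 s denominator are representable since
  the period is a plain config field.
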