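# dissectflow

Desk-scale fluid–structure interaction study of an idealized **dissected
internal carotid artery**.

A carotid dissection tears the vessel's inner layers, creating a second
(false) blood channel alongside the original (true) lumen, separated by a
mobile intimal flap. Whether such a lesion thromboses, extends, dilates into
an aneurysm, or transiently occludes the true lumen depends on hemodynamic
quantities no scan measures directly: shear strain rate γ, wall shear stress
τ = ηγ, its streamwise gradient (WSSG, Pa/mm), the pressure difference
between the lumens, and the motion of the flap and wall. `dissectflow` builds
a two-dimensional synthetic analog of such a vessel — stenotic true lumen,
blind false lumen, intimal flap, intramural-hematoma bulge, distal kink,
wall thickness one eighth of the outer diameter — and simulates pulsatile
blood flow through it with two-way flow–structure coupling under a 3 × 2
condition matrix: hypotension (100/60), normotension (120/80) and
hypertension (160/100 mmHg) crossed with a normal (E = 1.5 MPa) and an
atherosclerotic (E = 4 MPa) wall. From each run it reports the phase-split
extrema a clinical FSI study tabulates, shear-rate dwell times against the
platelet-activation (> 2 600, > 4 000 s⁻¹) and stasis (< 10 s⁻¹) thresholds,
and categorical risk assessments (thrombosis, platelet activation, dissection
extension, aneurysm formation, functional occlusion) with the numeric
evidence behind each.

The core is a masked staggered-grid projection solver for incompressible
Newtonian flow (ρ = 1062 kg/m³, η = 0.0037 Pa·s) driven by Dirichlet
pressure at inlet and outlet (outlet fixed 10 mmHg below the regime
diastolic; cycle 0.86 s ≈ 70 bpm), a tension-corrected Euler–Bernoulli flap
filament, a quasi-static spring-backed wall (thin-wall stiffness
k = E·h/((1−ν²)R²)), and partitioned coupling with Aitken relaxation. See
`docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Steady flow under a 10 mmHg drop (`python examples/03_steady_venturi.py`):

```
inlet flux 2.382e-03 m^2/s, outlet flux 2.382e-03 m^2/s (mismatch 3.8e-15)
bulge                  p =  1296.5 Pa   |u| =  0.61 m/s
true_lumen_throat      p =   552.4 Pa   |u| =  1.23 m/s
false_lumen_mid        p =  1312.3 Pa   |u| =  0.00 m/s
false_lumen_terminus   p =  1312.3 Pa   |u| =  0.00 m/s
kink                   p =    -3.4 Pa   |u| =  0.74 m/s

true - false lumen pressure difference: -856.8 Pa (negative)
```

The stenotic true lumen carries a fast jet at *lower* pressure than the
stagnant false lumen (the Venturi effect) — the pressure gradient that loads
the intimal flap toward the true lumen; the lowest pressure of all sits at
the distal kink, and mass balance holds to machine precision. A full
pulsatile condition with the phase-split summary, dwell table and deformation
report is `examples/04_pulsatile_condition.py`; on the normotensive default
it places the systolic shear-rate maximum (2 981 s⁻¹) at the true-lumen
throat, the minimum (~0 s⁻¹) at the blind false-lumen terminus, a systolic
true−false ΔP of −4 829 Pa, and the largest systolic WSSG (4.05 Pa/mm) on
the true-lumen wall at the proximal dissection (C2) — the locus the aneurysm
rule reports as the predicted dilatation site.

The other examples cover geometry generation and its area audit
(`01_build_geometry.py`), pressure regimes and the inlet waveform
(`02_pressure_regimes.py`), the compiled risk report (`05_risk_report.py`)
and the analytic validation suite (`06_validation_suite.py`).

A thin CLI wraps the same library calls:

```sh
dissectflow generate-geometry -o out/   # polyline CSV + legacy VTK
dissectflow run -o out/                 # the six-condition study
dissectflow validate --full             # analytic validation suite
dissectflow report -o out/              # re-print a study's risk report
```

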