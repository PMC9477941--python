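# cardiowave

A desk-scale simulator of heart–vessel interaction: a 1D arterial
pulse-wave solver monolithically coupled to reduced-order cardiac cavity
models through a saddle-point volume/pressure scheme.

## Who this is for

Alterations of the arterial tree — stiffening with age, a coarctation, the
wave reflections generated at bifurcations — change the pulsatile load the
circulation imposes on the ejecting ventricle. Lumped (0D) afterload models
cannot represent these wave-transmission effects; 3D fluid–structure models
are far too heavy for parameter studies. `cardiowave` occupies the middle
ground: it propagates genuine pulse waves along a compliant arterial
network and feeds them back onto a beating cardiac cavity, at a cost of
seconds per heartbeat on a laptop. It is aimed at students and researchers
in computational haemodynamics who want a transparent, fully testable
implementation of the heart–artery coupling problem.

## The model

**Vessels.** Mass and momentum balance of blood in a compliant tube,

```
A_t + Q_x = 0
Q_t + (α Q²/A)_x + (A/ρ) P_x = f/ρ
```

with cross-sectional area `A`, flow `Q`, Coriolis coefficient `α = 1.1`,
and friction `f = −2π(ζ+2) μ u` for a power-law velocity profile (ζ = 9).
The wall is a Voigt visco-elastic ring,

```
P = P_ext + K (√A − √A0)/A0 + G (A0 √A)⁻¹ A_t ,
K = (4/3)√π E h ,   G = (2/3)√π φ h ,
```

giving the elastic wave speed `c(A) = √(K√A / 2ρA0)`. The discretisation
is a second-order MUSCL finite-volume scheme with an HLL flux and
two-stage explicit Runge–Kutta time stepping under a CFL bound; the
viscous wall term is an implicit (unconditionally stable) correction.

**Boundaries.** Characteristic-based inlet forcing; three-element (Z–R–C)
Windkessel terminals, `Q(1 + Z/R) + CZ Q_t = (P − P_out)/R + C P_t`;
junctions enforcing mass conservation and total-pressure continuity; and a
Young–Tsai-type lumped stenosis, `Δp = Kv μ/(A0 D0) q + Kt ρ/(2A0²)
(A0/As − 1)² q|q| + Ku ρ Ls/A0 q̇`.

**Heart.** Interchangeable cavity models exposing `V_heart(p, t)`:
a time-varying elastance chamber, and a thick-walled incompressible sphere
whose wall carries the transversely isotropic Guccione strain energy
`Ψ = κ/2 (log J)² + C/2 (e^Q − 1)` and an orthotropic active stress (full
force along the fibre, 40% along the sheet) driven by the phenomenological
transient `S_a = S_peak φ(λ) tanh²(t_s/τ_c) tanh²((t_dur−t_s)/τ_r)`.
The aortic valve is a Bernoulli resistor with blood inertance acting as a
diode.

**Coupling.** At each coupling step the cavity pressure `p` is the extra
unknown of the saddle-point condition `V_heart(p) − V_CS(p) = 0`, where
`V_CS(p)` is obtained by actually sub-stepping the valve + network over
the coupling window at trial pressure `p`. A scalar Newton iteration
(k_max = 10, absolute residual 1e-6 mL) with a finite-difference vascular
compliance `dV_CS/dp` solves it; during isovolumetric phases the vascular
side degenerates (`C' = 0`, `V_CS = V0`) and pressure adjusts to the
evolving active stress at constant volume. A four-phase machine (filling →
isovolumetric contraction → ejection → isovolumetric relaxation) sequences
the beat.

## Worked example

```python
from cardiowave import benchmarks

traces, beats, net = benchmarks.coupled_run(
    benchmarks.make_single_vessel(length=0.126, E=0.25e6),
    beats=3, init_cycles=10)
last = beats.iloc[-1]
print(f"EDV {last['EDV']*1e6:.1f} mL  ESV {last['ESV']*1e6:.1f} mL  "
      f"EF {last['EF']:.2f}")
print(f"aortic pressure {last['p_root_max']/133.322:.0f}/"
      f"{last['p_root_min']/133.322:.0f} mmHg")
```

prints, for the baseline 126 mm aortic segment (E = 0.25 MPa) after three
coupled beats:

```
EDV 120.9 mL  ESV 56.3 mL  EF 0.53
aortic pressure 120/61 mmHg
```

i.e. a normal left-ventricular end-diastolic/end-systolic volume pair, a
normal ejection fraction, and a normotensive central pressure. Raising the
Young modulus to 0.75 MPa raises peak aortic pressure to ~139 mmHg and the
end-systolic volume with it — the classic afterload response to aortic
stiffening — while end-diastolic volume, which is preload-controlled, does
not move.

The same module exposes the other studies: `dt_robustness_study` (the
solution is unchanged across vascular sub-steps 5e-4…5e-5 s),
`stiffening_study(stenosis=True)` (a 30% mid-aortic coarctation raises
peak LV pressure), and `tree_study` (pulse-pressure amplification towards
the periphery of a bifurcating tree, stronger in a young vessel profile
than an aged one).

A shell interface is available as `cardiowave run <config.yaml>`,
`cardiowave verify`, and `cardiowave make-fixture <name>`; simulations are
configured by YAML files with SI-unit-suffixed keys and write delimited
text traces.

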