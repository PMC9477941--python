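# Methods

This note records the model equations as implemented, the defaults and why
they were chosen, the numerical choices that matter, and the known
limitations. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1D blood flow

The solver integrates the (A, Q) form of the cross-sectionally averaged
Navier–Stokes equations,

    A_t + Q_x = 0
    Q_t + (α Q²/A)_x + (A/ρ) P_x = f/ρ ,

closed by the Voigt visco-elastic tube law

    P = P_ext + K (√A − √A0)/A0 + G Ψ,   Ψ = (A0 √A)⁻¹ A_t,
    K = (4/3)√π E h,   G = (2/3)√π φ h.

The momentum-flux correction is applied in the conservative (A, Q)
formulation with a configurable Coriolis coefficient; the flat-profile
(A, u) variant is not a separate code path — setting α = 1 recovers it.
The friction model is a power-law velocity profile of exponent ζ:
f = −2π(ζ+2) μ u, and α = (ζ+2)/(ζ+1). The default ζ = 9 yields α = 1.1,
the standard large-artery value. Blood: ρ = 1060 kg/m³, μ = 4 mPa s
(the tabulated value labelled ν is used as a dynamic viscosity — its unit,
Pa s, decides). Wall viscosity defaults to φ = 1 kPa s; a tabulated
"1 kPa" wall-viscosity magnitude cannot be a G (units Pa s m), so it is
read as φ and both φ and G remain configurable.

### Discretisation

* Space: cell-centred finite volumes, MUSCL linear reconstruction
  (minmod default; monotonised-central and unlimited slopes available) and
  an HLL flux with wave-speed estimates αu ± √(c² + α(α−1)u²). The
  pressure-gradient term enters through the flux potential
  B(A) = K A^{3/2}/(3ρA0); tapered vessels sample A0(x), E(x) piecewise
  constant per element and the corresponding non-conservative products
  appear as centred source terms (analytically well-balanced at rest;
  discretely balanced to second order).
* Time: two-stage explicit SSP Runge–Kutta under dt = CFL·min(Δx/(|u|+c)),
  CFL default 0.9. The Voigt wall term, a diffusion on Q of coefficient
  G√A/(ρA0), would impose a Δx² step limit if explicit, so it is split off
  and integrated implicitly (backward Euler, Thomas solve) each sub-step.
  Splitting keeps the hyperbolic core and its characteristics purely
  elastic.
* Boundaries: each vessel end exchanges its outgoing Riemann invariant
  W = u ± 4(c − c0) with the attached element (inlet table, Windkessel,
  junction, stenosis); the resulting boundary state is imposed as the
  interface flux. Boundary and interface elements are solved once per
  sub-step and their fluxes held fixed across the two RK stages. This
  choice makes the discrete blood-volume bookkeeping exact — inlet volume
  minus terminal outflow equals vessel plus capacitor storage to machine
  precision — at the price of formally first-order accuracy at
  boundaries; the interior scheme's second order is verified on a
  periodic manufactured solution (observed L2 slope ≈ 1.94 on
  160/320/640-element grids with unlimited slopes; the limited scheme is
  used for production runs where monotonicity matters more than the last
  decimal of the convergence slope).
* Default element size Δx = 2.5 mm. The time-step robustness benchmark
  uses Δx = 12.5 mm so that its coarsest sub-step (5e-4 s) respects the
  CFL bound; robustness is a property of the coupling, not of the mesh.

### Boundary elements

* Windkessel (Z, R, C, P_out): the capacitor pressure is the internal
  state, advanced by backward Euler (unconditionally stable, exact
  discrete volume balance); the ODE's P_e is identified with the terminal
  pressure. The boundary area solves the characteristic + lumped system by
  a warm-started scalar Newton.
* Junctions: mass conservation and continuity of total pressure
  P + ρu|u|/2 (static-pressure matching by flag), solved by a damped
  Newton on all connected end states with a relative residual of 1e-13.
  Linear reflection at a stiffness jump reproduces (Y1−Y2)/(Y1+Y2) to
  ~0.1%.
* Stenosis: a Young–Tsai-type element embedded as an internal interface —
  equal through-flow, total-pressure jump Δp(q, q̇) with Kv = 32 Ls/D0,
  Kt = 1.52, Ku = 1.2 by default (all configurable; only the 30% area
  reduction itself is prescribed by the study design). q̇ is a backward
  difference on the element's stored flow.

## Cardiac cavities

Both cavities expose V_heart(p, t) and its pressure derivative; the
coupled solver is model-agnostic.

* **Elastance chamber**: p = E(t)(V − V_rest) with E(t) sliding from
  E_min = 1.2e7 Pa/m³ to E_max = 2.7e8 Pa/m³ (≈ 0.09 → 2.0 mmHg/mL)
  along the normalised active-stress transient at unit stretch. With the
  default 10 mmHg preload this gives EDV ≈ 121 mL; the defaults were set
  once to place EDV/ESV and central pressures in the normal adult range.
* **Thick-walled sphere**: reference radii R_i = 25 mm, R_o = 35 mm,
  incompressible inflation map r³ = R³ + r_i³ − R_i³, circumferential
  fibres. The wall carries the transversely isotropic Guccione energy
  (defaults b_f = 18.48, b_t = 3.58, b_fs = 1.627, C = 0.8 kPa,
  κ = 650 kPa as incompressibility penalty — the map itself is isochoric,
  so κ never activates) plus the orthotropic active stress (100% fibre,
  40% sheet) with the transient parameters S_peak = 60 kPa,
  t_dur = 575 ms, τ_c0 = 105 ms, τ_r = 90 ms, ld = 35, ld_up = 100 ms,
  λ0 = 0.7 (a stretch, despite one tabulation listing "ms"), electro-
  mechanical delay 15 ms, activation time a plain scalar parameter (no
  electrophysiology solve). Cavity pressure is the shell equilibrium
  p = ∫ 2(σ_t − σ_r)/r dr by 8-point Gauss quadrature, with the two
  tangential Cauchy stresses of the anisotropic wall averaged into one
  effective hoop stress (the standard symmetrisation for a spherical
  surrogate). An orthotropic parameter tabulation (b_ff … b_ns with
  a = 0.8 kPa) is shipped as an alternative config collapsed onto
  (b_f, b_t, b_fs) by averaging; it is an approximation and not the
  default.

**Known limitation — the sphere's descending limb.** With ld = 35 and
λ0 = 0.7 the length-dependence φ(λ) = tanh(ld(λ−λ0)) saturates above
λ ≈ 0.76, while inflating the shell erodes its geometric advantage
(p_act ∝ S_a·ln(r_o/r_i)); the activated p(V) relation therefore rises
only where d ln φ/d ln λ > 3, i.e. below λ ≈ 0.75, and has a descending
limb at physiological stretches. V(p) is then only branch-locally
invertible; the implementation inverts by continuation (nearest root to
the previous volume) and the test suite asserts this explicitly. Full
PV-loop studies consequently use the elastance chamber, which satisfies
the monotone coupling contract globally; the sphere exercises the
constitutive code paths (energy, analytic passive stress vs the symbolic
gradient, active tensor identities, isovolumetric coupling).

Cavity volume from a closed triangulated surface — the quantity a 3D
electromechanics code would feed this coupling — is provided as the exact
divergence-theorem sum V = (1/3)|Σ x_c·n dA| over the deformed positions
(a displacement-only reading of that integral does not yield an enclosed
volume), with open/non-manifold surfaces rejected.

## Coupling

At each coupling step of size dt3D (default 1 ms) the cavity pressure is
the unknown in V_heart(p, t^{n+1}) − V_CS(p) = 0. V_CS(p) is evaluated by
restoring a committed network snapshot and sub-stepping valve + network at
dt1D (default 0.1 ms) with p held constant; dV_CS/dp is a central finite
difference of such trials (ε default 10 Pa; estimates at ε and ε/2 agree
to ~1% in ejection). The scalar Newton update is the Schur-complement
reduction of the full block system. Convergence: absolute volume residual
below tol·V_scale with tol = 1e-6 and V_scale = 1 mL (the natural unit of
the residual; configurable). k_max = 10; if a trial pressure destabilises
the 1D solver the update is halved, up to six times. On success the
committed cavity volume is taken from the vascular side
(V^{n+1} = V^n − ∫q dt), so stroke volume and ejected charge agree to
round-off and the residual measures the heart–vessel volume mismatch.
In practice the baseline run converges in ≤ 3 iterations with residuals
~1e-12 m³.

Isovolumetric phases solve V_heart(p, t^{n+1}) = V0 with the cavity
Jacobian alone (the vascular block degenerates, C' = 0). Phase triggers:
filling → IVC when beat-local time passes activation + EM delay; IVC →
ejection when p exceeds root pressure (1 Pa hysteresis against valve
chatter); ejection → IVR when the implicit valve flow would reverse;
IVR/IVC → filling when p falls below the preload (or the transient ends —
so a cavity with zero active stress simply stays on its passive filling
curve, and the phase machine cannot deadlock). Filling prescribes a
left-atrial pressure (default constant 10 mmHg; no atrium model), making
EDV purely preload-controlled — which is why EDV is invariant across the
afterload studies.

The valve is a Bernoulli resistor + inertance diode,
p_cav − p_root = B q|q| + L q̇, stepped implicitly (B = 2e9 Pa s²/m⁶,
L = 6e4 Pa s²/m³, roughly a 3–4 cm² effective orifice; no regurgitation in
the default model; the precise coefficients are configurable because only
"Bernoulli valve" is prescribed by the design).

## Study conditions and fixtures

All experiments run on generated networks; no external data. Single
vessels: radius 10 mm, wall 1.5 mm, E = 0.25/0.50/0.75 MPa, lengths
200 mm (robustness) and 126 mm (stiffening/coarctation). Terminals:
Z matched to the vessel (ρc0/A0), Z + R = 1.8e8 Pa s/m³ referenced to
P_out = 10 mmHg, C = 1e-8 m³/Pa (τ = RC ≈ 1.6 s) — documented
physiological choices, since no terminal values are prescribed by the
study designs. Inflow for initialisation: a squared-sine systolic pulse
(peak 400 mL/s, systole 30% of the cycle), period 1.231 s (0.8 s for the
tree case, with the active-transient time constants rescaled by the
period ratio). The bifurcating tree halves into two daughters per
generation (radius ×2^(−1/2.3), length ×0.7, stiffness ×(1+0.3·gen),
5% linear taper); the aged profile scales all E by 2.0 and all terminal
resistances by 1.3.

Coupled studies initialise the arterial model alone until near-periodic
(10 cycles for the studies; a dedicated test runs the full 20-cycle
protocol and checks the periodicity flag at a cycle-to-cycle relative L2
change of 1e-3) and then run 3 coupled beats (2 for the tree), reporting
the final beat. The coarctation study uses dt1D = 5e-5 s — stable for
this scheme at the fixture's resolution, and verified to give the same
peak pressures as dt1D = 1e-4 s to 0.01 mmHg. The problem sizes above
are the package's standard configurations; all are configurable.

What the generated fixtures do not emulate: anatomical taper/branching
patterns of a real arterial tree, measured inflow or pressure waveforms,
venous return and preload feedback, atrial contraction, and regurgitant
valves. Passing studies therefore demonstrate the solver's physics
(wave speeds, reflections, conservation, afterload coupling) and the
qualitative physiological responses, not patient-specific calibration.

## Numerical details worth knowing

* All internal units SI; mmHg/mL appear only in reporting.
* Junction/boundary Newtons are warm-started from the previous state;
  junction residuals are scaled (velocity, flow, pressure scales) and
  converged to 1e-13 relative; junction mass defects in network runs sit
  at ~1e-16 of the local flow.
* Snapshot purity: trial evaluations of V_CS restore vessel states,
  terminal capacitor pressures, stenosis flow states, volume tallies and
  the cached inlet state, so two trials at the same pressure are
  bit-identical and the whole pipeline is deterministic (identical config
  → byte-identical trace files).
* Degenerate inputs: collapsed lumens, non-SPD deformation tensors, open
  surface meshes, non-positive terminal resistances and malformed network
  files raise typed errors; an unstable explicit step names the offending
  vessel element.
* The hot kernels (MUSCL-HLL right-hand side, junction Newton, implicit
  wall solve) are numba-compiled; first use in a fresh environment incurs
  a one-time JIT cost of a few seconds.
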