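# Methods

`coaflow` couples a zero-dimensional (lumped-parameter) model of the left
heart and systemic circulation to a three-dimensional D3Q19
lattice-Boltzmann solver, to quantify both global hemodynamics (left
ventricular workload, instantaneous pressures) and local hemodynamics (wall
shear stress, turbulent kinetic energy, trans-stenotic pressure drop) of
coarctation of the aorta (COA) from non-invasive inputs alone.  This note
records the models, the numerical choices, and what the synthetic fixtures
do and do not establish.

## Lattice-Boltzmann solver

**Discretization.** D3Q19 stencil (one rest velocity, six face links, twelve
edge links; weights 1/3, 1/18, 1/36), lattice sound speed `cs^2 = 1/3`.
Populations live on a node-centred grid with spacing `dx` and step `dt`;
lattice density 1 corresponds to the physical density (blood: 1050 kg/m^3,
dynamic viscosity 0.0035 Pa s), and pressure maps through the ideal lattice
equation of state `p = rho_phys (dx/dt)^2 cs^2 (rho_lat - 1) + p_ref`.
The molecular relaxation time is `tau_mol = 3 nu_lat + 1/2` and a
construction-time guard rejects unit choices with `tau_mol` outside
(0.5, 2).

**Collision.** Multiple-relaxation-time (MRT) collision in the orthogonal
moment basis (density, kinetic energy, energy squared, momentum, energy
flux, five stress moments, five third-order ghost moments).  The five
stress moments relax at the viscosity rate `1/tau`; the kinetic moments use
the standard stability-optimised constants (1.19, 1.4, 1.2, 1.4, 1.98); mass
and momentum are conserved identically (rate 0).  The ghost equilibria
default to the stability-optimised set (energy-squared coefficient
-475/63 j^2/rho, zero equilibria for the fourth-order stress corrections).
A "projection" ghost set, equal to `M f_eq` of the second-order BGK
equilibrium, is available on `MRTOperator`; with it, uniform relaxation
rates make MRT algebraically identical to BGK, which the test suite checks
to 1e-12 over 100 steps.  A consequence of the optimised ghost set worth
knowing: the BGK equilibrium populations are *not* an exact fixed point at
rest (the ghost content relaxes to a slightly different invariant state),
but density and momentum are untouched and the rest state is preserved to
machine precision.

The production kernel evaluates the moment transform from the explicit
D3Q19 moment polynomials and reconstructs the post-collision populations
through `Minv = M^T diag(1/|m_q|^2)` (the rows of M are mutually
orthogonal), about 300 flops per node; it is verified against the dense
matrix reference implementation to 1e-13 in the suite.

**Turbulence closure.** Smagorinsky subgrid-scale model with `Cs = 0.1`.
The filtered strain magnitude is recovered locally from the second-order
moment of the non-equilibrium populations,
`Pi_bar = ||sum_a (f_a - f_a^eq) e_a e_a||_F`, and enters the collision as
an added turbulent relaxation time

    tau_turb = 1/2 ( sqrt(tau_mol^2 + 18 sqrt(2) Cs^2 Pi_bar / (rho cs^4))
                     - tau_mol ),

so the total viscosity obeys `nu = (tau - 1/2)/3 = nu_mol + nu_turb` with
`nu_turb >= 0`, vanishing exactly in the laminar limit.  The Frobenius norm
is taken without traceless projection (a flag on `noneq_moment` enables
it); at the low Mach numbers the solver enforces the trace term is
negligible.

**Walls.** Curved walls use Bouzidi's interpolated bounce-back.  Each cut
link stores the exact normalized wall distance `q = |AC|/|AB|` (analytic
for the synthetic tubes, segment-triangle intersection for voxelized
meshes): for `q < 1/2` the reflected population interpolates between the
boundary node and the next fluid node upstream; for `q >= 1/2` it blends
the reversed post-collision population at the boundary node.  Both branches
reduce to simple bounce-back at `q = 1/2`.  Where the upstream node is
solid the scheme degrades to simple bounce-back, and any streaming pull
whose source is solid (e.g. unrecorded corner links) also defaults to
simple bounce-back, so no population is ever read from a solid node.

**Inlet.** Prescribed-velocity patch (Poiseuille profile rescaled so the
discrete patch flux equals the target flow rate exactly).  All 19
populations are rebuilt as equilibrium plus the regularized Chapman-Enskog
non-equilibrium correction `f_neq = -(w rho tau / cs^2) (e e - cs^2 I):S`,
with the strain assembled from in-plane finite differences of the
prescribed profile and a second-order one-sided normal derivative from the
interior.  The boundary density uses the one-sided closure
`rho = (sum_{e_n=0} f + 2 sum_{e_n=-1} f) / (1 - u_n)` from the node's own
post-streaming populations.  A pure bulk extrapolation of the density was
tried first and abandoned: it decouples the boundary density from the
one-sided flux balance and the steady interior flux converged tens of
percent away from the prescription.  Start-up uses a `sin^2` ramp
(C1-continuous, default duration one quarter cycle).

**Outlet.** Pressure outlet: the outlet plane copies the neighbouring
interior plane's populations rescaled to the density prescribed through the
equation of state.  This zero-normal-gradient closure leaves the velocity
profile undistorted (an equilibrium-rebuild outlet produced a spurious
boundary-layer jet several nodes thick) and behaves as zero-gradient
outflow when the pressure is constant.  Aortic branch outflow, when branch
patches are present, is split in proportion to branch cross-sectional
areas; the fixtures used in the tests have no side branches, so the flow
entering the descending-aorta fixture is the transvalvular flow minus the
upper-body branch flow taken by the circuit model.

**Walls are rigid**, consistent with the reduced compliance of hypertensive
COA patients; no fluid-structure interaction is modelled.

## Lumped-parameter heart and circulation

**Left ventricle.** Time-varying elastance `P_LV = E_max E_N(t/T_Emax)
(V - V_0)`.  The normalized shape `E_N` is a double-Hill curve (activation
Hill with exponent 1.9, relaxation Hill with exponent 21.9) rescaled in
time and amplitude so its maximum is exactly 1 at `t_N = 1`, with a small
diastolic baseline (0.03).  Any same-shaped curve can be substituted.
Defaults: `V_0 = 10 mL`; `T_Emax = ejection time + 0.05 s` (isovolumic
contraction allowance).  The ventricle fills through a prescribed two-lobed
(E-wave/A-wave) mitral waveform supported on diastole whose integral equals
the stroke volume exactly (closed-form sin^2 normalization; E/A peak ratio
default 1.6).

**Valve, regurgitation and coarctation elements.** All three use the
energy-loss-coefficient net-gradient formulation

    TPG = 2 pi rho / sqrt(ELCo) dQ/dt + rho / (2 ELCo^2) Q^2,
    ELCo = EOA A / (A - EOA),

i.e. an inductance `L = 2 pi rho / sqrt(ELCo)` in series with a
flow-proportional resistance `R(Q) = rho/(2 ELCo^2) |Q|`.  The aortic valve
and regurgitant path are one-way elements (flow-gated diodes: the forward
path conducts when LV pressure exceeds aortic pressure or forward flow
persists; the regurgitant path only in diastole and only when a regurgitant
orifice is specified).  When `EOA_coa -> A_dist` the coarctation element
degenerates continuously to a plain resistor (the inductance tends to zero,
which would otherwise make the branch ODE singular); the cross-over is at
98% of the distal area.

**Systemic circuit.** LV -> valve element -> aortic-root capacitor `C_ao`
-> aortic resistance `R_ao` -> two parallel branches (upper body `R_ub`;
proximal descending aorta `R_pda` in series with the coarctation element)
-> systemic arteries `R_SA` -> systemic capacitor `C_SAC` -> veins `R_SV`
-> constant central venous pressure (4 mmHg).  Constants: `R_ao = R_SV =
R_pda = 0.05 mmHg s/mL`; initial `C_ao = 0.5`, `C_SAC = 2 mL/mmHg`; `R_SA`
0.8 initially.  Placing `R_ao` between the root capacitor and the branch
split makes the DC identity `mean P_ao = CO * R_total + P_CV0` exact for
the healthy template, which the suite checks at 5%.

**Calibration from non-invasive inputs.** Total systemic resistance
`R_total = MAP / CO` with `MAP = P_dia + PP/3`; `R_SA` absorbs the
difference from the fixed constants (the flow-dependent coarctation
resistance is linearized at the mean trans-coarctation flow by a short
fixed-point iteration).  `R_ub` is set algebraically so the upper-body
branch carries 15% of the flow in the healthy case (the parallel pair is
purely resistive, so the "healthy-template run" reduces to a current
divider).  `E_max` is found by a secant iteration so peak LV pressure
matches cuff systolic pressure plus the transvalvular gradient at peak
ejection flow (a sine-lobe estimate `Q_peak = pi/2 SV / ET`); targeting
peak *aortic* pressure instead is ill-conditioned, because once the stroke
volume is fixed by the filling waveform the aortic peak saturates in
`E_max`.  The compliances are then scaled jointly (bounded secant on a log
scale) until the simulated aortic pulse pressure matches the cuff pulse
pressure within 2 mmHg; the two fits alternate up to three times.

**Integration.** Fixed-step classical Runge-Kutta at 0.1 ms with per-step
valve gating and clamping of reverse flows, compiled with numba; cycles are
integrated from rest (all stored pressures and flows zero, end-diastolic
volume estimated as `V_0 + SV/0.55`) until the aortic pressure waveform is
cycle-periodic to 1% (20-cycle cap).  A variable-step implicit scheme was
considered and rejected: the diode switching makes the right-hand side
discontinuous, which fixed-step integration with explicit clamping handles
robustly and deterministically, and the step is small enough that the
discretization error is far below the model error.

## Hemodynamic indices

- **WSS**: the velocity gradient is evaluated by first-order finite
  differences on shells 2 and 3 lattice nodes inside the fluid (clear of
  the staircase layer), the viscous traction `tau = sigma.n - (n.sigma.n) n`
  (`sigma = 2 mu eps`; the pressure part of the total stress drops out of
  the tangential projection) is formed on both shells, and |tau| is
  extrapolated linearly to the wall using each wall node's exact normal
  distance to the surface.  Plain off-wall sampling at a fixed shell
  under-reads |tau| by O(offset/R) - 17% at a 12-node radius - which is why
  the two-shell extrapolation is the default.
- **TAWSS** = (1/T) integral |tau| dt, trapezoid over the final measured
  cycle.
- **TKE** = 1/2 rho (u'^2 + v'^2 + w'^2) with fluctuations about the
  phase-ensemble mean over the measured cycles, averaged over phases;
  accumulated in streaming form (per-phase sums of u and u^2).
- **Reynolds number** = peak cross-section-mean velocity x local diameter /
  kinematic viscosity, evaluated at the throat.
- **Pressure drop**: area-averaged plane pressures at stations 15% and 85%
  along the duct, reported in mmHg.
- **Percent changes** are reported with the magnitude rounded to the
  nearest integer percent ("29% decrease"); raw signed values are always
  retained in the machine-readable output.

## Synthetic fixtures and what they show

Patient CT geometries are replaced by idealized axisymmetric ducts: a
straight tube and a cosine-taper coarctation
`R(z) = R0 - (R0 - R_throat)(1 + cos(pi (z - z0)/w))/2`, voxelized with
exact analytic wall distances, plus an inclined plane channel used to
compare interpolated against staircase bounce-back, and an STL voxelization
path (ray-parity containment and Moller-Trumbore segment-triangle
intersection) cross-validated against the analytic tube.  The synthetic
patient (SV 60-70 mL, HR 75-80 bpm, ejection time 0.3 s, aortic areas ~5
cm^2, COA effective orifice area 0.9 cm^2, cuff 140/85 mmHg) represents a
moderate adult coarctation.

The coupled test runs are *scaled down*: grid radii of 8-12 nodes,
viscosity raised ~50x above blood (throat Reynolds number O(100) instead of
O(10^4)), two measured cycles.  At these sizes the runs demonstrate
conservation, determinism, correct coupling of the waveforms, laminar
validation against closed forms, and the monotone response of pressure drop
and wall shear to stenosis severity.  They do not reproduce the turbulent
transition, absolute TKE/TAWSS magnitudes, or patient-specific values of
the clinical study; those depend on patient geometry and echo inputs that
are not part of the package.  The published pre/post percent changes are
reproduced from their printed pre/post values through the package's own
percent-change reporting, not re-simulated.

## Numerical conventions and degenerate inputs

- Velocity scale: runs are set up so the peak lattice velocity stays below
  ~0.1 (low-Mach constraint); compressibility then perturbs the density by
  O(1%) and the laminar validation errors are dominated by discretization.
- Steady state is declared when the relative velocity change per step falls
  below 1e-8.
- Degenerate stenosis (`R_throat = R0`) reproduces the straight tube
  exactly; tubes with radius under 8 dx (throats under 5 dx) are rejected.
- All randomness (test fields, probe seeds) flows through explicit seeds;
  the coupled pipeline is bit-deterministic given its configuration.

## Known limitations

- Rigid walls; Newtonian rheology; no aortic branch vessels in the default
  fixtures (the branch-split boundary machinery exists and is unit-tested,
  but the arch anatomy is out of scope).
- The inlet/outlet closures are first/second order at the patch; the
  inlet-adjacent plane carries a small ringing artifact (<2% in mass flux)
  that decays within two nodes.
- Single-block domains only; no multi-block decomposition or parallel
  halo exchange.
- The elastance shape and mitral waveform are population templates, not
  patient measurements; only their scales are calibrated per patient.
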