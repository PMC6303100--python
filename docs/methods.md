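# Methods

## Model

The lateral intercellular cleft is treated as a long narrow rectangle of
width `b` and length `L` (`b ≪ L`), with the tight junction (TJ) sealing the
lumenal end `y = 0` and the basal end `y = L` open to the interstitium.
After averaging across the width, the steady state is described by the total
osmolyte concentration `c(y)` and axial water velocity `v(y)` (positive from
TJ toward interstitium).  Ion transport is convection–diffusion with a
uniform lateral source `2j/b` from membrane ATPases; integrating once with
the zero-axial-ion-flux condition at the sealed end gives the first-order
system solved here:

```
-D c' + v c = 2 j y / b,
v' = (2 f_aq / b)(c - c3),
c(L) = c4,
v(0) = k_TJ RT (c(0) - c1).
```

Assumptions, in decreasing order of importance:

1. **Uniform pumping.**  `j` is constant along the cleft.  This is the
   model's central structural choice; a position-dependent `j(y)` would
   change the analysis qualitatively and is deliberately not supported.
2. **Osmotic driving only.**  Hydrostatic pressure is neglected in both the
   aquaporin and TJ driving forces: at a typical Δc = 100 mM,
   `RT Δc ≈ 2.58e6` CGS versus `Δp = 0.1 atm = 1e5` CGS — a ~26× margin
   (`model.pressure_neglect_ratio`).  Viscosity `mu` is therefore carried in
   the parameter set but never used.
3. **Ion-tight TJ.**  The TJ passes water only; all pumped ions exit at the
   open end (`-D c' + v c = 2jL/b` at `y = L`).
4. **Fixed reservoirs.**  `c1`, `c3`, `c4` are boundary data, not dynamical
   variables.  For scenarios where the cytosol tracks the lumen,
   `scenarios.linked_c3` provides an explicitly phenomenological linear
   coupling with a configurable slope.
5. **Steady state.**  No transients; the time-dependent narrowing dynamics
   of the cleft (cadherin-mediated width regulation) are outside scope.

## Parameters

Internally everything is CGS with concentrations in mol/cm³; all user I/O
uses "value unit" strings (mM, nm, µm) so silent unit errors are impossible.
Defaults describe a moderately leaky absorbing epithelium:

| symbol | meaning | default | unit |
|---|---|---|---|
| `k_aq` | single-aquaporin permeability | 5e-14 | cm³/s |
| `n_aq` | aquaporin density | 1e3 | µm⁻² |
| `j` | lateral ion pump flux | 18.5e-9 | mol cm⁻² s⁻¹ |
| `D` | osmolyte diffusivity | 1e-5 | cm²/s |
| `b` | cleft width | 400 (range 40–400) | nm |
| `L` | cleft length | 100 (range 20–100) | µm |
| `w_TJ` | TJ pore width | 2 | nm |
| `P_f` | TJ hydraulic permeability | 13.1e-3 | cm/s |
| `RT` | thermal energy per mole | 310.15·8.314e7 | CGS |
| `c1` | lumen osmolarity | 600 (range 200–1000) | mM |
| `c3`, `c4` | cytosol / interstitium | 300 | mM |

Notes on these choices:

* The tabulated aquaporin "permeability 5e-14 cm/s" is dimensionally
  inconsistent with a velocity law `v = f_aq (c - c3)`; it is interpreted
  here as the single-channel permeability `k_aq` [cm³/s], so that
  `f_aq = k_aq V_wat n_aq = 0.09 cm⁴ mol⁻¹ s⁻¹`.  This is the unique
  reading under which the homogeneous concentration at `c3 = 290 mM`
  evaluates to the expected ≈620 mM.
* For the range-valued geometry and lumen entries, the defaults take the
  wide-cleft / long-cleft / hypertonic baseline (b = 400 nm, L = 100 µm,
  c1 = 600 mM) used by the canonical length sweep.
* Quoted reference values for `y_inh` (≈12.2 µm at b = 40 nm, ≈38.5 µm at
  400 nm) differ by ~5 % from direct evaluation with the constants above
  (11.6 / 36.6 µm); the inputs behind the quoted figures are not fully
  specified.  The package does not force agreement: only the exact
  `y_inh ∝ sqrt(b)` scaling and ~10 % level agreement are asserted.

## Regime classification

`long` if `L ≥ r_long · y_inh` (boundary inclusive), `short` if
`L ≤ r_short · y_inh_short` with the enlarged short-cleft scale
`y_inh_short = y_inh · sqrt(2 (1 + f_aq c_hom² / (2j)))`, else
`intermediate`.  Defaults `r_long = 1.0`, `r_short = 0.5`; both are
arguments of `derived_scales`.  With baseline constants at b = 400 nm this
classifies 20 and 30 µm clefts as short and 80–100 µm as long, matching the
behavior of the solutions (inlet pinned near `c4`-shifted values vs pinned
at `c_hom`).

## Numerics

**Nondimensionalization.**  `Y = y/L`, `C = c/c3`, `V = vL/D` turn the
system into `C' = VC − αY`, `V' = β(C − 1)`, `V(0) = γ(C(0) − c1/c3)`,
`C(1) = c4/c3` with `α = 2jL²/(bDc3)`, `β = 2 f_aq c3 L²/(bD)`,
`γ = k_TJ RT c3 L/D`.  All solver tolerances are scale-free in these
variables.

**Relaxation solver.**  Second-order midpoint (box) discretization on a
mesh of 512 intervals, graded toward the open end: the last
`min(2 y_inh, 0.6 L)` of the cleft holds half the points with quadratic
clustering at `y = L` (grading exponent = `SolverOptions.refinement`).  The
nonlinear system is solved by Newton iteration with a halving line search
(max 20 halvings) that also enforces positivity of the concentration
iterate; the sparse Jacobian is assembled exactly.  Convergence requires the
scaled discrete residual below `min(1e-10, tol·1e-3)`.  Initial guesses are
regime-appropriate analytical profiles (long-cleft boundary-layer formula,
explicit short-cleft parabola, or their blend); if the direct solve fails, a
deterministic continuation in `L` from `0.3 y_inh` is attempted.

**Shooting solver.**  The inlet concentration is the single unknown; the TJ
condition supplies `v(0)`, DOP853 integrates forward at `rtol = 1e-12`, and
the outlet mismatch `c(L) − c4` is bracketed over
`c0 ∈ [min(c1,c3,c4)/10, 10 c_hom]` (16-point monotonicity-checked scan,
then Brent).  Runs whose trajectory hits `c = 0` or exceeds a large cap
return sign-preserving, monotone penalty values so bracketing stays valid.
Forward deviations from the true solution grow roughly like
`exp((L/y_inh)²)`, so the method refuses `L/y_inh > 3` and the dispatcher
uses it only for short clefts.  The reported profile is sampled from the
dense output on a mesh 4× finer than the relaxation mesh, which keeps the
midpoint-operator defect of the sampled exact solution below the 1e-6
residual tolerance even at the steepest admissible layers.

**Residual diagnostics.**  Every profile carries a `ResidualReport`: outlet
and TJ boundary defects, the midpoint ion-flux defect normalized by the
total pumped flux `2jL/b` (with a diffusive floor `D·max(c)/L` covering the
pump-free case), and the trapezoid volume-conservation defect normalized by
the outlet velocity scale.  A profile is only flagged converged if all are
below `SolverOptions.tol` (default 1e-6).  The two solvers agree node-wise
to better than 1e-5 across a 36-point parameter grid (tested).

**Determinism.**  No operation anywhere consumes randomness; identical
inputs produce byte-identical outputs.

## Analytical approximations

The source expressions for the long- and short-cleft formulas are
typographically degraded; each undetermined sign/grouping was fixed by two
hard constraints — exact satisfaction of `c(L) = c4`, and decay of the
outlet disturbance into the cleft over the scale `y_inh` — and then
validated quantitatively against the numerical solver:

* **Long cleft:** `c = c_hom + (c4 − c_hom) E(y)` with
  `E = exp((y² − L²)/y_inh²)·(y/L)^p`, `p = f_aq c_hom²/j`; the velocity
  correction `D f_aq c_hom (c4 − c_hom) E/(j y)` follows from integrating
  the volume equation across the layer.  Verified within 2 % of the solver
  at the baseline long cleft.
* **Short cleft, variant 2 (explicit):**
  `c = c_hom + (c4 − c_hom)[1 + κ(y² − L²)/y_inh²]`,
  `κ = 1 + f_aq c_hom c4/j`.  Valid only for very short clefts (≈10 µm,
  where it is within 5 % of the solver).
* **Short cleft, variant 1:**
  `c = c_hom[1 + C0 + ((c4 − c_hom)/c_hom − C0) y²/L²]`, with the
  dimensionless inlet offset `C0` free.  A closed form for `C0` exists but
  is unwieldy; `fit_C0` estimates it by linear least squares against the
  relaxation solution (labelled `source="fitted"`), and a plug-in slot
  accepts an externally supplied closed-form value.  The fitted variant 1
  is markedly more accurate than variant 2 at 20 µm (tested).
* **Inlet shift:** variant 2 at `y = 0`,
  `c(0) − c_hom ≈ (c4 − c_hom)(1 − κL²/y_inh²)`; within 10 % of the solver
  at 10 µm, and the outlet disturbance is *always reduced* at the inlet
  (`|c(0) − c_hom| ≤ |c4 − c_hom|`, asserted on every short-cleft solve).

All approximation velocities are reconstructed from volume conservation plus
the TJ inlet velocity, so they are internally consistent with their
concentration ansatz.

## Scenario conventions

* `flux_summary` partitions the per-unit-depth volume flux into
  `Q_tj = v(0)·b`, `Q_lateral = 2 f_aq ∫(c − c3) dy` and `Q_out = v(L)·b`
  (budget closes to 1e-6, tested), reports the efflux osmolarity
  `c_e = 2jL/(b v(L))` only when water actually leaves the open end, and
  locates the interior point where the lateral aquaporin flow reverses
  (`c = c3`), if any.
* `volume_per_area` converts a flux summary into cm³ per cm² of epithelium
  per duration using a cleft line density; the default (2×10³ cm⁻¹,
  square cells of 10 µm side) is a geometry convention of this package, not
  a measured constant, and must be overridden for other cell shapes.
* Sweeps (`L`, `b`, `c1`, `c3`) warm-start each point from the previous
  converged profile and record per-point failures instead of aborting.

## Problem sizes

Default meshes are 512 intervals (relaxation) / 2048 sample points
(shooting); the cross-validation grid uses 36 parameter combinations over
widths 40–400 nm, lengths 10–30 µm and osmolarities 290–600 mM.  The full
test suite runs in well under a minute on one CPU; the acceptance script in
a few seconds.

## Known limitations

* 1-D width-averaged fields only; no resolution across the cleft width and
  no 3-D equilibration of the efflux outside the cleft mouth.
* No hydrostatic pressure / Poiseuille resistance, no electro-diffusion, no
  temperature dependence beyond fixed `RT`, no time dependence.
* Position-dependent pump distributions are intentionally unsupported.
* The daily-volume estimate depends linearly on the assumed cleft line
  density; only its order of magnitude is meaningful without a measured
  cell geometry, and the package asserts exactly that.
* The alternative high-TJ-conductance regime (TJ permeabilities ~500×
  larger, where TJ water becomes 10–100 % of the efflux) is reachable by
  overriding `P_f` in config, but no reference numbers are attached to it.
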