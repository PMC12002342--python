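# Methods

This note documents the models implemented in `mnph`, the assumptions behind
them, the default parameter values and where they are genuinely a choice, the
numerical schemes, and what the test suite does and does not establish.

## Ferrofluid composition

A partially coated ferrofluid is described by two atom-count ratios measured
by elemental analysis (DCP-AES): iron per gold atom over the whole fluid,
r_T = N_Fe(T)/N_Au, and within the coated particles, r_C = N_Fe(C)/N_Au. The
uncoated-particle fraction is 1 − r_C/r_T; requiring r_C ≤ r_T at
construction keeps it in [0, 1]. The gold-to-iron atomic ratio
AR = N_Au/(3 N_Fe(C)) uses the three iron atoms per Fe₃O₄ formula unit, and
is exposed both in atom-count form and in the equivalent mole-count
(mass/molar-mass) form; a test asserts they agree.

The shell thickness follows from equating AR to the mole ratio implied by a
spherical core-shell geometry and inverting the resulting cubic in
(1 + 2d/D). The forward map (geometry → AR) and the inversion are exact
algebraic inverses; a property test checks the round trip to 1e-12 relative
over AR ∈ (0, 10]. Defaults: ρ_Fe₃O₄ = 5.196 g/cm³, ρ_Au = 19.3 g/cm³,
M_Fe₃O₄ = 231.5326 g/mol, M_Au = 196.9666 g/mol, all configurable. Lengths
enter in nm and densities in g/cm³ (the units such measurements are reported
in) and are converted to SI once at the constructor boundary.

The model is strictly monodisperse; no size distribution or synthesis
chemistry is represented.

Note on the two shell-thickness values in circulation for this particle: the
composition inversion with D_core = 13.90 nm gives d_shell ≈ 0.55 nm, while
the heating-stage default particle carries d_shell = 5.5 nm. Both are
representable; the heating default keeps 5.5 nm as the hydrodynamic coating
thickness (the quantity that actually enters the Brownian drag), and the
0.55 nm DCP-AES value is what the composition module computes.

## Linear-response heating

The chain is Rosensweig's linear response theory for a monodisperse
superparamagnetic suspension, valid for small Langevin parameter ξ (the
default operating point has ξ ≈ 0.03):

* ξ = μ₀ M_d V_m H₀ / k_BT, χ_i = μ₀ φ M_d² V_m / 3k_BT;
* χ₀ = χ_i (3/ξ)(coth ξ − 1/ξ): the chord susceptibility. Below ξ = 1e-4 the
  bracket is evaluated by its Taylor series (1 − ξ²/15 + 2ξ⁴/315); the direct
  form loses ~8 significant digits to cancellation there. Series and direct
  branch are both checked against a 50-digit reference at the switchover.
* τ_N = (√π/2) τ₀ e^Γ/√Γ with Γ = K V_m/k_BT; τ_B = 3 η V_h/k_BT;
  1/τ_eff = 1/τ_N + 1/τ_B. For Γ > 700, e^Γ overflows double precision; the
  implementation returns an explicit Néel-blocked flag and falls back to
  Brownian-only relaxation instead of overflowing.
* Q_nano = π μ₀ χ₀ H₀² f · 2πfτ/(1 + (2πfτ)²).

As a function of frequency Q_nano is monotone increasing and saturates at
μ₀χ₀H₀²/2τ — the f prefactor cancels the 1/f tail of the Debye factor. What
peaks (at value ½, exactly when 2πfτ = 1) is the bracketed dissipation
factor alone. In the small-ξ regime the power scales as H₀².

Defaults (the simulated particle): D = 15 nm, d_shell = 5.5 nm,
M_d = 4.10×10⁴ A/m, M_s = 2.86×10⁴ A/m, K = 2.0×10⁴ J/m³, η = 2.35×10⁻³ Pa·s,
φ = 0.071, τ₀ = 10⁻⁹ s, H₀ = 1500 A/m, f = 571 kHz, evaluated at body
temperature 310.15 K. The LRT quantities are **not** re-evaluated against the
evolving tissue temperature: the bioheat stage treats Q_nano as a constant
source, which is consistent with the ~1 % change of k_BT across the
therapeutic range.

With these defaults the chain yields ≈ 25 kW/m³. The alternative reading of
the volume fraction as φ = M_s/M_d ≈ 0.698 (available as
`with_phi_from_magnetization()`) scales this to ≈ 244 kW/m³. The bioheat
scenario's source strength is therefore an explicit, independent input
(default 214 kW/m³) rather than being coupled to the particle chain: the two
readings of φ differ by an order of magnitude and the choice belongs to the
user, not to a hidden coupling.

## Coil field

The on-axis flux density of the finite solenoid (length l = 40 mm, radius
R = 30 mm, N = 3 turns, 15 A) uses the current-sheet closed form with
symmetric half-lengths a = b = l/2. The independent reference is the exact
superposition of N discrete circular loops (complete elliptic integrals),
placed at z_k = −l/2 + (k+½)l/N, which preserves total ampere-turns and
symmetry. The two routes agree on axis to < 2 % at N = 3 and < 0.2 % when the
same ampere-turns are spread over 20 loops (sheet-limit convergence). The
loop formulation is singular on the winding itself and raises an error there.

The coil field is deliberately not coupled into the thermal solve — the
tissue source is the prescribed Q_nano — so this module is a verification
and reporting surface (B(z), H(z) line profiles, optional (r, z) maps). Eddy
currents, tissue electrical properties and coil self-heating are out of
scope.

## Bioheat solver

Geometry: tumor cylinder (radius 5 mm) nested radially inside the skin
cylinder (radius 15 mm), both 30 mm tall. Because the domains, sources and
boundary conditions are all rotationally symmetric, the 3-D problem reduces
exactly to the (r, z) half-plane; that reduction is what is solved.

Materials (SI): tumor ρ = 1090, C_p = 3421, k = 0.563, ω_b = 1.34×10⁻² 1/s,
Q_met = 13.08 kW/m³; skin ρ = 1109, C_p = 3391, k = 0.372, ω_b = 1.96×10⁻³,
Q_met = 1.83 kW/m³; blood ρ_b = 1050, C_b = 3617, T_b = 37 °C. Where the
tumor's metabolic heat is reported both as 13.08 kW/m³ (tabulated) and
1.83 kW/m³ (in passing), the tabulated per-domain value is the default; it
is a one-line configuration change and shifts the peak by < 0.25 K. Each
grid node takes the material of the domain its radius falls in
(nearest-material assignment at the interface, tumor side inclusive).

Boundary conditions: convective flux h(T − T_ext) with h = 3.6 W/m²/K,
T_ext = 37 °C on the lateral surface r = 15 mm; insulated end faces (the
treated patch is embedded in more tissue above and below). The face
assignment is configurable per face. Initial temperature 37 °C everywhere.

Discretization: node-centered finite volumes on a uniform grid (default
dr = dz = 0.5 mm — 10 cells across the tumor radius — dt = 1 s, 60 min).
Face conductances use the harmonic mean of nodal conductivities, making the
flux continuous across the tumor-skin jump. The axis r = 0 is a natural
zero-flux half-cell. Time integration is backward Euler by default: it is
unconditionally stable, and its fixed point is the exact discrete steady
state, so the 60-minute field (≈ 50 perfusion time constants) is
discretization-independent in time; Crank-Nicolson (θ = ½) is available and
is used in the test that tracks a transient against a closed form. The
constant system matrix is LU-factorized once; a full reference run
(1891 nodes × 3600 steps) takes under a second.

Verification (all in the test suite):

* equilibrium preservation: with no sources and uniform T = T_b the state is
  a fixed point to 1e-12 K;
* uniform perfusion relaxation: with conduction inert by uniformity the
  discrete solution tracks T_b + ΔT₀ e^{−t/τ}, τ = ρC_p/ρ_bC_bω_b ≈ 73.3 s,
  to 1e-4 relative;
* independent steady-state oracle: the converged center temperature matches
  the analytic two-region modified-Bessel solution of the perfused cylinder
  (I₀/K₀ radial profiles matched at the interface, Robin condition at the
  outer radius) to < 0.05 K;
* self-convergence: refining 0.5 mm → 0.25 mm moves the 60-min peak by
  < 0.05 K; halving dt leaves it unchanged to < 1e-3 K;
* discrete energy bookkeeping closes to 1e-6 of the source term each step;
* the peak never exceeds the conduction-free bound
  T_b + (Q_nano+Q_met)/(ρ_bC_bω_b).

With the default scenario the 60-minute peak is ≈ 40.46 °C against a
perfusion-limited ceiling of 41.46 °C. A frequently quoted operating point
for this configuration, 42.3 °C, lies *above* that ceiling and is therefore
not attainable under these parameter values with any consistent solver — the
perfusion sink alone caps the local temperature rise at
(Q_nano+Q_met)/(ρ_bC_bω_b) = 4.46 K, and radial conduction out of a 5-mm
tumor (diffusion length √(k/ρ_bC_bω_b) ≈ 3.3 mm) costs another kelvin. The
package reports the self-consistent value.

## Arrhenius damage

Damage is post-processing on stored histories: Ω = A_f ∫ exp(−E_a/RT) dt by
trapezoidal accumulation over the stored snapshots (closed form exactly for
constant T; window-additive to 1e-12; second-order under dt refinement), and
θ = 1 − e^{−Ω} (the sign that keeps θ ∈ [0, 1); Ω = 4.6 ≈ 99 % necrosis).
The rate is evaluated in log space so extreme activation energies underflow
cleanly to zero rather than raising.

Defaults: E_a = 6.27×10⁵ J/mol with A_f = 3.1×10⁹⁸ s⁻¹ — a Henriques-type
pair whose magnitudes are mutually consistent (ln A_f ≈ E_a/RT at ~43 °C, so
Ω is O(1) on therapeutic timescales). An E_a three orders larger is
representable by configuration but drives the rate to exactly zero at any
therapeutic temperature; the kinetic parameters used are recorded in every
CLI output header for that reason. At the simulated ≈ 40.5 °C peak, one hour
accumulates Ω ~ 10⁻³–10⁻² (θ well under 1 %): mild hyperthermia that
sensitizes rather than ablates. Claims of 90–99 % necrosis require either
hotter exposures or different kinetics; no parameter choice shipped here
produces them at 40.5 °C, and the package does not pretend otherwise.

CEM43 dosimetry and cell-line-specific parameter libraries are out of scope.

## Sensitivity sweeps

One parameter at a time over fixed grids (ω_b 0.001–0.005 1/s, ρ_b 700–1100
kg/m³, C_b 2800–4400 J/kg/K, Q_met 1–5 kW/m³, Q_nano 110–190 kW/m³, five
values each), all else at the base scenario; tissue-side parameters (ω_b,
Q_met) are applied to both domains, blood properties are global by
construction, and Q_nano exists only in the tumor. The headline scalar per
run is the domain-maximum temperature at the final time — robust to any
probe-placement convention. The monotonicity report classifies each
parameter by the signs of successive differences: perfusion, blood density
and blood heat capacity act inversely on the peak; metabolic and
nanoparticle heat act directly. Per-run failures are reported in-row and do
not abort the sweep; rows are independent of execution order. The test suite
runs the five sweeps on a 1 mm screening grid (the steady state is reached
within minutes of simulated time, so the verdicts are grid-robust; the
0.5 mm production grid is available behind a flag).

## Scenario generation and reproducibility

The scenario module is the package's only data source: the reference
configuration above, uniformly sampled parameter ensembles (single explicit
`numpy` generator per ensemble, no global random state; identical seeds give
identical ensembles), and synthetic single-point temperature profiles
(constant, linear ramp, ramp-plateau, noisy plateau) that exercise the
damage stage — the constant profile enables the exact closed-form oracle.
Uniform sampling was chosen over Latin hypercube: for one-at-a-time
sensitivity screening with five parameters it is the simplest defensible
default. Scenarios serialize to JSON (readable back from JSON or TOML) with
a lossless field-by-field round trip.

What the synthetic stage does *not* emulate: spatially heterogeneous
nanoparticle deposition (the source is uniform in the tumor), discrete
vasculature, temperature-dependent material properties, irregular tumor
shapes, and measurement noise on anything but the synthetic point profiles.
Passing tests establish the numerics and the stated physics on the idealized
nested-cylinder scenario; they do not validate the model against tissue
data.

## Known limitations

* Perfusion is a homogeneous sink (Pennes); no discrete-vessel or vascular
  network effects, which matter near large vessels.
* Material properties are temperature-independent; real perfusion responds
  strongly (and non-monotonically) to heating.
* The particle model is monodisperse LRT — no hysteresis, no
  Stoner–Wohlfarth switching, no size-distribution averaging — so it
  underestimates heating for particles driven beyond the linear regime.
* The magnetic field module and the thermal module are uncoupled by design;
  spatial non-uniformity of H over the tumor (< few % at the coil center) is
  ignored.
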