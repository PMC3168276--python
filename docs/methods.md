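# Methods

## Model

A spherical tumor of radius R (default 4 mm) sits in unbounded, homogeneous,
isotropic host tissue. Everything is steady-state and spherically symmetric;
the factor-transport dynamics are much faster than tumor growth, so no
transient terms are carried.

**Pressure.** Interstitial flow follows Darcy's law, u = −K dp/dr, fed by a
distributed Starling source across the vessel walls. Substituting both into
the incompressible continuity equation eliminates the source term and yields,
after scaling p by the effective pressure p_e = p_v − σ(π_v − π_i) and r by
R, the interior equation ∇²p̃ = −α_t²(1 − p̃) with α = R·√(L_p(S/V)/K).
Outside the tumor, host lymphatics drain excess fluid toward a zero baseline;
we model this as Helmholtz decay ∇²p̃ = α_h²·p̃, the simplest form consistent
with p̃ → 0 far away and a nonzero host α. Matching conditions at r̃ = 1 are
continuity of p̃ and of the Darcy flux K dp̃/dr̃ (conductivities are equal by
default, K_h = K_t, but the flux matching carries the ratio).

**Factor transport.** Each factor family (proangiogenic p, antiangiogenic a)
diffuses (D), degrades with first-order kinetics (k), is produced at a
constant rate (g), and is convected with the interstitial fluid. Each tissue
has its own D, k, g. Concentrations are scaled by the host steady state
f_s = g_h/k_h — so f̃ = 1 is the far-field value and host g̃ = k̃ by
construction — giving per-tissue groups k̃ = kR²/D, g̃ = gR²/(D f_s),
K̃ = K p_e/D. At the boundary, concentration and the *dimensional* total
flux −D ∂f/∂r + u·f are continuous; because the velocity and concentration
are themselves continuous, this reduces to D_t f̃′(1⁻) = D_h f̃′(1⁺), and
the diffusivity ratio enters the discrete matching explicitly.

**Activity and regimes.** The activity a(f̃_p, f̃_a) is the symmetric ratio
measure (±(ratio − 1)); it is antisymmetric in its arguments, zero at
balance, and strictly increasing in the stimulator. The regime label is the
sign pattern of a on r̃ ∈ [0, 1]: positive everywhere → global angiogenesis,
negative everywhere → global suppression, negative core with a positive
point farther out → focal suppression. A sign tolerance of 1e-6 guards
against floating-point flutter near exact balance, and a fourth label
`mixed` makes the classifier total (e.g. a stimulated core with a suppressed
rim, or a profile pinned at balance).

## One global pressure scale

The shipped host column lists its own effective pressure (10.9 mmHg), but
all K̃ values — host included — are consistent only with the *tumor*
effective pressure (20 mmHg). The package therefore uses a single global
pressure scale, the tumor-column p_e, for p̃ and every K̃; the per-tissue
effective pressure remains available as a tissue property. `global.pe`
overrides the scale directly (used by the convection-strength studies).

## Default parameters

`src/angiofield/data/defaults.yaml` carries the three tissue columns
(host / tumor / vascular-normalized) and the two factor families per tissue:
hydraulic conductivity K = 2.5e-5 mm²/s/mmHg everywhere; vessel permeability
L_p = 3.6e-7 / 1.86e-5 / 3.7e-6 mm/s/mmHg and vessel density S/V = 17.4 /
16.5 / 15.2 /mm for host / tumor / normalized (α ≈ 2 / 14 / 6 at R = 4 mm);
vascular pressure 20 mmHg with tissue-specific osmotic parameters; factor
diffusivities of order 1e-5 mm²/s, deactivation rates of order 1e-4 /s and
tumor production elevated ~6-fold over host (nondimensionally g̃_p = 349,
g̃_a = 280 vs host 80 / 73.8). These are literature-anchored estimates for
representative factor families, not molecule-specific constants.

## Numerics

* **Grid.** Uniform in r̃ on [0, r_max], r_max = 5 (i.e. five tumor radii),
  n = 2001 nodes by default (h = 0.0025), with a node exactly on r̃ = 1.
  Extending to r_max = 8 changes the interior pressure by < 1e-12
  (`domain_truncation_error`), and the factor far-field Dirichlet f̃ = 1 at
  r_max = 5 is equally benign: the host screening lengths 1/√k̃_h ≈ 0.12 are
  tiny compared to the domain.
* **Closed-form pressure.** Interior 1 + A·sinh(α_t r̃)/r̃, exterior
  B·exp(−α_h r̃)/r̃; the 2×2 matching system is solved in a rearranged form
  (ratios of sinh/exp) that is overflow-safe for arbitrarily large α_t and
  reduces smoothly to the zero field as α_t → 0. α_t = 0 returns the zero
  field exactly; a nonpositive matching denominator (e.g. K_h/K_t ≤ 0)
  raises a diagnostic error.
* **Finite-difference pressure (cross-check oracle).** Solved in the
  transformed variable w = r̃·p̃, which removes the singular 1/r̃ term and
  makes both regions constant-coefficient; centered second-order stencils,
  w(0) = 0 for regularity, 5-point one-sided derivative stencils for the
  interface flux matching (so the closure does not dominate the truncation
  error), and an exact Robin far-field condition w′ + α_h w = 0 that any
  decaying exterior mode satisfies — no circular use of the analytic
  constants. Observed convergence is cleanly second order; at n = 2001 the
  two paths agree to ≲ 8.5e-6 in max norm for the steepest default case
  (α_t = 14).
* **Factor transport.** Conservative finite volume: fluxes
  D·r̃²(f̃′ + K̃ p̃′ f̃) at cell faces with centered differences and face
  pressure gradients from grid differences of p̃ (second order). Fluxes are
  D-weighted so they are continuous across the tissue boundary; the
  interface node owns two half-cells with their own source terms, and the
  cell budget telescopes exactly — the discrete
  production − degradation − outflux balance closes to ~1e-14 relative.
  The center node owns the half-cell [0, h/2] with zero flux at the origin.
* **High Péclet.** If any face's cell Péclet number |K̃ p̃′| h exceeds 2 the
  solver warns and halves the spacing (re-evaluating the pressure field on
  the finer grid) rather than upwinding, preserving second order. Default
  parameters sit near Pe_cell ≈ 0.1.
* **No-convection closed form (oracle).** With K̃ = 0 the transport equation
  has the piecewise sinh/exp solution matched by concentration and
  D-weighted flux continuity; the finite-volume solver reproduces it to
  < 1e-4 max-norm at the default grid and to second order under refinement.

## Scenario machinery

Overrides address dimensional parameters; α and K̃ are always *derived*.
This preserves the physical couplings: changing L_p moves only α, changing
p_e moves only K̃, changing K moves both (in opposite directions). The six
therapy-table scenarios set α_t ∈ {2, 6, 14} by inverting
L_p = α²K/(R²(S/V)) at the tumor vessel density, so the target α is exact
rather than inherited from rounded permeability values; tumor production is
set nondimensionally (g̃_p ∈ {349, 279}, g̃_a = 280) to match the table's
axes. Two vascular-normalization presets record both readings of the α_t = 6
state (L_p + S/V reduction vs the full normalized column); the
deactivation-increase (k_p ×1.25) and ECM-degradation (K ×2 at p_e = 10.9)
presets use representative magnitudes chosen here, since only the direction
of those interventions is specified in the source material.

Production-plane sweeps hold the pressure field fixed (it is independent of
factor kinetics) and reuse one LU factorization per factor family — the
transport matrix does not involve g̃ — so a 41×41 map costs two
factorizations and 82 back-substitutions. Regime boundaries are midpoints
between differently-labeled neighboring cells; no subgrid refinement is
attempted, as the maps are qualitative.

## Limitations

* Spherical symmetry, homogeneous tissues, constant coefficients across each
  region; no vascular network geometry, no poroelasticity, no transients.
* α is treated as concentration-independent, although VEGF is known to raise
  vessel permeability; feeding the computed factor fields back into α would
  couple the two solvers nonlinearly and is out of scope.
* The two factor "families" are effective species; molecular identities,
  receptor kinetics and factor-specific therapies are not modeled.
* Activity is a diagnostic of imbalance, not a growth law: no vessels are
  actually grown or regressed.
* The regime classifier's `focal_suppression` follows the suppressed-core /
  stimulated-rim definition; profiles that invert this pattern are labeled
  `mixed` rather than forced into the trichotomy.
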