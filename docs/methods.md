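# Methods

## Model equations

Both models describe an axisymmetric annular layer of Bingham liquid (yield
stress `τ_y`, plastic viscosity `η`) on the interior wall of a rigid tube of
radius `a`, with a passive gas core and an insoluble surfactant monolayer on
the gas–liquid interface whose surface tension is linear in concentration,
`σ(Γ) = 1 + 𝓜(1 − Γ)`.  Gravity, air flow, wall elasticity, surfactant
diffusion and non-linear equations of state are outside scope.

The **long-wave model** evolves the interface radius `R(z,t)` and the
conserved surfactant density `RΓ`:

* exact curvature `κ = [1/R − R_zz/(1+R_z²)] / √(1+R_z²)`, pressure
  `p = −κ σ(Γ)`;
* shear stress across the layer
  `τ_rz = (p_z/2)(r − R²/r) + (R/r) 𝓜Γ_z`; solving `|τ_rz| = 𝓑` gives the
  yield radii `ψ±`, clipped to `Ψ± = max[R, min(1, ψ±)]`; the branch of the
  closed-form flux `Q` and surface velocity `w_s` (auxiliaries `F1–F4`,
  `G1–G4`) is selected by the stress ratio `2𝓜Γ_z/(R p_z)` with thresholds
  `{1, 1 + 𝓑²/(R p_z)²}`, and the pair is continuous across both thresholds
  and at `p_z = 0`;
* `R_t = Q_z/R`, `(RΓ)_t + (w_s R Γ)_z = 0`, with symmetry/no-flux boundary
  conditions `R_z = Q = w_s Γ = 0` at `z = 0, L`.

The **thin-film model** is the `|1−R| ≪ 1` reduction: thickness
`H = (1−R)/ε` of order one, time `t̃ = ε³ t`, groups `B = 𝓑/ε²`,
`M = 𝓜/ε²`, pressure gradient `p̃_z = −H_z − H_zzz`, yield heights
`y± = H + MΓ_z/p̃_z ± B/|p̃_z|` clipped to `[0, H]`, and polynomial flux
`q(H, Γ_z)` and surface velocity `w̃_s`.  The wall stress is
`τ̃_w = H p̃_z + MΓ_z`.  In the strong-surfactant limit the interface is
immobilised and `H` alone evolves with flux
`p̃_z Ỹ²(2Ỹ−3H)/6`, `Ỹ = max(0, H/2 − B/|p̃_z|)`; replacing `B → B/2`,
`t̃ → t̃/4` recovers the surfactant-free equation exactly (strong surfactant
doubles the effective capillary Bingham number and slows time four-fold).

Both closed-form flux/velocity pairs were verified against direct numerical
quadrature of the Bingham velocity profile built from the shear-stress
expressions (300 random parameter draws across all five yielding regimes,
agreement to integrator tolerance), and against each other in the
`ε → 0` limit (relative difference `O(ε)`).

## Discretisation and time integration

* Uniform node-centred grid over `[0, L]` including both endpoints; default
  `L = 2π` (the symmetric half of the one unstable perturbation wavelength)
  and `N = 200` nodes.
* Second-order central differences with ghost nodes from parity reflection:
  even extension for state fields (`H`, `R`, `Γ`), odd extension for fluxes
  (`q`, `w̃_sΓ`, `Q`, `w_sRΓ`), whose boundary values are pinned to zero.
  With trapezoidal quadrature this makes the discrete conservation laws
  telescope exactly: mass/volume and surfactant integrals are conserved to
  integrator tolerance (typically `1e-8` or better over a full run).
* Yield surfaces are regularised before flux evaluation:
  `Ŷ± = max(Y_min, Y±)`, `Ψ̂± = min(1−Y_min, Ψ±)` with `Y_min = 1e-8`;
  halving `Y_min` changes late-time peak heights by `< 1e-6`.
  `|p_z| < 1e-30` selects the `p_z = 0` branch; the clipped surfaces are
  continuous there so the exact floor is uncritical.
* Time integration: scipy's variable-order BDF with a banded Jacobian
  sparsity pattern (bandwidth 4 per field), `rtol = 1e-8`,
  `atol = 1e-10`.  Long-wave runs integrate in unscaled time and report
  `t̃ = ε³t`.  Plugging is a terminal integrator event on
  `min_z R − 0.3`; `detect_plug` independently locates the crossing on the
  stored min-R series by monotone (PCHIP) interpolation.  Tightening the
  tolerances tenfold moves plugging times by well under 1%; doubling `N`
  moves them by well under 2%.
* Inside the right-hand side the radius is clipped to `[0.02, 1−1e-9]`
  and regime classification is skipped: an implicit integrator probes
  predictor/Newton trial states outside the physical domain, and the
  right-hand side must return finite values there.  The clip floor is far
  below the plug threshold, so it is never active on accepted states.
* When the Marangoni number is exactly zero the concentration field is
  dynamically inert (nothing depends on it); it is held at its initial
  value and only the profile is integrated.  This is the surfactant-free
  model.  (Evolving the passive field anyway invites feedback-free central
  -difference blow-up near the boundary stagnation points.)

## Static states and stability thresholds

At late times an unstable thin film approaches a marginally-yielded static
state: the wall-stress magnitude equals the yield stress where the layer
last crept, `|H₀(H₀' + H₀''')| = 2B` (with `B` in place of `2B` for a
surfactant-free layer), and the surfactant approaches the linear profile
`MΓ₀ = M − BL/2 + Bz`, which is admissible only while `2M ≥ BL`.

Two findings shaped the implementation:

1. On the default domain `L = 2π` the flat film is *resonant*:
   `H = 1 − A cos z` satisfies the marginal relation exactly with `B = 0`
   for every amplitude, and the single-signed static equation
   `H₀(H₀' + H₀''') = +2B` with `H₀' = 0` at both ends and fixed volume has
   no nontrivial classical solution — a perturbation expansion about the
   flat state is obstructed at second order, and exhaustive two-parameter
   shooting scans at several `B` find a residual floor proportional to `B²`
   rather than roots.
2. The attractors actually reached by the dynamics are marginally yielded
   with *piecewise* stress sign: a reversed-stress lobe forms near the thin
   end of the domain, so the single-signed relation holds only over most of
   the domain.

The static family is therefore computed operationally, from the dynamics it
summarises.  `marginal_bingham(A)` (and `bm_of_A`) defines `B_m(A)` as the
stability threshold of the strong-surfactant limit equation: the largest
`B` for which the standard cosine perturbation of amplitude `A` still
grows (peak-height increase above `1e-2` by `t̃ = 1e4`), located by
bisection to 1% relative tolerance.  This is precisely the property the
static lower branch predicts, and the surfactant-free threshold is its
exact double (measured ratio 2.01).  `solve_static_profile` returns the
relaxed profile of a run just above threshold (lower branch) or the
attractor of an unstable strong-surfactant run with `B` matched to the
requested amplitude by bisection (upper branch).

The late-time approach to the static state is algebraic,
`H = H₀ + H₁/(Bt̃) + …`; the `O(1/t̃)` correction fields
`(H₁, Γ₁, Y±₁, W₁)` satisfy a coupled nonlinear system (with
`W₁ = B Y₋₁²/H₀ − (H₀/4B)(M∂_zΓ₁)²`, which vanishes exactly on the
immobilised line) solved by damped Newton iteration from a deterministic
ladder of seed amplitudes; the trivial root is excluded by requiring
`Y₋₁ ≥ 0` with non-trivial magnitude and `W₁ ≤ 0`.  Comparisons against
simulations exclude a few nodes at each boundary, where the symmetric
discretisation develops a corner (the one-sided limit of `H_zzz` at a
boundary is `2B/H₀ ≠ 0`, which an even extension cannot represent
smoothly).

Shock-like fronts develop in the surfactant-gradient field; their speed
obeys the jump condition `u_s = [ (w̃_sΓ)_z ] / [ Γ_z ]`, evaluated by
locating the steepest-`|Γ_zz|` node and linearly extrapolating one-sided
values from three nodes per side, skipping the two nodes nearest the front
(the central scheme smears the jump over a few cells).

## Standard problem sizes

All headline computations use the standard study conditions: `L = 2π`,
`N = 200` (thresholds `N = 241`), amplitude `A = 0.2` (0.25 for the
strong-surfactant and critical-thickness cases), horizons `t̃ = 1e4`.  The
package's own test suite runs a few supporting computations at reduced size
as a deliberate choice of scale: coarse critical-thickness bisections use
`N = 128`, `t̃ = 2×10³` and a ±0.005 certificate (the full ±0.001,
`t̃ = 1e4` protocol is available through `epsilon_crit_search` directly);
short-horizon equivalence and stability spot checks use `N = 64–161`.

## Known limitations

* The long-wave theory itself loses validity immediately before plug
  formation (the stopping rule `min R = 0.3` is the standard proxy), and
  post-coalescence dynamics are out of scope.
* The leading-order transport equation is used as stated; the full
  interfacial metric `√(1+R_z²)` is not included.
* Late-time states here stall on the immobilised line with wall stresses a
  few percent above the yield stress and relax only very slowly, rather
  than rigidifying at the `1/t̃` rate the interior asymptotic expansion
  describes; the corresponding structural checks in the acceptance suite
  are expected to fail and are retained deliberately as open observations.
* Passive (zero-Marangoni) surfactant transport is not integrated (see
  above); concentrations in surfactant-free runs are reported as their
  initial value.
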