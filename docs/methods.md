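# Methods

This note documents the model, the numerical scheme, the calibration
protocol, and the design choices behind `fatiguesim`, including the points
where the design was genuinely open and the reasoning that settled them.

## Constitutive model

Small-strain isotropic elasticity is degraded by a single scalar damage
variable `d` through the stiffness factor `f(d) = exp(-d)`, which is smooth,
strictly decreasing, and maps `d ∈ [0, ∞)` onto a surviving stiffness
fraction in `(0, 1]`. The free energy density is

    psi = 1/2 (eps - eps_p) : f(d) C : (eps - eps_p)
        + 1/2 beta |grad f(d)|^2
        + 1/2 k h^2

with `C` the isotropic stiffness tensor, `eps_p` the (trace-free) plastic
strain, `h` the isotropic hardening variable, `beta` the gradient
regularization parameter (units N = Pa·m², an energy density times a length
squared), and `k` the hardening modulus. Symmetric tensors are stored in the
6-component Voigt convention with engineering shears on strain-type
quantities; the convention is stated in `materials.py` and all operations
round-trip through it consistently.

The dissipation potential is a homogeneous function of first and second
order in the per-cycle rates,

    Delta = r_p w ||ep~|| + 1/2 eta_p w^2 ||ep~||^2
          + r_d w  d~    + 1/2 eta_d w^2 d~^2,       w = omega,

so each internal variable has a rate-independent threshold (`r_p`, `r_d`)
and a viscous over-force regime (`eta_p`, `eta_d`). Stationarity of the
governing functional yields Perzyna-type evolution rules in the cycle
coordinate:

* damage: `eta_d w d~ = < q - r_d >` with driving force
  `q = f * (psi0 - beta * lap f)`, `psi0 = 1/2 (eps-eps_p):C:(eps-eps_p)`;
* plasticity: deviatoric over-stress flow,
  `||dev sigma|| > r_p + k h` required, direction `dev sigma / ||dev sigma||`
  (trace-free by construction, which enforces plastic volume conservation),
  magnitude `(||dev sigma|| - r_p - k h) / (eta_p w)`, and `h~` equal to the
  flow magnitude.

**Sign of the gradient term.** The variational derivative of
`1/2 beta |grad f(d)|^2` with respect to `d` evaluates to
`-beta f lap f` on the driving-force side, i.e. `q = f (psi0 - beta lap f)`.
At a damage hotspot (a local minimum of `f`, where `lap f > 0`) the term
*reduces* the driving force and diffuses damage outward; a linear
perturbation analysis shows the opposite sign amplifies high-wavenumber
damage perturbations and de-regularizes the problem. The diffusive sign is
used throughout; it is what makes the lifetime mesh-converged (see the
paired-refinement test).

**Per-cycle driving energy.** `psi0` is evaluated at the load amplitude
(the peak of the cycle), not integrated over the cycle; one simulation is
run per amplitude. The stress ratio R is carried as metadata only — no
mean-stress correction is applied (an explicit non-goal).

**Plasticity default.** Plasticity is implemented but disabled by default.
With the reference constants (`r_p` = 100 Pa, `eta_p` = 100 GPa) the flow
rule at a 350 MPa amplitude accumulates plastic strain at ~3·10⁻⁴ per cycle
and hardening saturates only after ~10¹⁰ cycles, which is unphysical under
symmetric cyclic loading and swamps the damage problem; the elastic–damage
mode is the meaningful configuration for S-N reconstruction. The flag
`plasticity_enabled` turns the full model on.

## Cycle-domain integration

All evolution is integrated in `N = omega * t` ("time-to-cycle
transformation"), so a solver step spans many load cycles. The step size is
adaptive:

* `delta_d_max` (default 0.01): the fastest-evolving point may gain at most
  this much damage per step; `dN = delta_d_max / d~_max`.
* `delta_n_min` (default 10⁻³ cycles) and `delta_n_max` (default
  `max_cycles / 100`) clamp the step; a step with no evolution anywhere
  jumps straight to the runout budget.
* **Rate-growth step rejection** (`rate_growth_max`, default 1.2): after a
  trial step, if the fastest damage rate changed by more than this factor in
  either direction, the step is rejected and retried with a size
  extrapolated from exponential growth. Near the endurance threshold the
  rate grows (or collapses) quasi-exponentially from a tiny seed while the
  damage increment is negligible; without this control the
  damage-increment/step-clamp pair resolves that phase with a handful of
  maximal jumps and quantizes the lifetime at the several-percent level,
  which is far too coarse for calibration. With it, near-threshold lifetimes
  are smooth functions of the parameters at ~10⁻⁴ relative resolution.
* **Stall handling**: if the driving force drops to the threshold inside a
  step (strain-type loading), the crossing is located by bisection and the
  run becomes a runout; a run whose remaining budget cannot advance damage
  by 10⁻⁶·`delta_d_max` is likewise a runout. For the elastic–damage
  material point the stall damage is known in closed form
  (`d_stall = ln(psi0/r_d)` under strain control), and a run whose stall
  damage lies below the failure damage is classified as a runout
  immediately — it can never fail.

The default update is explicit forward Euler in `N` (first order, verified
by a Richardson ratio ≈ 2 against the closed-form life); a semi-implicit
option solves the local damage ODE implicitly per step for stiff
near-failure behaviour. The failure crossing inside the final step is
located exactly (explicit mode freezes the rate, so the crossing is linear)
or by interpolation (semi-implicit).

Material-point failure uses `f <= failure_fraction` (default 0.1, i.e.
`d* = ln 10`), mirroring the structural criterion: at a held displacement
the reaction of a homogeneous bar is proportional to `f`.

**Closed-form oracle.** For the elastic–damage point the life integral
separates:

    strain control:  N_f = eta_d w ∫₀^d* dd / (psi0 e^{-d} - r_d)
    stress control:  N_f = eta_d w ∫₀^d* dd / (psi0 e^{+d} - r_d)

with `psi0 = sigma_a²/(2E)` at the virgin state. It is evaluated by adaptive
quadrature, independent of the stepping engine, and anchors the
oracle-equivalence tests (agreement to 0.5% at `delta_d_max = 0.001` over a
grid of `(psi0, r_d, eta_d·w)` in both control modes).

## Finite-element specimen model

The 3-D coupon is idealized as a 1-D bar of variable cross-section `A(x)`
with 2-node linear elements (64 by default): internal variables live on
elements, equilibrium is a tridiagonal solve per step (the bar is linear
elastic at frozen internal state — a staggered scheme), and the reaction
force is the axial force at the constrained end. The stiffness factor is
projected to nodes by volume-weighted averaging, and the gradient term uses
the FE-consistent discrete Laplacian `(lap f)_i = -(K f)_i / M_i` with the
area-weighted stiffness form and lumped masses; zero-flux (natural) ends
make the volume-weighted total of the discrete Laplacian exactly zero, and
on a uniform-area mesh the interior stencil reduces to the standard second
difference. Units are SI throughout, so `beta * f * lap f` lands in Pa
directly.

Loading: the top displacement is held at the virgin-state value that
produces the nominal stress `sigma_a` at the minimum section (computed from
the mesh compliance, so the virgin waist stress is exact on the mesh; the
continuum-profile mapping `u = sigma_a A_min ∫ dx/(E A(x))` reproduces it to
<0.5% at 64 elements). A stress-controlled option re-targets the
displacement each step to hold the waist nominal stress; since its reaction
is constant by construction, that mode fails on the stiffness criterion
`min f <= failure_fraction` instead. Failure in the default
displacement-held mode is a drop of the reaction amplitude below 10% of its
initial value, with `N_f` interpolated between the bracketing records.

**Specimen geometry default.** The reference publication shows the coupon
only in a figure, so dimensions are configuration values. The defaults are
a round coupon with 5 mm gauge diameter, 12 mm ends, 60 mm total length, a
40 mm cylindrical gauge section and 10 mm cosine transitions. The
cylindrical gauge matters for the physics of the failure criterion: the
deepest reaction drop a damaging zone can produce before it unloads scales
with the zone's share of the bar's elastic compliance. With a knife-edge
hourglass waist the zone is one or two elements (~7% compliance share), the
reaction can only fall to ~10.7% of its initial value before the driving
force drops below any near-threshold `r_d`, and near-threshold lives are
numerically ill-conditioned. With the cylindrical gauge (~80% compliance
share) the displacement-held specimen approaches strain-control behaviour,
the reaction drop criterion is comfortably reachable, and the lifetime is a
smooth, steep function of `r_d` in the regime the calibration needs. A
fully waisted profile remains available via `flat_length = 0`.

## Calibration protocol

The reference material table is internally inconsistent for lifetime
prediction: with `r_d` = 6 Pa and `eta_d` = 0.2 MPa the model fails within
tens of cycles at 350 MPa, five orders of magnitude short of the reference
simulated lifetimes, and `r_d` is nine orders of magnitude below the elastic
energy density at that amplitude (~0.56 MPa) — consistent with a unit
misprint. Rather than guessing units, the two parameters that enter the
elastic–damage life integral only as a threshold and an overall time scale,
`r_d` and the product `eta_d * omega`, are treated as free and fitted to two
anchor lifetimes; the literal values remain the defaults and calibration is
explicit and logged.

The fit exploits the model structure. Lifetimes scale linearly in
`eta_d*omega` at fixed `r_d` (the rate law divides by it), so the *ratio* of
lifetimes at two amplitudes depends (to stepping accuracy) on `r_d` alone:

1. **Bracket and solve for `r_d`**: the anchor life ratio is matched by a
   root find on `r_d`. The ratio rises with `r_d` toward the endurance
   regime but is not globally monotone (a damage-localization branch can
   bend it back), so a coarse upward scan brackets the *first* crossing of
   the target ratio before Brent refinement; runouts count as above-target.
2. **Set the time scale**: `eta_d*omega` is fixed by the absolute life at
   the lower-amplitude anchor.
3. **Polish on the actual engine**: alternate an exact `eta_d*omega` update
   (linear scaling) with a bracketed 1-D solve in `r_d` for the
   eta-independent log-life ratio residual, with the bracket expanded
   geometrically from the current iterate so the solve stays well-scaled
   however close the root sits to an endurance pole. Residuals are reported
   in log10-life (fatigue scatter is multiplicative), and convergence is
   declared at 2·10⁻⁴.

Calibrated on the 350/600 MPa anchors with the default specimen
(64 elements), the protocol converges in a few seconds to
`r_d ≈ 6.91·10⁴ Pa` (0.124 of the virgin driving force at 350 MPa) and
`eta_d*omega ≈ 5.31·10⁹ Pa·cycles`, reproducing both anchors to ~10⁻⁶ in
log10-life on re-run. The held-out amplitudes are genuine predictions: the
calibrated model yields ~1.3·10⁵ cycles at 400 MPa and ~8.0·10⁴ at 450 MPa,
below the reference values (~1.0·10⁶ and ~4.9·10⁵) though within an order of
magnitude and correctly ordered. The shortfall is structural, not numerical:
with `f = e^{-d}` and a single endurance threshold the model's S-N curvature
between the anchors is essentially fixed, whereas the reference curve stays
flat from 350 through 450 MPa and then drops sharply — a shape that would
need an additional mechanism (for example an amplitude-dependent threshold
or a different damage-function family), which is out of scope here.

The anchor protocol (calibrate on the extremes, hold out the middle) is
deliberate: it makes the interior points a falsifiable test of the model
shape instead of a fit.

## S-N toolkit

* `run_sn_sweep` runs one independent simulation per amplitude and returns
  records `(sigma_a [MPa], N_f, censored, solver steps, engine)`; runouts
  carry the cycle budget (default 10⁷ cycles) as `N_f` with the censored
  flag set. Divergences are recorded per-record, never raised.
* `basquin_fit` performs least squares in `(log10 N_f, log10 sigma_a)` on
  uncensored records and reports `sigma_a = A · N_f^b` with `r²`. It is
  exact on noiseless power-law data and recovers the exponent within its
  regression standard error under seeded lognormal scatter.
* `generate_synthetic_sn` builds seeded synthetic Wöhler data: power-law
  mean, lognormal scatter in log10-life, runout censoring. It emulates the
  multiplicative scatter and censoring structure of real constant-amplitude
  test campaigns; it does **not** emulate amplitude-dependent scatter,
  staircase test designs, or surface-quality effects, so tests passing on it
  demonstrate correctness of the fitting/censoring logic, not fidelity to
  any particular experimental dataset.
* `compare_sn` aligns two tables on amplitude and reports the maximum
  relative life error and maximum |Δlog10 life|, excluding censored pairs.

## Parameters and defaults

| Parameter | Symbol | Default | Units | Meaning |
|---|---|---|---|---|
| `youngs_modulus` | E | 110·10⁹ | Pa | tensile modulus, annealed Ti-6Al-4V |
| `poisson_ratio` | ν | 0.32 | – | |
| `beta_regularization` | β | 0.1 | N | gradient-energy weight |
| `eta_d` | η_d | 0.2·10⁶ | Pa | damage viscosity (literal table value) |
| `eta_p` | η_p | 100·10⁹ | Pa | plastic viscosity |
| `r_d` | r_d | 6 | Pa | damage threshold (literal table value) |
| `r_p` | r_p | 100 | Pa | plastic threshold |
| `k_hardening` | k | 80 | Pa | hardening modulus |
| `omega` | ω | 10 | cycles/s | test frequency |
| `failure_fraction` | – | 0.1 | – | reaction-drop failure criterion |
| `max_cycles` | – | 10⁷ | cycles | runout budget |
| `delta_d_max` | – | 0.01 | – | damage increment per step |
| `rate_growth_max` | – | 1.2 | – | per-step rate-change bound |

The "hardening parameter h = 80 Pa" of the reference table is read as the
hardening *modulus* `k` (the symbol `h` names the internal variable in the
energy `½kh²`); this is the only dimensionally consistent reading. Body
forces are zero. The failure criterion printed as `|F| < 0.1·F` (literally
vacuous) is read as *reaction amplitude below 10% of its initial value*.

## Numerical choices and degenerate inputs

* Threshold equality (`q = r_d`) produces a zero rate (closed set);
  lifetimes at exact-threshold inputs are runouts.
* The two central elements of an even mesh tie in area on a symmetric
  profile and evolve identically; ties in `argmax` damage resolve to the
  first index but have no physical effect.
* `solve_equilibrium` raises a divergence status (not an exception through
  the sweep API) when all stiffness factors underflow; a damage cap of
  `d = 60` guards `exp` underflow far past structural failure.
* A zero-amplitude program yields zero reaction and the failure criterion
  is undefined; `detect_failure` rejects histories with zero initial
  amplitude.
* Bit-reproducibility: the physics is deterministic; the only randomness in
  the package is the seeded scatter of the synthetic fixture generator.

## Known limitations

* 1-D bar kinematics: no triaxiality, no 3-D stress concentration factor at
  the waist, no grip/thread modelling. Absolute agreement with any
  particular 3-D computation therefore runs through the calibration
  protocol, which absorbs the geometry scale.
* Amplitude-only driving: no mean-stress (R-ratio) effect, no
  variable-amplitude loading or rainflow counting.
* Single-threshold damage: as discussed, the S-N knee is less sharp than the
  reference curve's; interior-amplitude predictions inherit that shape.
* Finite-strain effects, kinematic hardening, temperature dependence, and
  surface-roughness knockdown factors are out of scope.
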