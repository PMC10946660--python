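# Methods

## Model

`luxqs` models a batch culture of a luminescent marine bacterium
(*Photobacterium phosphoreum*-type physiology) with six coupled ODEs in four
blocks. State: substrate `S`, biomass `N`, mean intracellular ATP `a`,
autoinducer `A`, LuxR receptor `R`, luciferase `L`; observed luminescence
`I = VL·L·a/(KL+a)`. Time is in hours; all concentrations are in the
arbitrary units of the fitted reference vector (no unit-conversion layer is
attempted, since the calibration itself is in arbitrary OD/RLU units).

    dS/dt      = −eps0·N·(fE + k0·fg)
    dN/dt      = fg·N
    eps1·da/dt = fE − k0·fg − ATPase
    dA/dt      = CA·N
    eps3·dR/dt = CR + VR·sat(a, a0)·D/(KR + D) − k3·R
    eps4·dL/dt = sat(a, KL)·D/(KR + D) − kdL·L

with `sat(x, K) = x/(K+x)`, the growth law
`fg = Vg·sat(S, Kg)·sat(a, Ka)`, ATP production
`fE = Ve·sat(S, Ke)·aⁿ/(Kae+aⁿ)·[inhibition]`, generalized ATPase
`kd·sat(a, eps2)`, and the quasi-steady-state dimer `D = (R·A)²/gamma` of the
Williams-type LuxR/autoinducer switch. `eps0 = Vb/Vc` is the cell-to-flask
volume ratio converting intracellular rates to flask-concentration rates;
`eps1 = 0.001` makes ATP the fast variable. Basal LuxR and autoinducer
synthesis are energy-independent (their cost is folded into the ATPase);
the induced LuxR and luciferase synthesis share the promoter activity
`D/(KR+D)` and are throttled by ATP. Autoinducer concentrations inside and
outside the cell are taken equal, there is no autoinducer degradation, and
no death term: the model covers inoculation through the end of the
logarithmic phase. An energy-starvation mortality law
(`death_rate`, `d0·K_d0/(K_d0+a)` with defaults d0=0.05, K_d0=0.5) is
provided for completeness but deliberately not wired into the combined
model.

### Structural configuration (`EnergyRateConfig`)

Three switches cover the family of defensible ATP balances:

* `activation_exponent` n ∈ {1, 2} — cooperativity of the autocatalytic ATP
  activation of its own production. n=2 is required for a *bistable* energy
  block (stable zero state), n=1 for an *unstable* zero state.
* `include_growth_cost` — whether `k0·fg` appears in the ATP balance.
* `atp_product_inhibition` — multiplies production by `a0²/(a0²+a²)`, a
  Selkov-style homeostatic feedback: production falls off once ATP exceeds
  the reference level `a0`. Off by default (the bare single-enzyme form used
  in the stationary-state analyses); **on** in the combined model's default
  configuration. Without it, the reference constants (Ve = 3.30 versus
  kd + k0·Vg ≈ 0.21) leave ATP production unopposed at high `a` for any
  substantial substrate level, ATP grows without bound during the growth
  phase, and the post-peak luminescence collapse — which in this model *is*
  the ATP crash — cannot occur. The inhibition scale is deliberately tied to
  the otherwise-unhoused constant `a0 = 1.40`, which also serves as the
  initial ATP level.

### Reference parameters

`reference_params()` carries the common fitted vector: Vg=2.18, Kg=3.99,
Ka=0.0033, Ve=3.30, Ke=4.02, Kae=0.008, a0=1.40, kd=0.0315, k0=0.082,
VR=1.50, CR=0.011, CA=0.14, k3=0.057, gamma=0.331, KR=0.06, KL=0.17,
eps0=0.01, eps1=0.001, eps2=1.54, eps3=0.39, eps4=3.34. The luminescence
scale `VL` and luciferase inactivation `kdL` are per-medium quantities and
live in the scenario presets. (Note eps2 = 1.54 is *not* small, so ATPase
activity varies substantially over the working ATP range; the package
treats this as an empirical fitting outcome, not an inconsistency.)

## Stationary-state analyses

The fast ATP equation is analysed as a 1-D rate law at frozen `S`:
roots of `atp_rate(S, ·)` are bracketed on a uniform grid (default 2000
intervals over [0, a_max], a_max defaulting to 4·max(1, a0)), refined by
bisection to 1e-10, deduplicated at 1e-6, and classified by the sign of the
rate on either side (step 1e-6; the boundary root a=0, which always exists
because production, growth cost and ATPase all vanish with ATP, is
classified one-sidedly). Two calibrated demonstrations ship with the
package:

* `bistable_demo()` — n=2, no growth cost, Ve=2, Ke=1, Kae=0.2, kd=0.5,
  eps2=0.5. Clearing denominators shows two positive roots exist exactly
  when `Ve·sat(S,Ke) < kd` and `(Ve·sat·eps2)² > 4(kd−Ve·sat)·kd·Kae`, an
  S-window of roughly (0.25, 0.33) for these constants; eps2 = 0.5 was
  chosen (over a smaller nominal value) because it widens that window from a
  numerically razor-thin sliver to a robust interval.
* `monostable_demo()` — n=1, growth cost on with k0=1.6 and Ka=0.04,
  Ve=3.299, Kae=0.008, kd=0.026, eps2=0.85. The zero state is unstable
  whenever `Ve·sat(S,Ke)/Kae > kd/eps2 + k0·Vg·sat(S,Kg)/Ka` (any S above
  ~4e-4 here), and the growth-cost channel caps production at large `a`
  (`Ve < kd + k0·Vg`), so exactly one stable positive root exists at every
  scanned S — ATP homeostasis.

## QS switch

With both binding steps of the (LuxR–AHL) complex at quasi-steady state the
switch reduces to one ODE in `R` with `A` as a parameter. Its stationary
condition inverts in closed form on `alpha < R < alpha + beta`
(`alpha = CR/k3`, `beta = VR/k3`, `sigma = KR·gamma`):

    A(R) = sqrt( sigma·(R − alpha) / (alpha + beta − R) ) / R

and the identity `luxr_rate(R, A(R)) = 0` is algebraically exact (the test
suite verifies it to 1e-9 over random parameter draws). Folds are located
as sign changes of the central finite-difference derivative of A(R) on a
10⁴-point grid refined by bisection — deliberately form-agnostic rather
than analytic. `hysteresis_loop` integrates the reduced equation along a
prescribed A(t); slow triangular ramps switch near the folds with a
finite-ramp-speed delay that shrinks as the ramp slows (checked by running
two speeds). Demonstration regime: alpha=0.1, beta=1, sigma=1, with the
induction-strength family beta ∈ {0.5, 1, 2, 4} (beta=0.5 is below the
bistability threshold at this alpha/sigma).

## Numerical integration

The combined model is stiff (eps1 = 0.001); `simulate` uses LSODA with
rtol=1e-8, atol=1e-10 by default. Negative round-off is clipped to zero in
*outputs* only, never in the integrator state; the RHS clamps components at
zero for rate evaluation (stiff solvers probe slightly negative values) and
raises on excursions beyond −1e-6 or on runaway/non-finite derivatives.

### Fast–slow diagnostics

`atp_tracking_error` compares a(t) with the largest stable positive root of
the energy block at the instantaneous substrate level, on the window from
0.5 h (past the initial relaxation layer — the inoculum enters at a0 = 1.4
and relaxes to the working root ≈ 5 within minutes, which also produces a
small upward blip in early luminescence) to the last time with
`S ≥ 0.1·S0`. Past substrate exhaustion the stable root is destroyed at a
fold; tracking necessarily degrades at a non-hyperbolic point for any
finite eps1, and the collapse *timing* is eps1-dependent, so the collapse
itself lies outside the reduction's domain of validity and outside the
diagnostic window. The same window is used when measuring the effect of
halving eps1 on the slow variables, and the luminescence-signature
diagnostic (`lum_signature`) starts at the same 0.5 h layer.

## Scenario presets and the synthetic-data generator

The generator emulates the phenomenology of the published batch-culture
curves (the raw data are not deposited): sigmoidal biomass growth to
saturation within the 16 h window, luminescence decaying slowly from the
inoculum level, igniting sharply at the QS threshold, peaking near 11–12 h,
then collapsing much faster than first-order luciferase decay. Presets
(model units, 0–16 h sampled every 0.25 h):

| preset | S0 | N0 | L0 | VL | kdL |
|---|---|---|---|---|---|
| rich | 4.0 | 0.03 | 0.2 | 1e4 | 0.30 |
| poor | 2.0 | 0.5 | 0.2 | 1e4/60 | 0.15 |

The per-medium ratios encode the reported contrasts: effective S0 halves
(growth is limited by the unchanged yeast-extract nutrients rather than the
100-fold-diluted peptone), VL drops ~60-fold, kdL roughly halves. The poor
preset carries a larger effective inoculum: with the reference QS constants
the ignition threshold is fixed, so onset time is
`ln(A_up·mu/(CA·N0))/mu` and a slower-growing culture at equal N0 would
ignite *later*; the larger N0 — consistent with the observed anomalously
dense early poor culture — is what reproduces the two-hour-earlier poor-
medium onset. With these presets the model yields rich onset 11.0 h, poor
onset 9.0 h, rich luminescence peak at 11.5 h with post-peak log-slope
≈ −9.1/h ≈ 30×kdL.

Observation noise: multiplicative lognormal on luminescence with requested
CV (unit mean; log-sd = sqrt(ln(1+cv²))) — photon-counting-style relative
error — and additive zero-truncated Gaussian on OD. The generator does not
emulate instrument dark counts, OD nonlinearity at high density, plate
effects, or biological replicate variation; passing recovery tests
therefore demonstrate self-consistency of the pipeline under the stated
error model, not robustness to real-instrument artifacts.

## Two-stage fitting

Stage 1 fits the growth side to the OD660 series with linear residuals;
stage 2 fits the QS/luminescence side to the luminescence series on the
log10 scale (its dynamic range spans orders of magnitude), with stage-1
values frozen. Log residuals use a detection-limit floor of 1e-6 × the
brightest observation (overridable): after the ATP crash the model's
intensity underflows toward round-off, and without a realistic floor the
dead tail would dominate the loss.

Free parameters are log-transformed and box-bounded (default: a factor of
10³ either side of the start), with out-of-box or failed-integration points
mapped to a large finite penalty (1e12 + squared bound distance). This
directly suppresses the half-saturation-constant collapse pathology of
unconstrained simplex search on Monod-type laws, which the test suite
reproduces on a minimal two-point example.

Default free sets: stage 1 {Vg, Kg, S0, N0} — the quantities a biomass
sigmoid actually constrains; Ka and the ATP-block constants are held at
reference because `sat(a, Ka) ≈ 1` along trajectories makes them
unidentifiable from OD data — and stage 2 {VL, kdL, CA, VR}. Both sets are
configurable, and stage 1 will use a substrate series alongside OD if the
data provide one.

The Nelder–Mead simplex is implemented in-package (reflection 1, expansion
2, contraction 0.5, shrink 0.5), declaring convergence on the joint
fminsearch-style test (simplex diameter < xatol *and* value spread <
fatol) — the joint test localizes the minimizer, not merely the minimum.
Benchmarks: quadratic bowls to 1e-6, Rosenbrock from (−1.2, 1) to 1e-4.
Stage fits default to xatol=1e-4 in log coordinates (≈0.01% in parameters),
fatol=1e-9, ≤500 iterations, and simulate at rtol=1e-6 for speed; fitting
is deterministic. `multistart` jitters starts log-normally from a seeded
generator, with the first start unjittered so n_starts=1 reproduces a
single fit and start sets are nested across n_starts.

Recovery-experiment problem sizes: the shipped analyses and acceptance run
use the 65-point preset grid, noise-free two-stage fits (4+4 free
parameters) and a 20-replicate noisy experiment freeing {VL, kdL} at 5%
luminescence CV with OD noise-free (stage 1 is then exact by construction
and is skipped). Typical results: noise-free recovery ≤0.12%, noisy
medians ≈1% (VL) and ≈4–6% (kdL).

## Known limitations

* The structural assignments of `a0`, `k0` and `KL` are the least
  constrained part of the model family; each is isolated in a single
  function (`fE`'s inhibition factor, the growth-cost terms, the
  luminescence/luciferase saturation) so a re-assignment touches one place.
* Which eps multiplies which equation follows the fast-ATP reading and
  listing order; it is a modeling commitment, not a derived fact.
* The energy-block demonstrations fix functional forms within the stated
  saturation family; they reproduce the *regimes* (state counts and
  stabilities), not any particular published curve point-by-point.
* Stage-2 identifiability of {CA, VR} rests on the onset transition shape;
  on sparser grids or higher noise these two partially trade off and the
  default free set should be narrowed.
* No uncertainty quantification beyond multistart dispersion and replicate
  IQRs; no stochastic (molecular-noise) switching, no spatial gradients,
  no stationary/death-phase biology.
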