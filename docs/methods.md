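# Methods

`gliomib` simulates a single glioma cell migrating through narrow gaps
between tethered normal glial cells in a two-dimensional tissue domain. This
note records the model, its numerical treatment, the parameter choices, and
what the scaled test configurations do and do not demonstrate.

## Model overview

**Fluid.** The interstitial medium is a viscous incompressible fluid on the
square periodic domain `[0, 0.1 mm)^2` (stored internally as 0.01 cm in CGS
units), with density 1.35 g/cm^3 and viscosity 2.7 g/(cm s). At these scales
the Reynolds number is ~1e-9, so the flow is effectively Stokes flow;
advection is retained as an option.

**Structures.** All cell boundaries are closed Lagrangian polylines of
zero-rest-length springs: the elastic energy is quadratic in the local
stretch, `E = (c/2) ∫ |∂X/∂s|^2 ds`, so the tension is `T = c|∂X/∂s|` and
curves are pre-tensioned circles. The glioma cell has a membrane
(c = 3.8e-5 g cm/s^2) enclosing a nucleus whose stiffness is dynamic (see
below). Normal cells are membranes (c = 2.3e-3) tethered node-by-node to
fixed anchors with stiffness 400 g/(cm s^2); they resist displacement but
deform passively. Structures and fluid exchange momentum through Peskin's
standard 4-point delta kernel. We use the standard (square-root) 4-point
kernel rather than the cosine variant because it satisfies the discrete
zeroth- and first-moment conditions exactly, which the test-suite asserts at
1e-14; the cosine kernel violates the first moment at the 1e-3 level.

**Migration cycle.** Movement alternates between elongation (active force
`c_a d` on the front membrane arc, rear arc tethered to anchors frozen at
the last switch) and retraction (no active force, front arc tethered to
anchors frozen at the switch, rear released, the pre-tensioned membrane
pulls the body forward). Switching is driven by the smoothed rate of change
of the cell-body length L(t): elongation ends when L' decays to the
retention rate `delta_ret+ > 0`, retraction when L' rises to
`delta_ret- < 0`; a switch is forced after a maximum phase duration, and a
minimum phase duration (an adhesion-turnover floor) suppresses switch
chatter when the cell is mechanically blocked. Front/rear arcs are the
membrane nodes within ±60° of ±d about the centroid (configurable), with a
fallback to extreme projections along d when confinement makes the shape so
non-convex that an angular window is empty.

**Direction and active force.** The migration direction d is the
disk-averaged chemoattractant gradient, normalized; when the sensing disk
(R_s^c = 0.4 um) is smaller than two grid cells the average is evaluated as
the bilinearly interpolated gradient at the centroid, since an
under-resolved disk integral is noisier. The active force magnitude is
`c_a = chi (alpha + |F_C|)` with `F_C = ∇C / (1 + lambda_s |∇C|^2)`
(chi = 0.7, alpha = 0.15, lambda_s = 20), so `|F_C| <= 1/(2 sqrt(lambda_s))`
for arbitrarily steep gradients. The gradient is evaluated at the front-most
membrane node for `|F_C|` and magnitude information enters only there; d
stays a unit vector.

**Acto-myosin and nucleus stiffness.** The mechanical signal is the sensing
pressure p^s: the fluid pressure averaged over disks of radius R_s = 4.69 um
around each membrane node and then over the membrane. Actin availability is
`[a] = max(0, k_p * pressure_scale * p^s)` (clamped: under the zero-mean
pressure gauge the sensed value can be negative, which carries no actin).
Bound myosin obeys `d[m_b]/dt = k1 [m_T][a] - (k1[a] + k_-1)[m_b]` with
steady state `[m_T][a]/([a] + 1/K)`, K = k1/k_-1 = 20. The nucleus stiffness
is `c_e^Gn = fold * c_e^Gn,b * r([m_b])` with the decreasing Hill rate
`r = k_s (1/m_b)^n / (K_mb^n + (1/m_b)^n) + k_s^min` (k_s = 5,
k_s^min = 0.1, K_mb = 1.8, n = 10): low myosin keeps the nucleus rigid
(r -> 5.1), accumulated myosin softens it 50-fold (r -> 0.1). Myosin-II
knockdown is exactly the sensitivity change k_p = 0.9 -> 0.045 and nothing
else.

**Chemoattractant.** `∂C/∂t = D_C ΔC + lambda_in 1_src - mu_C C` with
homogeneous Neumann boundaries (D_C = 2.15e-6 cm^2/s, mu_C = 1e-6 1/s,
lambda_in = 0.82 baseline). C is nondimensional: the tabulated numeric
source strengths (0.14 / 0.82 / 1.64) are used directly and the chemotactic
coupling consumes this nondimensional field. The source is one grid cell by
default (the source radius is otherwise unspecified); the fluid is periodic
while the chemical is no-flux — the mismatch is accepted as given.

**Drugs.** Blebbistatin B(t) adds a degradation term `-alpha B [m_b]`
(alpha = 1e-4 1/(s uM)); an association inhibitor D(t) multiplies the
binding rate by `exp(-D)`. Both obey `dc/dt = I * on(t) - mu c` with a
pulse during the first 1/3 hour of each injection cycle of length tau
(pulse duration configurable), decay rate 5.13e-4 1/s.

## Numerics

- **Fluid solver:** FFT-based. Pressure comes from the spectral solution of
  the quasi-static force balance (`p_hat = -i k·r_hat / k^2`), and the
  viscous term is integrated exactly per Fourier mode (exponential
  integrating factor), with advection explicit in skew-symmetric form.
  The integrating factor reproduces analytic Stokes decay to machine
  precision and, unlike Crank–Nicolson, damps grid-scale modes strongly —
  with a trapezoidal viscous step the near-unit-magnitude amplification of
  stiff modes couples to the explicit structure forcing and rings up over
  thousands of steps. Nyquist modes are dropped (their spectral derivative
  is undefined for real fields). The spatial-mean force mode is removed
  (momentum gauge) so a net active force cannot accelerate the whole
  periodic box; the mean mode can be evolved exactly when the gauge is
  disabled. Velocity is projected to the discretely divergence-free space
  every step; pressure has zero spatial mean.
- **Stability:** the structure coupling is explicit, so dt is bounded by
  the fastest boundary relaxation rate, roughly `c (pi/ds)^2 h / mu` for
  stretch modes and `c_t h / mu` for tethers. `fluid.stability_dt` applies
  these bounds with a safety factor; the published grid and stiffnesses may
  bound dt below the published 0.004 s, in which case the runner sub-steps.
- **ODEs (myosin, drugs):** exact exponential updates with coefficients
  frozen over the step — unconditionally stable, no solver tolerance. Drug
  steps split exactly at pulse on/off edges.
- **Chemoattractant:** cell-centered grid; the reflecting 5-point Laplacian
  is diagonal under DCT-II, and each step applies the exact semigroup of
  the semi-discrete operator plus the exact particular solution for the
  source. Positivity and the integral mass balance
  `dM/dt = lambda_in |src| - mu_C M` hold to round-off.
- **Curve maintenance:** glioma curves are resampled to uniform arclength
  spacing only at phase switches, where the front/rear index sets and
  frozen anchors are rebuilt anyway, so resampling never invalidates live
  node indices. Node spacing targets h/2 (h/3 in the scaled fixtures).
- **Step order** (fixed): force assembly → spreading → fluid solve →
  interpolation/advection → chemoattractant → sensing/kinetics/stiffness →
  drugs → phase machine → logging. Everything is deterministic; identical
  configurations give identical outputs, and checkpoint/restart is
  bit-exact.

## Parameters without published values

- **Nucleus radius:** 3 um (0.6 × cell radius), so the nuclear diameter
  (6 um) exceeds the default intercellular gap; configurable.
- **Retention rates:** ±0.02 um/s with a 120 s maximum phase duration at
  full scale, calibrated so the free-space cycle period is ~2 min;
  configurable, and scaled with the force boost in the mini fixtures.
- **Front/rear arc width:** ±60° about ±d; configurable.
- **pressure_scale:** the tabulated units of k_p against CGS pressure leave
  an overall scale between the simulated pressure gauge and the kinetic
  input unrecoverable from the published material; it is exposed as a
  single calibration constant. The scaled fixtures use the value at which
  the wild-type soft state is self-sustaining while knockdown remains
  below the Hill threshold at all observed pressures.

## Scaled test configurations

The published runs use a 512² grid, dt = 0.004 s and hours of simulated
time — far beyond a test suite. The mini fixtures run the identical code at
128², where the 4 um gap is only ~5 grid cells wide and the lubrication
films between sliding membranes are unresolvable, so a direct parameter
copy either jams every cell or blocks none. Relative to the published set
the fixtures therefore use: normal-cell membranes softened to 2.3e-4 with
radius 5 um (which relaxes the explicit-coupling dt bound to 0.04 s) and
their tether stiffness raised to 500 g/(cm s^2) so the gap's bulk
resistance is preserved; a glioma envelope pre-stiffened to 7e-5 so its
tension translocates the nucleus tail through the under-resolved pinch; a
~3× stronger active force; myosin kinetics 10× faster at the same
equilibrium ratio K = 20; a pressure-scale of 3; and the published
soft-regime Hill threshold variant K_mb = 3.6, which keeps the wild-type
soft state self-sustaining across transient dips of the sensed pressure.
In the Stokes regime velocities are linear in forces, so the boosts
compress the trajectory in time without changing the structure of the
force balance. The mini fixtures demonstrate the mechanism — pressure-fed
myosin accumulation softens the wild-type nucleus (stiffening rate 5.1 →
0.1) and lets it squeeze through a sub-nuclear gap in ~20 min of
compressed time, while the knockdown cell keeps a rigid nucleus (r ≈ 5.1),
a nearly undeformed lateral width, and stalls in the gap mouth — not the
published absolute passing times or speeds.

What the synthetic scenarios do not emulate: three-dimensional geometry,
ECM proteolysis, cell proliferation, membrane-membrane adhesion, multiple
competing pseudopods, or stochastic direction noise. Passing tests on these
fixtures show internal consistency of the coupled solver and the direction
of the published parameter effects, not quantitative agreement with tissue.

## Known limitations

- The sensing pressure is partly self-generated (membrane and nucleus
  pre-tension), so the confinement signal rides on a baseline that depends
  on the nucleus's own stiffness state; pressure_scale positions the
  wild-type and knockdown steady states on opposite flanks of the Hill
  threshold.
- Quantities reported by the reduced-scale runs (passing times, speeds)
  are in compressed time units and are not comparable to the published
  absolute numbers.
- No contact or adhesion model beyond fluid mediation; very narrow gaps
  are resolved only a few grid cells wide at 128².
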