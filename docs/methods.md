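# Methods

## The glide model

During a glide the body produces no thrust, so its along-path
acceleration is the sum of three external-force terms: quadratic drag
opposing motion, tissue net buoyancy, and gas net buoyancy, the two
buoyancy terms projected onto the movement axis by sin(pitch):

a = −½·k·ρ_sw·v² + g·sin p·(ρ_sw − ρ_t(d))/ρ_t(d) + g·sin p·(V_air/m)(d)·(ρ_sw − ρ_air(d))

* **k = (Cd·A)/m** (m² kg⁻¹) — drag coefficient × reference area ÷ mass,
  treated as one parameter because the three factors are not separately
  identifiable from glide data. A plausible central value, built from
  drag coefficients of similar-sized cetaceans (≈0.0030) and
  allometrically estimated area (23 m²) and mass (6816 kg), is
  0.0030·23/6816 ≈ 10×10⁻⁶ m² kg⁻¹; the prior is Normal(10×10⁻⁶, 2×10⁻⁶)
  truncated to [5, 20]×10⁻⁶.
* **ρ_tissue** (kg m⁻³) — density of the non-gas body compartment at
  surface pressure; uniform prior on [800, 1200]. At depth the tissue is
  compressed: volume shrinks as V₀(1 − r·P) with P the model gauge
  pressure, so ρ_t(d) = ρ_tissue/(1 − r·P(d)). The reciprocal form is the
  volumetric definition; it differs from the linearised (1 + r·P) form
  by O((rP)²) ≈ 10⁻⁵ at 1000 m, far below every tolerance used here.
* **V_air/m** (ml kg⁻¹) — air carried from the surface per unit mass.
  The gas compartment is unprotected from ambient pressure and follows
  Boyle's law under the absolute pressure ratio q = 1 + d/10 atm: volume
  scales by 1/q (1% of the surface value at 1000 m) and gas density by q.
  Uniform prior [5, 50] on the population mean.
* **r** (Pa⁻¹) — tissue compressibility, a single global scalar (it is
  set by gross anatomy, not by behaviour); uniform prior
  [0.3, 0.7]×10⁻⁹, a physical band bracketing seawater.

Pressure conventions: the model books pressure at 1 atm (101,325 Pa) per
10 m of depth — gauge pressure for tissue compression, absolute ratio for
the gas law. Gas mass is excluded from body mass (≤0.003% of it). Lift
and induced drag are ignored; speed is the non-negative along-path
scalar. Surface air density defaults to 1.225 kg m⁻³; its effect on the
gas term is ≤10⁻⁴ near the surface.

## Seawater

Ambient density uses the EOS-80 international equation of state
(one-atmosphere equation plus secant bulk modulus), validated against the
published check values to <0.01 kg m⁻³. CTD casts are linearly
interpolated; below the deepest cast point temperature and salinity are
held at their deepest values while pressure keeps increasing, which keeps
the profile continuous and defined at all depths. Temperature-only casts
are completed with a user-supplied constant salinity (default 35 psu).

Two compressibility quantities are deliberately distinguished:

* the **instantaneous** isothermal compressibility κ = (1/ρ)∂ρ/∂P,
  computed by a symmetric finite difference (step 10⁴ Pa; step-halving
  changes the result by <10⁻³ relative). For 0 °C, S=35 water at the
  surface this is 0.463×10⁻⁹ Pa⁻¹ (= 1/K₀ with K₀ ≈ 21,582 bar).
* the **dive-equivalent** compressibility: the value of the model's r
  that reproduces seawater's actual compression from the surface to a
  dive depth, i.e. (1 − ρ(0)/ρ(d)) / P_model(d), with seawater's
  compression evaluated at the oceanographic hydrostatic pressure
  (~1 dbar per metre) and P_model the model's atm-per-10-m gauge
  pressure. Because the secant compression over a deep dive is smaller
  than the surface derivative, and the model pascal is slightly larger
  than the oceanographic one, this gives 0.450×10⁻⁹ Pa⁻¹ at the default
  1000 m (0.447×10⁻⁹ at 1500 m). This — not the instantaneous surface
  value — is the number comparable with a fitted tissue compressibility,
  which acts as a secant coefficient over the whole dive range.

## Tag processing

* Pitch/roll: a moving-average low-pass (default 3 s) estimates the
  gravitational component, normalized to |g| = 9.8; pitch is the arcsine
  of the normalized component on the pitch axis, roll an arctangent of
  the lateral/dorso-ventral pair. Samples whose gravity-estimate
  magnitude deviates from 9.8 by >30% are flagged unreliable. The pitch
  axis defaults to the longitudinal (surge) axis — the standard gravity
  geometry — with a switch to the dorso-ventral axis for tag conventions
  that put sin(pitch) there.
* Glide detection: the dorso-ventral axis is high-pass filtered
  (zero-phase 2nd-order Butterworth, default 0.2 Hz within the
  0.19–0.25 Hz band used in the field) and its absolute value is closed
  morphologically over 1 s to form a stroking envelope; samples whose
  envelope exceeds a per-deployment threshold (0.1–0.5 m s⁻², default
  0.3) are stroking, and glides are the maximal complementary intervals.
  The closing window bridges the sub-second zero-crossing dips of a
  stroking oscillation, so a continuous stroke bout is not shredded into
  spurious micro-glides.
* Dive phases: a dive is an excursion beyond 20 m (configurable).
  Descent runs until smoothed pitch first becomes non-negative or depth
  first exceeds 0.75 × max depth, whichever is first; ascent is found
  symmetrically from the end; bottom is the remainder. Using "pitch ≥ 0"
  (rather than strictly positive) makes an idealized flat-bottomed dive
  open its bottom phase at the moment the body levels off, while an
  ideal V-dive's phases meet at the apex.
* Speed: from the calibrated propeller channel when present (ordinary
  least squares of depth-rate reference speed on rotation rate over 5-s
  windows with mean |sin p| > 0.9, the predictive regression direction,
  since the line is subsequently applied to rotation data), otherwise
  from vertical rate ÷ sin(pitch) — the reason segments are required to
  be steeper than 30°.
* Segments: each glide is cut into 5-s windows from its start; windows
  1, 3, 5, … are kept (alternate-drop, to reduce autocorrelation) and
  trailing partials discarded, so a glide of duration T yields
  ceil(floor(T/5)/2) segments. Per window: a = OLS slope of speed vs
  time, σ_a = RMS of the fit residuals, v/d/p = window means. Filters:
  |pitch| ≥ 30°, roll circular variance < 0.1, window fully inside a
  descent or ascent phase (bottom-phase glides are excluded), reliable
  gravity estimate, positive speed. Per-stage drop counts are logged.

## Bayesian estimation

Each segment's measured acceleration is Normal around the model
prediction with its own residual RMS as a known observation s.d.
(σ floored at 10⁻³ m s⁻²; an optional global multiplicative error scale
is available but off by default). Density, drag and gas can each be
global, per-group (individual, or dive for gas), or hierarchical:
group values drawn from a truncated normal with estimated population
mean and s.d. Between-group s.d. hyperpriors are uniform: U(0, 20)
kg m⁻³ for density, U(0, 10×10⁻⁶) for drag, U(0, 50) ml kg⁻¹ for gas.
Dive-level gas values live on [0, 200] ml kg⁻¹ — wider than the [5, 50]
prior, which constrains only the population mean, because individual
dives can plausibly carry far less or more air than the average.

The sampler is a blocked adaptive Metropolis-within-Gibbs kernel. All
groups of a block are proposed jointly and accepted elementwise — valid
because, conditional on everything else, group values enter disjoint
likelihood factors — which reduces a sweep to a handful of vectorized
array operations regardless of the number of individuals and dives.
Scalar parameters (r, hyperparameters, error scale) get univariate
random-walk updates. Proposal scales adapt toward 0.44 acceptance with a
Robbins–Monro schedule during burn-in and are frozen afterwards, so the
retained draws target the exact posterior. Chains initialize at prior
means jittered by 1% (seeded); a non-finite starting state triggers up to
5 re-jittered restarts. The default protocol is 3 independent chains of
24,000 iterations, 12,000 discarded as burn-in, thinning by 36 (~334
retained draws per chain). Identical seeds give bit-identical output.

Convergence is monitored with the classic potential-scale-reduction
factor (between/within variance ratio); summary tables flag rows with
R̂ > 1.1. Model comparison uses DIC = D̄ + pD with pD = D̄ − D(posterior
mean), deviance being −2 × the Gaussian log-likelihood. Credible
intervals are equal-tailed 2.5%/97.5% quantiles of the pooled chains.

Sampler correctness is established against independent oracles rather
than against a named reference sampler: a brute-force grid posterior for
the one-parameter reduced model (2% total-variation agreement), the
closed-form truncated-Gaussian posterior of the linear-in-gas reduced
model, and prior recovery under an uninformative likelihood
(Kolmogorov–Smirnov).

## Synthetic data

The generator emulates the study conditions the estimator assumes. The
default population: 12 individuals × 10 dives, tissue densities
TruncNormal(1031.5, 1.5²) — individuals spanning roughly 1028–1034
kg m⁻³ — drag terms TruncNormal(12.6×10⁻⁶, (2×10⁻⁶)²), dive gas volumes
TruncNormal(27.4, 15²) on [0, 200] ml kg⁻¹, and r = 0.38×10⁻⁹ Pa⁻¹. The
per-dive gas s.d. of 15 ml kg⁻¹ is deliberately smaller than the spread
of fitted per-dive estimates reported in the field, since that spread
includes per-dive estimation noise on top of behavioural variation.

Glide tables draw (v, p, d, phase) per segment — depths log-uniform on
20–800 m so the shallow depths that carry the gas information are well
represented, pitch magnitudes uniform on 30–80°, speeds uniform on
0.8–2.5 m s⁻¹, σ_a uniform on 0.005–0.05 m s⁻² — and add Normal(0, σ_a)
noise to the model acceleration. The default 300 glide segments per
individual matches the scale of real deployments (hundreds per animal).

Full tag records alternate stroking bouts (thrust relaxes speed toward a
1.5 m s⁻¹ cruise with a 5 s time constant, plus a 0.4 Hz, 0.8 m s⁻²
oscillation on the dorso-ventral axis) with glide bouts integrated from
the glide dynamics by RK4; a glide is abandoned once speed decays below
1.0 m s⁻¹ (~2/3 of cruise), which concentrates gliding in the
buoyancy-aided travel direction as observed in real records — dense
animals glide mostly during descent. Gravity components in the simulated
accelerometer are consistent with pitch; white noise (0.02 m s⁻²) is
added; roll is held near zero so the stability filter passes by
construction. The fitted model never sees stroking data, so the thrust
model only affects glide initial conditions.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: tag-frame→whale-frame misalignment,
heading-dependent maneuvering and non-zero roll, speed-sensor biases,
depth-dependent temperature effects on tissue, non-Boyle (protected) gas
compartments, lift/induced drag at shallow pitch, and model
misspecification of the drag law. Recovery results bound estimator error
under a correctly specified observation model only.

## Numerical choices and problem sizes

* EOS finite-difference step 10⁴ Pa; small negative gauge pressures are
  admitted so the symmetric difference can straddle the surface.
* Glide integration: fixed-step RK4, dt ≤ 0.1 s (halving dt changes a
  20 s glide's final speed by <10⁻⁶ m s⁻¹); integration terminates if
  speed reaches zero.
* Degenerate prior bounds (lo = hi) pin a parameter, which is how the
  reduced one-parameter and linear-in-gas oracle models are built.
* Study sizes used by the test-suite and the acceptance script: the
  recovery study fits 12 × 300 segments with the full 3 × 24,000
  protocol (~30 s); the grid-oracle comparison uses 240 segments and
  3 × 60,000 unthinned iterations so Monte-Carlo error sits well below
  the 2% TV criterion; DIC selection uses 10 replicates of 6 × 60
  segments at a reduced protocol (4,000 iterations); the glide-pattern
  contrast simulates 4-dive records at 5 Hz.

## Known limitations

* The drag term and tissue density are partially confounded unless the
  data span both descent and ascent and a wide speed range; the
  informative drag prior is doing real work in sparse designs.
* Gas volume is informed almost entirely by glides shallower than
  ~100 m; records without shallow ascent glides leave it close to its
  prior (this is itself verified by a test).
* DIC is the only model-comparison criterion implemented.
* The dive-phase rule is a simple pitch/depth heuristic; records with
  prolonged level swimming at depth can blur the descent/bottom
  boundary.
* NetCDF output uses the netCDF3 (scipy) backend.
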