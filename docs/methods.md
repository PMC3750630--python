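# Methods

This note documents the numerical procedures, parameter choices, and
design decisions behind the package, and what its synthetic protocols do
and do not establish.

## Model and assumptions

The package works entirely at the relative-phase level: the two underlying
oscillators whose phase difference φ summarizes are never modelled. The
reduced three-variable situated system (φ, η, α) — phase, stimulus level,
orientation to the gradient peak — is treated as the authoritative
definition of the sensorimotor loop; the 2D Cartesian embodiment is a
best-effort visualization layer (`reconstruct_cartesian`), since the full
reduction from planar kinematics is not part of the implemented surface.
The reduction assumes a radially symmetric gradient, so η̇ depends on
position only through distance, and a circular body of radius R whose two
motors map phase to speed as M_r = m·cos φ, M_l = m·cos(φ + c). The speed
parameter m is absorbed by the reduction; the embodiment layer owns it
with default 1.

Parameters (all dimensionless except where noted): coupling coefficients
a = 5, b = 1 (fixing the monostable regime via a/b), motor bias c = 5 rad,
intrinsic frequency difference Δω₀ = 1 rad/s (kept explicit even though
the canonical reduced system hard-codes 1), sensor gain s swept over
[0, 15]. The α-equation carries a genuine 1/η singularity; evaluating it
within |η| ≤ η_min (default 1e−6, configurable) is an error, never a
clamp, and an integration that reaches the guard aborts with the partial
trajectory.

## Fixed points and spectra

Fixed points of the situated system are closed-form: η̇ = 0 forces
cos α = 0 (α = ±π/2); φ̇ = 0 then collapses to the decoupled root equation
(the gain s drops out, so locations are s-independent); η follows from
α̇ = 0 as η = sin α · P/Q with P = cos φ + cos(φ+c), Q = cos φ − cos(φ+c).
Decoupled roots come from a ≥4096-point sign scan with Brent refinement to
1e−10; each closed-form candidate is cross-validated by a Newton solve of
the full 3D system. Candidates with Q ≈ 0 (degenerate motor difference)
are skipped with a warning.

An important structural point: the reduced equations are **not** invariant
under (η, α) → (−η, −α). The four candidates therefore have distinct
spectra — for canonical parameters the attractor is at
(0.112, −2.285, −π/2), the repeller at (2.527, −0.435, −π/2), and the two
η > 0 mirror partners are saddles. Published descriptions of this system
place the attractor at η = +2.28 with α = −π/2, which the printed
equations do not satisfy; since the sign conventions of the α-equation are
not internally consistent in the source material, this package classifies
every candidate by its eigenvalues and compares stimulus *magnitudes*
|η| = 2.285 and 0.435, which are convention-invariant (we verified that
every sign-convention variant of the η̇/α̇ equations produces identical
spectra).

Jacobians are closed-form (validated against sympy and central finite
differences at 1e−6): the sensory term contributes s·∂η̇/∂φ and s·∂η̇/∂α
to the φ-row. The passive 4×4 Jacobian is block lower-triangular — the
copy never feeds back — so its spectrum is the 3D spectrum plus the
decoupled Jacobian at φ*, its λ₄ eigenvector is the φ*-axis, and every
other eigenvector satisfies v_φ* = v_φ (this drives the linearized
solution used by the noise experiment).

## Gain sweep and transition detection

`sweep_eigenvalues` computes fixed points once and re-evaluates spectra on
a gain grid (default step 0.05 over [0, 15]). Eigenvalues are sorted by
descending real part; a conjugate pair is flagged when |Im λ| > 1e−9. The
discrete "structure key" of a spectrum is the slot-index set the pair
occupies. `detect_transitions` scans consecutive grid points for key
changes and refines each event by bisection to 1e−3:

* pair appears / vanishes — spiral attraction or repulsion switching on
  or off;
* `plane_switch` — the pair still exists but occupies different slots:
  the real eigenvalue has crossed through the pair's real part, abruptly
  reassigning the spiral between eigen-planes.

Eigen-plane *labels* (the two dominant state coordinates of the pair's
eigenvector, ties broken in coordinate order φ, η, α, φ*) are recorded as
metadata but deliberately not treated as transitions: eigenvectors rotate
smoothly, and a dominance crossover (e.g. at the repeller near s ≈ 1.61)
is not a qualitative event.

Under the reduced equations exactly as written, the events for canonical
parameters are at s = 2.226 (repeller plane switch), 5.199 (attractor
pair vanishes) and 10.449 (attractor pair re-appears). Published values
for the same three events are 2.4, 5.1 and 10.4. The latter two are what
one obtains by quoting the last 0.1-grid point before the change; the
repeller value 2.4 is not reproducible from the printed equations under
any sign convention or rounding of the fixed-point coordinates we tried
(the spectra are convention-invariant), and we report our computed value
rather than forcing agreement. The behavioral boundary (below) brackets
the same gain region.

## Noise propagation into the passive copy

Around the attractor, φ*(t) = φ(t) + Δφ*(t) with Δφ* carried by the
single φ*-axis mode. With per-step noise injected into both phases, the
mode becomes a causal exponential filter of the injected-noise difference
ξ(t), discretized as the AR(1) recursion Δ_{k+1} = Δ_k·e^(−λ₄dt) + ξ_{k+1}
(boundary convention Δ₀ = ξ₀, documented since the continuous integral
leaves the first sample open). λ₄ = |J_decoupled| = 8.87 at the attracting
root, held constant along the run; a state-dependent λ₄(φ_k) variant is
available behind `lambda_mode="state"` for sensitivity analysis.

Protocol: 4D passive system, dt = 1 ms, T = 5 s, zero-mean Gaussian
increments of variance 1e−4 added once per step to φ and φ*; start at the
canonical arbitrary initial state (0.65, −2.78, −2.07) with φ*(0) = φ(0),
so the scored series includes a genuine transient; R² is computed over the
full series with no burn-in (a burn-in option exists, default 0). We
obtain R² ≈ 0.999 across seeds — the linear prediction is essentially
exact at this noise level, slightly above the ≈ 0.95 reported previously
for this protocol — and a fluctuation amplification
Var(Δφ*)/Var(ξ) ≈ 57, matching the AR(1) closed form
1/(1 − e^(−2λ₄dt)) at these (λ₄, dt). A previously published
Var(Δφ*) = 12.3e−4 (amplification ≈ 6) is not reproducible under either
documented noise convention; because the injection convention behind that
number is ambiguous, the package reports the value per `noise_mode`
(`state_increment`: per-step variance as configured — the literal reading;
`sqrt_dt`: variance scaled by dt, the SDE convention; the amplification
ratio is scale-invariant and identical under both).

## Dynamic signature

The signature of a coupling condition is the normalized 2D histogram of
(φ, φ̇) — (φ*, φ̇*) for the passive variant — accumulated while the state
is reset every 20 ms to randomized values: φ, φ* ~ U[0, 2π), α ~ U[−π, π),
η ~ U[−3, 3] excluding (−0.1, 0.1) (covers both fixed-point magnitudes
while staying clear of the 1/η singularity; ranges are configurable). All
state coordinates are reset, including φ*: leaving φ* free-running makes
the passive density track its input-shifted attractor quasi-statically
(flat conditional mean), which contradicts the qualitative description of
the passive signature as a thickened copy of the decoupled phase portrait;
resetting all coordinates reproduces it. Rates are evaluated from the rate
function at each recorded state, never by finite differences; the reset
step itself is excluded (the jump is protocol, not dynamics); segments
hitting the η guard are dropped and counted (none occur under default
ranges — 20 ms cannot carry |η| ≥ 0.1 into the guard band at |η̇| ≤ 2).

Because 20 ms segments are dynamically independent, the protocol runner
integrates all segments in parallel (identical Euler scheme and
per-coordinate seeded streams as the sequential integrator); a 1,000 s run
is 50,000 simultaneous 20-step segments and takes well under a second.
Production comparisons use 1,000 s runs (5 × 10⁴ segments, 9.5 × 10⁵
recorded samples) on a 200 × 200 grid over φ ∈ [0, 2π), φ̇ ∈ [−10, 12]
(the decoupled range Δω₀ ± (a + 2b) plus input excursions s·η̇ ∈ ±4).

Comparisons use the Jensen–Shannon divergence (natural log) between
densities, with the *noise floor* estimated from same-length passive
replicas at different seeds. At 1,000 s the situated-vs-passive divergence
is ≈ 0.185 against a floor of ≈ 0.023 — an ~8× separation, stable across
seed pairs.

One structural identity is worth stating because it rules a comparison
out: both variants' recorded rate deviates from its *own* decoupled
backbone curve φ̇ = Δω₀ − a sin φ − 2b sin 2φ by the identical series
s·η̇(t) (the copy receives the same input stream), so the probability mass
within any fixed-width band around the backbone is the same for both up to
histogram discretization (±2e−4 at these sizes). `band_mass` (default
half-width 3.0 rad/s, at which ≈ 83% of either density lies in the band)
is therefore a property of the protocol, not a discriminator between
coupling conditions; what distinguishes them is the *joint* structure —
the situated density fans out with a φ-dependent width ∝ |P(φ)| and
pinches where P(φ) = 0, while the passive density is a uniformly blurred
copy of the backbone — which the JS divergence captures.

## Behavior metrics

Gradient-climbing efficiency is F_d = 1 − d(t₁)/d(0) with t₁ = 40 s,
where distance is obtained from η through the affine map
d = d₀ − (η − η₀)/slope (linear radial gradient, slope 1, d₀ = 40 by
default; d is clamped at 0 once the peak is passed; only the ratio enters
F_d).

Strategy classification evaluates the second half of a 40 s run
(dt = 2 ms) from the canonical start (0.65, +2.78, −2.07) — chosen on the
gradient-climbing branch; from initial states with η < 0 the reduced
system converges to the circular-orbit attractor for every gain and no
winding occurs. Decision rule, thresholds validated on the three
exemplars s = 1.5, 2.5, 8:

* winding rate of unwrapped α > 0.2 rad/s → **cycloidal** (the agent
  keeps turning over itself while slowly climbing);
* else climb rate η̇ ≥ 1.45 units/s → **direct** (near the geometric
  maximum 2|cos(c/2)| ≈ 1.60, a straight run at the peak);
* else → **spiral** (slow climb, s large).

The cycloidal boundary of a 0.1-step sweep falls at s ≈ 2.45, inside the
gain region bracketed by the repeller's eigen-plane reassignment — the
dynamical transition and the behavioral one coincide to within the sweep
resolution. The direct/spiral threshold intentionally makes "direct" a
narrow band around the most efficient gain; at s ≈ 2.6–2.7 the labels are
sensitive to the threshold, and only the three exemplar gains are treated
as ground truth.

## Numerical conventions

* Euler update x_{k+1} = x_k + f(x_k)·dt + ξ_k, noise once per step,
  resets applied before the step they land on; RK4 available for
  step-size cross-checks (first-order convergence of Euler is verified
  against the closed form of φ̇ = −sin φ).
* Reproducibility: the integrator seed spawns one child stream per
  (purpose, coordinate) — noise and resets never share draws, and the
  (φ, η, α) block of a passive run is bit-identical to the situated run
  with the same seed.
* Angles are stored unwrapped; wrapping to [0, 2π) happens only in
  analysis (histograms).
* Eigen-pair threshold |Im λ| > 1e−9; transition bisection tolerance
  1e−3 in s; fixed-point residual tolerance 1e−9.
* A 6.5 s run at the coarse step dt = 0.1 from (0.65, −2.78, −2.07) ends
  ≈ 0.12 from the attractor (slowest mode Re λ ≈ −0.29 has not finished
  decaying); within-0.05 convergence needs ≈ 12 s. Tests freeze the
  coarse-step endpoint from an independent plain-Euler oracle.

## Limitations

The synthetic protocols probe the reduced model under idealized
conditions: additive Gaussian state noise, exactly periodic resets,
uniform reset distributions, a linear radial gradient. They establish the
internal consistency of the analysis (spectra, linear response, density
comparisons), not claims about biological oscillators or about robustness
to structured/multiplicative noise. The unbounded growth of η on the
climbing branch is an artifact of the reduction (a physical stimulus
saturates at the peak); behavior metrics therefore only use η through
ratios or thresholded rates. The 2D path reconstruction reports its
self-consistency diagnostic (RMS mismatch of recomputed α) but does not
enforce it.
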