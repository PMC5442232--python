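# Methods

## Model class

The package integrates networks of rate units

τᵢ dXᵢ = [ −Xᵢ + μᵢ + φ(Σⱼ wᵢⱼ ψ(Xⱼ(t−dᵢⱼ))) ] dt + √τᵢ σᵢ dWᵢ,

with per-unit time constant τ (ms), mean drive μ, noise amplitude σ and
one non-trivial input nonlinearity: a `linear_summation` flag selects
whether the unit's gain acts as φ (on the summed input, the default) or
as ψ (per source rate before summation).  The noise is additive, so the
Itô and Stratonovich readings coincide.  The √τσ convention fixes the
uncoupled stationary variance at σ²/2; it also fixes the noise increment
of every discrete scheme below.  Supported gains: linear g·x, tanh(g·x),
threshold-linear g·(x−θ)·H(x−θ), identity.  Optional extensions per unit:
an intrinsic drift a(X) replacing −X+μ (Euler–Maruyama only), a leaky
intrinsic nonlinearity f with −X+f(X) and a multiplicative coupling
factor H(X) (exponential Euler), and output noise, where the noise rides
on the published rate Xₖ + √(τ/Δt)σηₖ instead of the state — the unique
scaling under which holding the white-noise term constant over a step
discretizes √τσξ(t).

## Integration schemes

* **Euler–Maruyama**: Xₖ₊₁ = Xₖ + [−Xₖ+μ+φ(·)]Δt/τ + σ√(Δt/τ)ηₖ.
* **Implicit (semi-implicit) Euler**, solved on the single-unit level by
  the fixed-point iteration Φ(y) = [Xₖ + (μ+φ(inputs(y)))Δt/τ +
  σ√(Δt/τ)ηₖ]/(1+Δt/τ), initialized at Xₖ.  The iteration contracts iff
  (Δt/τ)/(1+Δt/τ)·max|eig(W)| < 1.  Inner defaults: tolerance 1e−12
  (max-norm), iteration cap 2000.  The cap is sized so that slow
  contraction near the stability edge (factor ≈0.95 for the stock
  all-to-all network at Δt = 0.05, needing ≈560 iterations) completes
  rather than being misreported as divergence.
* **Scalar stochastic exponential Euler**: Xₖ₊₁ = e^{−Δt/τ}Xₖ +
  (1−e^{−Δt/τ})[μ+f(Xₖ)+H(Xₖ)φ(·)] + σ√((1−e^{−2Δt/τ})/2)ηₖ.  Leak and
  additive noise are integrated exactly; only the recurrent drive is held
  piecewise constant, so the scheme is exact at any step for uncoupled
  units.
* **Exact linear propagator** (identity gains, homogeneous τ, no delays):
  mean via e^{AΔt/τ} with A = −I+W, drift response via the block-matrix
  integral (no explicit inverse, so singular A is fine), and one-step
  noise covariance Σ from a Lyapunov solve of AΣ+ΣAᵀ = PQPᵀ−Q.  The noise
  map is the **symmetric** square root of Σ: it stays within O(Δt^{3/2})
  of the diagonal map σ√(Δt/τ)I, so a scheme and the oracle driven by the
  same normal draws share the leading-order noise path.  An arbitrarily
  rotated factor (e.g. V√Λ from an eigendecomposition) satisfies SSᵀ = Σ
  but decorrelates the trajectories and destroys the strong-error
  measurement.

## Noise streams

Every unit consumes exactly one standard-normal draw per step.  Draws are
organized in 256-step blocks: block b of a run with master seed s is the
(256, N) matrix generated from Philox keyed by SeedSequence([s, b]);
column u belongs to unit u.  The draw for (seed, unit, step) is therefore
a pure function of those integers, which makes trajectories independent
of chunking, lets waveform-relaxation sweeps replay identical noise, and
lets approximate schemes share increments with the exact propagator.

## Accuracy protocol and RMSE

For each step size the exact reference and the scheme are driven by the
same per-(unit, step) draws; the RMSE between the trajectories is the
discrete L² time average √(Σᵢⱼ(Xⱼⁱ−X̂ⱼⁱ)²/(N·n)) over the n grid points
after t₀ — equivalently the Δt-weighted integral norm divided by the
duration.  Under this norm the stationary trajectory deviation of all
three schemes scales linearly in Δt and the log-log fit of RMSE vs Δt
measures the strong order (≈1 for additive noise; observed 0.95–1.14 on
the stock networks).  A grid-point sum left unweighted by Δt would divide
the stationary deviation by √Δt and bias the measured slope to 0.5.  In
the accuracy harness the implicit-Euler state is advanced by a direct
linear solve of the fixed-point equation, guarded by the exact
contraction condition on the spectral radius of W — this is the value the
production iteration converges to at tolerance 1e−12, at a fraction of
the cost; the scheduler always runs the true iteration, and a test pins
the two paths to each other.

Stock study sizes: both accuracy networks have N = 400 (all-to-all
inhibitory, τ = 1 ms, σ = 10; sparse balanced e/i, p = 0.2, τ = 0.5 ms,
σ = 10), horizons of 200 ms, five halved steps per scheme inside its
stable region.  Empirical stability bounds use 50 ms horizons: detecting
divergence (amplification ≥ 1.03 per step on the binding mode) needs far
less time than that, and the stable-side RMSE is horizon-independent.

## Scheduler and waveform relaxation

Delayed connections decouple the network for the minimal delay d_min;
rates travel through ring buffers indexed by global step (a rate sent at
step k over delay d steps is read exactly at k+d; pre-run history equals
the initial state).  Instantaneous connections contribute
min(d_min, wfr_comm_interval) when WFR is enabled and h otherwise.
Within a WFR interval, sweep m reads the other units' trajectories from
sweep m−1 (iteration 0: the last exchanged rates held constant; explicit
schemes read the previous-sweep value at the step being left, the
implicit bracket at the step being entered) and stops when no rate at any
grid point changes by more than wfr_tol between sweeps — the stricter
all-grid-points reading, so convergence implies trajectory-wide
agreement.  Reported iteration counts include the certifying sweep.
Defaults follow the communication-model convention: use_wfr on,
wfr_comm_interval 1.0 ms, wfr_tol 1e−4, wfr_max_iterations 15 (on
exhaustion a warning is emitted and time advances), omit_initial_input
off (the first interval's network input is computed; the option exists to
mirror simulators whose first exchange happens after the first interval).
wfr_interpolation_order is accepted in configs and ignored — it concerns
gap-junction interpolation, which does not apply to rate dynamics.

## Stability analysis

One update step along an eigenvalue λ of A = −I+W amplifies a
perturbation by ζ_EM = |1+λx|, ζ_EXP = |1+λ(1−e^{−x})| or
ζ_IE = x/(1+x)·|λ+1| (the fixed-point contraction factor), x = Δt/τ.
Because ζ_EM and ζ_IE are monotone in x and ζ_EXP in 1−e^{−x}, the
per-eigenvalue maximal stable x has an exact closed form for complex λ
(EM: 2|Reλ|/|λ|²; EXP and IE by the same algebra on the substituted
variable; unbounded when the criterion holds for all x) — the quantity a
bisection would approximate, computed without iteration error.  Both the
implicit and the scalar exponential Euler are unconditionally stable
exactly for real |λ| ≤ 2 (both ζ limits equal |λ+1|); their step-size
bounds cross at the root of −ln(1−2/v) = 1/(v−2), v ≈ 2.796 (2.8 at the
1-decimal reporting convention used for all printed thresholds).  Random
e/i spectra are computed by dense nonsymmetric eigensolves; the large
sparse-network study uses N = 2000, p = 0.2 and reports the median over
five network realizations (measured EM ratio ≈ 1.10–1.12; the e/i
circular-law estimate is radius √(N·Var w) = 0.8, hence x = 2/1.8 ≈ 1.11).

## Linear covariance theory

For stable linear networks, M = I−W, the stationary covariance solves
MC₀+C₀Mᵀ = σ²I (the Lyapunov route is the normative ground truth; it is
τ-independent).  Lags: c(t) = e^{−Mt/τ}C₀ for t ≥ 0, c(−t) = c(t)ᵀ.  The
eigenmode assembly c(t) = Σᵢⱼ σ²(vⁱ·vʲ)/(λᵢ+λⱼ) uⁱ(uʲ)ᵀ e^{−λᵢt/τ}
(right/left eigenvectors of M, H(t)/H(−t) branches) is validated against
the matrix-exponential form to 1e−10 and falls back to it near-defective
M (eigenvector condition number > 1e12).  The overall scalar prefactor is
anchored by c(0) = C₀ rather than transcribed.  Simulation comparisons
discard a 10τ burn-in.

## Siegert mean field

Population rate: 1/X = τ_r + τ_m√π ∫_{y_r}^{y_θ} e^{u²}(1+erf u) du with
y_V = (V−μ)/σ + γ√(τ_s/τ_m) and boundary-shift constant
γ = |ζ_R(1/2)|/√2 ≈ 1.03265 (ζ_R the Riemann zeta function; exposed as an
overridable parameter for sensitivity checks).  The integrand is
evaluated as erfcx(−u), finite for |u| up to ±40 where the naive form
overflows (u ≳ 26) or cancels (u ≲ −2.5 in double precision); quadrature
is adaptive Gauss–Kronrod, split at u = 0.  σ = 0 uses the deterministic
limit 1/(τ_r+τ_m ln((μ−V_r)/(μ−θ))) above threshold, 0 below.  Input
moments: μ_α = τ_m[Σ_β K_αβ w_αβ X_β + K_ext w_ext X_ext], σ²_α likewise
with w² — diffusion coupling therefore carries separate drift and
variance weights, defaulted to K·w and K·w² and independently
overridable.  Stationary rates relax τ dX = −X+Φ(X) (pseudo-time τ = 1 ms,
h = 0.1 ms, X₀ = 0) with the exponential-Euler stepper; the run stops
when the per-step change is below tol = 1e−10 **and** the residual
|X−Φ(X)| is below 10·tol (with h/τ = 0.1 the change criterion alone
corresponds to a residual of ≈10.5·tol; a constant-Φ map is approached
geometrically, so machine-precision residuals are not reachable in a
bounded number of steps).  Non-convergence within the pseudo-time budget
returns the trajectory (limit cycles are possible).

## Neural field and pattern classification

The ring field τdX(φ) = (−X + [I_ext + ∫(w₀+w₁cos(φ−φ'))X(φ',t−d)dφ']₊)dt
is discretized on N grid points with wᵢⱼ = (2π/N)(w₀+w₁cos(φᵢ−φⱼ)); the
rectification applies to the total input **including** I_ext, realized as
a threshold-linear gain with θ = −I_ext and μ = 0.  Default initial
profile: (π²−φᵢ²)/2.  The classifier works on the post-transient window
(default discard 50τ; the window must exceed 20τ) from m₀(t) = mean
activity and the first spatial Fourier mode m₁(t):

* spatially structured when mean|m₁| > 0.05·mean m₀;
* m₀ oscillating when std/mean > 0.05;
* **amplitude reversals** when min|m₁| < 0.25·mean|m₁| — the nodal
  signature of standing-type states (a breathing but non-reversing bump
  is not a standing wave);
* **phase transport** from the unwrapped phase of m₁: net velocity
  (threshold 2π/(100τ)) and coherence |Σ increments|/Σ|increments|
  (threshold 0.8) separate a coherently rotating mode (traveling) from
  incoherent ±π flips (standing).

Decision order: uniform → stationary/oscillatory by m₀; structured with
reversals → traveling if transport is coherent, else standing; structured
without reversals → traveling if coherently drifting, else stationary
bump.  Constructed calibration fields (constant, static bump, rigid
traveling wave, standing wave, uniform oscillation) are separated with
order-of-magnitude margins.  All thresholds are exposed
(`ClassifierThresholds`).

**Known limitation.**  With the stock parameters (w₀ = −80,
w₁ ∈ {15, 5, −46, −86}, N = 100, d = 0.1 ms, h = 0.01 ms) the effective
mode couplings after the 2π/N discretization are large (uniform mode
2πw₀ ≈ −503, first mode πw₁ up to −270), and the four runs settle into a
pinned mildly breathing bump, a uniform delay-driven oscillation, and two
standing-type alternation states — regular at w₁ = −46, irregular with a
strong mean-field oscillation at w₁ = −86.  No traveling-wave attractor
exists there in this implementation: checks across h ∈ {0.01, 0.005,
0.0025}, N ∈ {100, 200, 400}, symmetric, asymmetric and random initial
profiles and horizons up to 1.5 s found a coherently rotating state at
w₁ = −46 only as a transient that decays by ≈0.6 s into the incoherent
flip state.  The four states are dynamically distinct and their labels
are stable under step refinement and rotated initial conditions, but the
two alternation states share the standing-wave label, so a four-way
label distinctness check over these parameter sets fails; the
corresponding validation test documents this as an unreproduced claim.

## Determinism and configuration

One master seed feeds the block-keyed noise streams; identical
configuration plus seed reproduces every output byte for byte.  Configs
are YAML (JSON accepted) with builder references or inline unit and
connection lists; delays are validated as multiples of h at load time.
Recordings are written as CSV with 17-significant-digit floats (exact
round trip; pandas readers need `float_precision="round_trip"`).
Network sizes, horizons and grids used in the validation studies are the
stock values listed above; the unit-test suite uses smaller instances of
the same constructions where exactness, not scale, is under test.
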