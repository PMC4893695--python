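# Methods

## Model and estimator

The package treats controlled dynamics `dx/dt = f(x) + g(x)u` with fixed
initial state `x0`, state dimension `n` and input dimension `m`.  The
controllability function is the minimum control effort to reach a target at
the horizon, with the **½-energy convention** `L^τ(x_f) = ½ min ∫₀^τ |u|² dt`.
This factor is what makes the chain of identities close exactly: for linear
dynamics `L^τ(x) = ½ x^T G_τ^{-1} x`, the Gibbs density `∝ exp(−L)` is then
the Gaussian `N(0, G_τ)`, and its second moment — the Gibbs Gramian — is
`G_τ` itself.

Under input-channel white noise of level (temperature) `T`,

    dx = f(x) dt + g(x) √T dW_t        (Itô),

the endpoint density of the uncontrolled system is the Gibbs density of the
stochastic controllability function divided by `T`.  The package's central
estimator is therefore the endpoint second moment

    Ĝ = (1/N) Σ_k (x̂_k − c)(x̂_k − c)^T,

with centering `c = 0` by default (matching the second-moment definition;
for a linear system this converges to `T·G_τ`), `c = sample mean` to
measure travelling distance instead of distance from the origin, or any
given reference point.  `GibbsGramianModel.fit()` symmetrises, performs a
PSD repair (eigenvalues in `[−10⁻¹⁰·λ₁, 0)` are clipped to zero; anything
more negative raises a consistency error), reports entrywise Monte-Carlo
standard errors `sd(x_i x_j)/√N`, a sorted eigen-decomposition with a
deterministic sign convention (largest-magnitude component positive), and
the condition number `λ₁/λ_n` (infinite for singular estimates — an
all-identical ensemble yields the zero matrix, not an error).

Pointwise values of `L` itself are recovered only in low dimension
(`n ≤ 3`) via `estimate_ctrl_function`: a Gaussian kernel density estimate
`p̂` of the endpoints gives `L̂(x) = −T log p̂(x)` up to an additive
constant, pinned so the minimum over the query points is zero.  Silverman's
rule is the default bandwidth; smoothing biases the implied variance by
`O(h²)` (≈1–2 % for the N = 50 000 Ornstein–Uhlenbeck fixture), well inside
the 10 % tolerance used in validation.  Queries with density below 1e−300
are masked with a warning rather than raised.

## Simulation

`simulate_noise_response` / `simulate_controlled` use the Euler–Maruyama
scheme: `x_{k+1} = x_k + f(x_k)dt + g(x_k)(u_k dt + √T ΔW_k)`,
`ΔW_k ~ N(0, dt·I_m)`.  The Itô convention is declared for state-dependent
`g`; every bundled system has constant `g`, where the distinction vanishes.
Control effort accumulates as `½ Σ|u_k|² dt`.  All increments come from one
`numpy` PCG64 generator seeded by the config seed, so identical arguments
reproduce ensembles bit-identically.  A path whose state exceeds 1e6 in
magnitude (or goes non-finite) aborts the run with the path index and time.
No higher-order or adaptive schemes are provided; weak `O(dt)` bias is the
price, and validation budgets for it explicitly (e.g. the 5-standard-error
linear checks use dt = 0.002–0.005 so the Euler bias stays below the
Monte-Carlo band).  Trajectory storage can be thinned (`save_every`) for
pooled-snapshot analyses without holding every step in memory.

## Linear oracles

`finite_horizon_gramian` evaluates `G_τ` by Van Loan's block
matrix-exponential method and cross-checks it against RK45 integration of
the differential Lyapunov equation (1e−6 relative agreement enforced at run
time; tests verify 1e−8 on random stable systems).  On top of it sit the
minimum-energy controllability function `½ d^T G_τ^{-1} d` with
`d = x_f − e^{Aτ}x0` (the free response is the zero-effort reference), the
open-loop minimum-energy input `u(t) = B^T e^{A^T(τ−t)} G_τ^{-1} d`, and
the exact noise-response moments (mean `e^{Aτ}x0`, covariance `T·G_τ`).
Gramians with condition number above 1e12 are treated as singular: the
error carries an explicit null-space basis of unreachable directions.

## Model reduction

`pod_basis` takes the top-`k` sign-fixed eigenvectors — the maximiser of
`Trace(ρ^T G ρ)` over the Stiefel manifold `Π_k`.  `projection_error`
returns both the mean squared residual `(1/N)Σ‖(I−ρρ^T)x_k‖²` and the
algebraically identical trace form `Trace((I−ρρ^T)M̂)`; the two must agree
to 1e−10, which is the sample-level statement of the
projection-error/Gramian identity.  `galerkin_reduce` builds
`dz/dt = ρ^T f(ρz)`, `ρ^T g(ρz)`, `z0 = ρ^T x0` with the lifting map
attached; for linear systems this is `(ρ^TAρ, ρ^TB)`.  With a degenerate
spectrum (`λ_k = λ_{k+1}`) the basis is defined only as a subspace; ties
break by eigen-solver order and subspace-level comparisons use principal
angles.  Snapshots default to single-horizon endpoints; multi-time
snapshot matrices can be stacked and fed to `pod_basis_from_snapshots`
(method of snapshots).

## The FitzHugh–Nagumo benchmark

`fhn_benchmark_spec` builds `p = 4` identical neurons,

    dv_i/dt = v_i − v_i³/3 − w_i + I + Σ_j η_ij (v_j − v_i) + b_i u
    dw_i/dt = ε (v_i + a − b w_i),

with `a = 0.7`, `b = 0.8`, `ε = 0.08`, `I = 0.8` (oscillatory regime;
limit-cycle period ≈ 36.5 time units), couplings `η₁₂ = η₃₄ = 0.1`,
`η₂₃ = 0.005`, a common scalar input into every voltage equation
(`b_i = 1`, so `m = 1`), and initial states `v₁(0) = −v₃(0) = [−1, 0]`,
`v₂(0) = −v₄(0) = [0, 2]`.  All constants are overridable through
`FHNParams` / `FHNNetworkSpec`.  Diffusive coupling acts on the voltage
coordinate only, the standard electrical-coupling convention.

Study conditions for `run_fhn_experiment`: `N = 1000` noise-response paths
per noise level (`T_L = 0.05²`, `T_H = 0.5²`), Euler step `dt = 0.005`,
horizon `τ = 120`.  The horizon is calibrated on the noise-free dynamics:
strong-coupling pair synchronisation completes around `t ≈ 60–80` with
these constants, so `τ = 120` (about three limit-cycle periods) leaves it
well finished before the endpoint, while the weak inter-pair coupling
(time constant of order `1/(2η₂₃) = 100` and practically never converging
deterministically) keeps the pairs apart at `T_L` over any horizon.
Shorter horizons (e.g. one period) sample the endpoint before
synchronisation completes and blur the block structure of the leading
eigenvectors.

Analysis steps:

* **Eigen ratios** `λ_i/λ_1` of the endpoint Gramian; two dominant modes at
  both noise levels (`λ_i/λ_1 ≈ 0.10–0.13 at worst for i ≥ 3`).
* **Block correlation**: each leading eigenvector splits into `p`
  two-component per-neuron blocks; for each neuron the blocks of `e₁, e₂`
  are concatenated, normalised, and compared by absolute cosine similarity.
  Verdicts: similar ≥ 0.9, dissimilar ≤ 0.5, otherwise indeterminate
  (reported without a verdict).
* **Synchronisation metrics**: on a separate 32-path full-trajectory
  sub-ensemble, each pairwise difference signal (`v_i − v_j`, `w_i − w_j`)
  is summarised by its RMS over a sliding window of one limit-cycle period
  and the first time that windowed RMS drops below 10 % of its initial
  value (infinite if never); the ensemble median is reported.  The window
  length matters: windows much shorter than a period track the within-cycle
  zero crossings of an oscillatory difference signal and report spurious
  decays during transients.
* **Dominant-subspace check**: principal angles between `span(e₁, e₂)` and
  a reference basis of block-replicated synchronisation patterns (shared
  v-indicator and w-indicator per group of mutually "similar" neurons).

A pooled-snapshot variant of the Gramian (thinned trajectories instead of
endpoints) is available; it mixes the transient into the estimate and
produces a heavier eigenvalue tail, so the endpoint estimator is the
default.

## What the synthetic data does and does not show

Every validation input is generated by the package itself: linear/OU
systems with closed-form moments, and the FitzHugh–Nagumo network.  The
linear fixtures validate the estimator exactly (the Gibbs Gramian *equals*
`T·G_τ` there); the FHN benchmark validates the nonlinear story only at the
structural level — eigenvalue dominance, block alignment, synchronisation
orderings — since no closed form exists.  Passing tests therefore show the
estimator is correct and the qualitative phenomenology is robust across
seeds; they do not show that 1000 paths suffice for any particular real
network, that the Euler scheme is adequate for stiff dynamics, or that the
two-mode dominance generalises beyond this coupling topology.  Density
estimation of the controllability landscape is limited to `n ≤ 3` by
construction; the Gramian route is the scalable summary.

## Numerical choices

* PSD repair threshold `−10⁻¹⁰·λ₁`; symmetry tolerances 1e−9 (inputs) /
  1e−12 (invariants); orthonormality 1e−10.
* Divergence guard `|x| > 10⁶`; Gramian singularity at condition number
  `10¹²`.
* Eigenvector sign: largest-magnitude component positive, for reproducible
  reports.
* Default Euler step `dt = 0.005` for FHN runs; `τ/dt` must be integral to
  1e−9 relative.
* Monte-Carlo assertions use measured per-entry standard errors plus an
  explicit ~1 % allowance for Euler bias where dt is not refined away.

## Known limitations

No observability/balanced truncation, no importance sampling for
high-dimensional endpoint densities, no nonlinear (manifold) projections,
no Milstein/adaptive SDE schemes, and no synthesis of optimal feedback laws
for nonlinear systems — the package quantifies controllability and reduces
models; it does not solve the optimal control problem.
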