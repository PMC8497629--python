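# Methods

## Model and conventions

The teacher is a fully connected Hopfield model: P patterns
`ζ^μ ∈ {−1,+1}^N` drawn i.i.d. uniform, Hebbian coupling
`J*_ij = N⁻¹ Σ_μ ζ^μ_i ζ^μ_j` (diagonal `J*_ii = P/N` kept in stored
matrices), Hamiltonian `H(s) = −½ Σ_ij J_ij s_i s_j` with the full double
sum, and Boltzmann weight `e^{−βH}`.  There are no external fields.  The
student knows β; only the M×N sample matrix is observable.

Solvers receive the coupling with its diagonal and decide inclusion
themselves: the naive-parallel TAP update sums over all j (as its update
rule is written), parallel AMP excludes j = i, and the Glauber sampler
excludes the self-term from the local field (it would shift both spin
states equally).

All randomness flows through explicit `numpy.random.Generator` objects;
no function touches global RNG state.

## Sampling protocol

"Equilibrium configurations, states equally sampled" is operationalized
as: one fresh chain per recorded sample, initialized at teacher pattern
`a mod P`, evolved for 100 full sequential heat-bath sweeps
(`P(s_i=+1) = [1+e^{−2βh_i}]⁻¹`), final configuration recorded.  Fresh
chains make samples exactly independent, matching the i.i.d. form of the
likelihood; 100 sweeps at β = 2 from a pattern start is far beyond the
relaxation time inside a retrieval basin (the basin is left with
probability exponentially small in N).  Per-state counts differ by at
most one when P does not divide M.  The sweep kernel is numba-compiled
with incremental local-field updates; uniforms are pre-drawn in numpy so
results are bit-reproducible given the seed.

At N ≤ 10 the sampler is validated against exhaustive enumeration of the
Boltzmann distribution: χ² over all states at 10⁶ recorded sweeps
(recorded every 2nd sweep after burn-in, so that records are effectively
independent at the tested temperature), plus pair-correlation and
energy-average checks.

## Solvers

Three schemes iterate the mean-field self-consistency for the local
magnetizations; `alpha` is the load of the model being solved — P/N in
the direct problem, M/N on the dual/posterior problem, where the M
samples play the role of patterns.

* **TAP (naive parallel).**  All sites updated synchronously;
  `q = mean(m²)` recomputed each step.  The Onsager denominator
  `1 − β(1−q)` is singular on the shell q = 1 − 1/β; parallel updates
  jump across it, and the iteration raises a numerical-singularity error
  only if a step lands within 10⁻⁸ of it.
* **AMP (parallel).**  The belief-propagation time indexing with cavity
  fields H and memory `u = β(1−q)`.  Bootstrap at t = 0: `m^{−1} = 0`,
  `u^{−1} = β`, `H⁰ = arctanh(m⁰)/β` with |m⁰| clipped to 1−10⁻¹²
  (magnitude-1 initial conditions are standard for the direct problem).
* **Sequential damped AMP.**  The literal sequential iteration of the
  parallel AMP recursion is ill-posed: slow (damped) trajectories cross
  u = 1, where the recursion factor |u/(1−u)| exceeds 1 and the cavity
  fields diverge geometrically while tanh saturates, so the stopping
  statistic mean|Δ tanh βH| reports convergence onto junk states.  This
  package therefore iterates the AMP *fixed-point* equations
  (`H_i = Σ_{j≠i} J_ij m_j − [αu/(1−u)] m_i`) site by site with the
  damped mixing rule `m_i ← (1−d) tanh(βH_i) + d m_i`, d = 0.95, u
  refreshed once per sweep.  The transient Onsager ratio u/(1−u) is
  clamped to ±10: at any fixed point the ratio is small and the clamp
  inactive, but without it quasi-static trajectories orbit the singular
  shell indefinitely.  With this scheme the sequential solver retrieves
  patterns throughout the deep retrieval phase, roughly 5–10× slower (in
  sweeps) than parallel TAP, and settles in the paramagnet below
  threshold — the reported phenomenology.
* **Dynamical-TAP.**  The single-instance dynamical mean-field scheme
  with memory field z and `A_t = β/(1+αu_t)`; at α = 0 and zero coupling
  diagonal it reduces exactly to `m' = tanh(βJm)`.  Its linear stability
  matches TAP's.  Initial magnetizations must be small at low
  temperature; 0.1 is the default used in the convergence experiments.

Iterations stop when mean|m^{t+1} − m^t| < 10⁻³ (the sequential solver
monitors tanh βH instead); `max_iter` defaults to 2000 and
non-convergence is flagged, never raised.  Stability thresholds are
computed spectrally: 1/λ_max for TAP/dynamical-TAP (∞ if λ_max ≤ 0),
1/(1 + max_λ|λ−1|) for AMP — 1/2 on a Hebbian coupling in the small-load
limit, smaller than 1/2 only when λ_max > 2 (the dual problem with strong
signal, where parallel AMP becomes usable).

## Deflation pipeline

Round τ: P′ students iterate TAP on `J^τ` from `|m_i| ~ U[0.1, 1]` with
random signs; converged students are scored with `S = Σ_a (s^a·m)²`
(equal to the printed double sum; computed via projections); the best
score wins (ties within 10⁻⁹ go to the lower student index);
`J^{τ+1} = J^τ − (γ/N) m^τ (m^τ)ᵀ`.  The loop ends at `max_rounds`
(default P′), when the best converged score drops below 10⁻³·N·M, or when
no student converges.  γ = M/P when the pattern count is known; the
"auto" mode runs a provisional pass with γ = M/P′, reads the kink round
τ*, and reruns with γ = M/τ*.

`kink_stop` declares the kink at the first round whose next increment of
L̂ falls below κ = 0.2 times the median of the increments seen so far (a
flat series kinks immediately; κ is configurable).  On clean runs the
kink coincides with the round where the score collapses from one
cluster's worth of data fit to noise level.

The reconstruction error compares `J_rec = N⁻¹ Σ_{t≤τ} m^t (m^t)ᵀ`
(weight 1 per retrieved pattern, as the teacher's Hebbian matrix) with
`J*` over off-diagonal pairs.  The operative definition is the relative
Frobenius form `√(Σ_{i<j} ΔJ² / Σ_{i<j} J*²)`; an optional flag restores
the literal `[N(N−1)/2]⁻¹` prefactor, which squeezes every value to
~10⁻⁶ at N = 1000 and is useless for comparison — the relative form is
the scale on which the error curves are O(1).

Known limitation: the first deflation rounds' TAP fixed points can carry
a few site flips relative to the exact pattern, caused by interference
from the not-yet-deflated states (relative amplitude ~√(P/N),
independent of M; the flips disappear in later rounds as interferers are
removed, and every student converging to a given state finds the same
flipped fixed point, so more students do not help).  At N = 1000, P = 20
this floors the relative reconstruction error at a few times 10⁻² even
for large M, while pattern identification (overlap ≈ 1) is unaffected.

Evaluation against a known teacher resolves the sign/permutation gauge
greedily: pairs are assigned in descending |N⁻¹ Σ m_i ζ_i|, each teacher
pattern used at most once; `n_recovered` counts matches above the 0.7
overlap threshold that excludes mixture states (a two-pattern mixture
scores ≈ 1/√2 ≈ 0.71 against each constituent, so thresholds ≥ 0.9 are
used when mixtures must be ruled out explicitly).

## RBM

Binary visible units, standard-normal hidden units, energy
`−Σ W_i^μ s_i λ_μ`, no biases (the underlying Hopfield model has none).
Conditionals: `λ | s ~ N(Ws, I)`; `P(s_i=+1|λ) = e^{h_i}/(2cosh h_i)`
with `h = Wᵀλ`.  Training is persistent contrastive divergence with 10
alternating-Gibbs steps, minibatch 100, 100 persistent chains (one per
minibatch sample) initialized uniformly at random.  The positive phase
uses the exact Gaussian conditional mean `E[λ|s] = Ws` (the gradient's
hidden average in closed form); the negative phase advances the chains
and likewise uses `W s_chain` in place of a sampled λ — identical in
expectation, lower variance.

Unstated training constants are this package's choices: learning rate
10⁻³ (gradient entries are O(√(βN)) for Gaussian hidden units, and 10⁻²
diverges outright at N = 1000 — a guard raises once any |W| > 10³),
weight init i.i.d. N(0, (0.01/√N_v)²), epoch cap 500.  Training stops
when the pseudo-likelihood flattens: the gain of the trailing 20-epoch
window mean over the previous window below 0.2% of the total improvement
so far.  The raw per-epoch pseudo-likelihood carries the one-draw Monte
Carlo noise of its estimator, which is why window means rather than
local slopes are compared.

The pseudo-likelihood `𝒮 = Σ_r M⁻¹ Σ_a log[e^{s_r h_r}/(2cosh h_r)]`
draws one hidden vector per sample from the exact conditional; the
estimator's expectation is the conditional-log-likelihood average
(verified against 1-D Gaussian quadrature in the tests).  It is ≤ 0 and
equals −N_v log 2 at W = 0.

Diagnostics: `β⁻¹WᵀW` is compared to `J*` with the same error metric
(invariant under hidden-space rotations of W, which is also why the RBM
cannot identify individual patterns); the data modes `u^{(α),D}` from the
SVD of the N×M sample matrix are projected on the left singular vectors
of `Wᵀ`, and `t_α = Σ_i|e^α_i| / Σ_i|u^{(α),D}_i|` measures what the
weight subspace misses of data mode α.  "Emerged" singular values are
those exceeding 3× the median of the trailing max(2, N_h//3) singular
values; with 15 hidden units on 10-pattern data the trailing 5 are the
bulk and exactly P modes emerge at the flattening stop.

## Orthogonality penalty

For two patterns at mutual overlap q the posterior's partition-function
term factorizes into Curie–Weiss blocks at β(1±q) over the sites where
the patterns agree/disagree.  The per-spin, per-sample penalty is

    φ(q) = (1+q)/2 · a(β(1+q)) + (1−q)/2 · a(β(1−q)),

with `a(β) = lim N⁻¹ log Z = max_m [log 2cosh(βm) − βm²/2]` the
Curie–Weiss log-partition, solved by bracketed root-finding of
m = tanh(βm).  φ is convex with its minimum at q = 0 — the soft
orthogonality regularizer.  The sign convention matters: building the
combination from the conventional free energy f = −a/β instead (in
either dimension convention) moves the minimum away from q = 0, so the
log-partition form is the operative one; `curie_weiss_free_energy`
(−log 2/β in the paramagnet, −1/2 as β→∞) is exposed separately for
thermodynamic use.  Convexity and the q = 0 minimum are verified
numerically on 0.01 grids at several temperatures.

## Problem sizes and determinism

Module tests run at N = 10–400 with exhaustive-enumeration or scalar
fixed-point oracles; the end-to-end checks run the full study conditions
(N = 1000 teachers, M up to 1000, 25 students, 15 hidden units), which
keeps the complete suite at a few minutes on one CPU.  Experiment
recipes default to the full conditions and expose a `--scale` factor
that shrinks N, M and trial counts proportionally (floored so phases
remain recognizable).  Identical configuration and seed give
byte-identical outputs.
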