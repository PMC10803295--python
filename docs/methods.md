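# Methods

## The model

`histddm` implements a family of accumulation-to-bound models of
two-alternative forced choice in which the accumulator's *initial
state* is updated from trial history, so that a single mechanism
produces both history biases and apparent lapses.

### Across trials: exponential history filters

Each choice-outcome pair h ∈ {Rw, Lw, Rl, Ll} has its own filter with
increment η^h and decay β^h ∈ [0, 1):

    i^h(n) = β^h i^h(n−1) + η^h 1[o_{n−1} = h],
    I(n)   = Σ_h i^h(n).

Positive I favors the rightward bound. Violation trials (no choice or
outcome) freeze the filters by default — they carry no history signal —
with a decay-only alternative behind a flag, since the data never pin
this down. Three tying schemes are provided: unconstrained (8 free
parameters), an identifiability-constrained form for fixed-duration
data (losses share η and β with a lose-switch sign convention; wins
share β; 5 free), and a 2-parameter reduction with one β and one |η|
signed by the chosen side, the exponential-filter approximation of a
dynamic belief model tracking a prior with unsignaled switches.

### Within a trial: analytic DDM and the click accumulator

For constant drift μ, diffusion variance σ², bounds ±B and start I,
the absorption probability is

    P(B+) = (1 − e^{−2μ(B+I)/σ²}) / (1 − e^{−4μB/σ²}),

a logistic function of μB/σ² only when I = 0; |μB/σ²| < 1e−8 is
replaced by the limit (B+I)/(2B). Pooling choices over
history-distributed I yields a heavy-tailed psychometric whose
4-parameter logistic fit shows nonzero asymptotes — apparent lapses.

For pulsatile (Poisson-click) evidence the accumulator follows

    dx = λx dt + (ε_R C_R ξ_R − ε_L C_L ξ_L) dt + σ_a dW,  x(0) = I(n),

with sticky bounds (dx = 0 once |x| ≥ B), per-click sensory noise
ξ ~ N(1, σ_s²) (a click of adapted magnitude C therefore injects mean
±C and variance C²σ_s²), and sensory adaptation
dC/dt = (1−C)/τ_ϕ + (ϕ−1)C(ε_R+ε_L): each click reports the state just
before its own jump, then multiplies it by ϕ; C(0) = 1 (fully
recovered at stimulus onset — the pre-stimulus gap is long relative to
τ_ϕ). A rightward choice is made if x(T) > bias; mass exactly at the
bias counts half, by symmetry.

### True lapses and the mixture

On a fraction κ of trials the choice bypasses accumulation: motor
error/exploration (P(R) = ρ, history-independent), inattention (choose
the side favored by I relative to a criterion ρ; 0.5 at ties), or a
hybrid logistic in m(I−ρ). Observed choice probability is the
κ-mixture. Note the two meanings of ρ: a probability for the motor
variant, a criterion in accumulator units for the others.

### Reaction times

RT = bound-hitting time + non-decision time (NDT). NDTs are Wald
(inverse Gaussian) draws with per-side bound ω_k and drift
ν_k − αn + γ_o·1⁻ (trial number n; 1⁻ = previous trial was an error;
γ_o < 0 reproduces post-error slowing). The joint (choice, RT)
likelihood marginalizes the first-passage density over hitting times
τ ≤ RT convolved with the NDT density at RT − τ (midpoint rule on the
solver's time bins); on lapse trials the RT is NDT alone. Mass still
unabsorbed at a horizon is treated as censored: it simply never enters
a per-trial likelihood, so the joint density integrates to 1 minus the
survivor mass (the normalization checks use fixtures where the
survivor is negligible).

## Numerics

The choice likelihood needs P(x(t)), evolved on a spatial grid of
n_bins interior bins (odd, default 201) spanning [−B, B] plus two
sticky absorbing bins, with transition step dt (default 2 ms).

- **Transitions.** Each step moves every bin's mass through a Gaussian
  whose mean integrates the linear drift exactly
  (x e^{λΔt} + drift·(e^{λΔt}−1)/λ) and whose variance is
  σ_a²(e^{2λΔt}−1)/(2λ). Mass is distributed by Gaussian-smoothed
  linear interpolation: node j receives ∫N(x; m, s²)hat_j(x)dx,
  computed as the second difference of E(a) = (a−m)Φ(z) + sφ(z). This
  is exactly mass-conserving and mean-preserving and degrades
  gracefully to two-node interpolation as s → 0, so deterministic
  limits are not numerically frozen. Because hat distribution is a
  convolution with a triangular kernel of variance dx²/6, that amount
  is subtracted from the requested variance; repeated applications
  then add no spurious diffusion.
- **Boundary crossing.** End-of-step absorption alone undercounts
  first passages by O(√Δt). A Brownian-bridge correction reassigns to
  the bounds the within-step crossing probability
  exp(−2(B−x₀)(B−x₁)/σ²Δt) of mass ending in the interior. The same
  correction is applied in every forward simulator (the analytic-DDM
  sampler, the particle reference, the generative session kernel), so
  solvers and samplers approximate the same continuous-time process.
  With it, the constant-drift first-passage masses agree with the
  closed-form two-boundary series to ~1e−6 sup-norm at the default
  grid.
- **Clicks.** Clicks are assigned to the transition step containing
  them; those in the first half of a step apply before the step's
  drift/diffusion substep, centering the time-quantization error.
  Clicks in one step apply sequentially in time order (left before
  right at exact ties, matching the adaptation pass). Click inputs are
  x-independent, so the batched engine applies them as displacement
  kernels rather than full matrices; the batched and per-trial solvers
  agree to round-off by construction, which is tested.
- **Deterministic limits.** With ϕ = 1, σ_s = σ_a = 0, λ = 0 the model
  reduces to click counting; on a grid commensurate with the click
  magnitude the solver reproduces the counting rule exactly.

Fitting uses bounded Nelder–Mead with seeded multi-start (neutral
defaults plus perturbations within box bounds — B ∈ (0.5, 10],
λ ∈ [−5, 5] s⁻¹, κ ∈ [0, 0.5], β ∈ [0, 0.999], all configurable).
Models are compared by per-trial BIC, (k ln N − 2 ln L)/N. Fits at
desk scale use a reduced grid (51 bins, 10 ms steps); the convergence
study above bounds the induced likelihood error.

## The synthetic-data generator

The generator emulates the Poisson-clicks task family: two independent
homogeneous Poisson click streams whose rates sum to 40 Hz, difficulty
set by the rate ratio (default levels 39:1, 31:9, 26:14, 22:18 and
mirrors; the real task's levels are not published, so these follow the
task family's convention and are configurable), rewarded side by
realized count (fixed-duration mode, ties at random) or generative
rate (reaction-time mode). Stimulus durations are uniform on
[0.2, 1.0] s by default.

The default generative agent was chosen once to look like a well-
trained rat: accuracy ≈ 0.79 at the defaults (λ = 0, σ_a² = 7 /s,
σ_s² = 0.2, B = 2.5, ϕ = 0.35, τ_ϕ = 0.1 s, bias = 0), moderate
win-stay/lose-switch history updating (η^Rw = 0.8, η^Lw = −0.8,
β^win = 0.55, lose-switch magnitude 0.35, β^loss = 0.35; initial-state
SD ≈ 0.9, repeat probability after wins ≈ 0.57), κ = 0.08 motor lapses
at ρ = 0.5, and NDTs with mean ≈ 0.15 s and post-error slowing
(ω = 1.5, ν = 10, γ_o = −1). The noise budget leans on accumulator
rather than per-click sensory noise; both regimes fit the observed
accuracy and the split is not separately constrained here.

The agent is simulated closed loop (its realized choices feed its own
filters) by Euler–Maruyama at 1 ms with the bridge correction, so the
generator and the likelihood engine describe the same process — the
recovery and model-selection harnesses depend on exactly this
consistency. Hidden ground truth (initial states, lapse flags,
decision times) is returned separately and written to a sidecar file,
never into the session CSV.

What the generator does *not* emulate: violation-rate dynamics,
satiation or attention drifts beyond the NDT trial-number term,
session-boundary nonstationarities, across-trial drift-rate
variability. Passing tests therefore demonstrate internal consistency
and statistical power at these conditions, not robustness to the many
ways real sessions are messier.

## Problem sizes in the shipped tests and acceptance script

All stochastic checks run at desk scale with fixed seeds: 8×10⁴
simulation paths per point for the analytic oracle grid, 4–5×10⁴
particles per trial for the Fokker–Planck cross-checks, 2×10⁴-trial
closed-loop sessions for apparent-lapse emergence, 20 agents × 6000
trials for the comodulation pattern, 10 seeds × 4000-trial sessions
for parameter recovery (5 free parameters, others pinned at their
generative values), 10 + 10 agents × 2000 trials for BIC model
selection, and 8000-trial reaction-time sessions for the RT
signatures. The acceptance script re-runs the same computations at
somewhat smaller sizes. These sizes are the package's choice of a
well-powered but quick experiment at each condition; the underlying
code paths are size-agnostic.

## Known limitations

- The Fokker–Planck grid must keep per-step diffusion SD comparable to
  or larger than the bin width; very small σ_a with large n_bins
  degrades (the variance compensation then clips at zero).
- The reaction-time likelihood loops trials in Python; joint fits are
  practical for exploratory use but have not been optimized like the
  choice-only batched path.
- The inattention lapse variant has a discontinuous likelihood in ρ at
  ties; the hybrid variant is the smooth surrogate and is what the
  optimizer should be given when ρ is free.
- Accuracy of the per-side session filter reading: per-side accuracy
  is computed over trials whose *correct* answer is that side; a flag
  would be needed to switch to a per-chosen-side reading.
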