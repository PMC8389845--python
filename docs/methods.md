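# Methods

## Models

### Posterior-utility-choice (PUC)

The agent treats the value of each item as a latent variable v and holds a
Gaussian belief over it. Time is discretized in 100 ms steps; each step of
fixation on an item yields one measurement x ~ N(v, σ²) of *that item only*
(the unfixated item receives no information). With a prior N(μ_p, σ_p²) and
T measurements of mean x̄, conjugacy gives

    μ_post = (μ_p/σ_p² + T·x̄/σ²) · κ_T⁻¹,   σ_post = κ_T^(-1/2),
    κ_T = 1/σ_p² + T/σ².

Utility is U = μ_post − A·σ_post. The default uncertainty penalty is the
posterior standard deviation; an optional threshold utility
U = Φ((μ_post − v_crit)/σ_post) is available for loss-domain exploration
(configuration `utility="threshold"`). The decision variable
DV = U_left − U_right starts at exactly 0 (both items at the prior) and is
absorbed the first time |DV| ≥ B(t) at the end of a step, where
B(t) = B₀·exp(−(t/λ)^k) is a Weibull collapsing bound. The item's "true"
value v used to generate measurements is the subject's own rating of the
item, with no rescaling, and σ is shared by all items of a subject.

Two channels produce the fixation→choice bias: the posterior mean moves
from μ_p toward the rating (multiplicative in the item's value relative to
the prior), and σ_post falls deterministically with looking time (additive,
value-independent). With A = 0 and ratings equal to μ_p both channels are
off and fixation imbalance cannot bias choice — a reduction the test suite
checks exactly.

### aDDM and acbDDM

The attentional drift-diffusion model increments
DV += d·(r_left − θ·r_right) + ε per left-fixation step (mirrored on the
right), ε ~ N(0, σ²), θ ∈ [0, 1]. The bound height is fixed at 1 — the
model has an arbitrary scale, unlike PUC, whose scale is set by the
ratings. The acbDDM replaces the fixed bound with the same Weibull family
as PUC; with k large and λ far beyond the trial horizon it reduces to the
aDDM (checked to 1e-6).

### Shared nuisance components

With probability g a trial is a guess: the choice is uniform and the total
fixation time is drawn from a Weibull fitted once per subject to that
subject's observed total fixation times (maximum likelihood,
`scipy.stats.weibull_min` with location 0, integrated over the 100 ms bins
plus an overflow bin). Fitting the guess-time distribution before
optimization keeps the likelihood well defined during the parameter search,
and the mixture keeps every trial's probability strictly positive (with a
hard floor of 1e-300 on the per-trial likelihood as a last resort). The
non-decision time τ is post-decision looking time: total fixation time =
decision time + τ.

## Likelihood by density propagation

The joint probability of (choice C, total fixation time T_obs) is computed
without simulation. Each trial's fixation series is quantized to the step
grid by cumulative rounding (boundary of fixation j at
round(cumdur_j/step); no drift accumulates over long series; sub-step
series promote to one step), and the DV density is propagated step by step
with boundary truncation; truncated mass per step is the probability of
responding in that 100 ms bin, and the mass surviving the final step is the
single "later decision" bin. The decision bin of an observed trial is
floor((T_obs − τ)/step); the observer is deliberately not constrained to
decide at the end of the series.

*aDDM family (1-D).* Drift and diffusion for a step are combined into one
cell-integrated Gaussian kernel applied by FFT on a 601-point grid spanning
[−1.5, 1.5] (the bound is ≤ 1). The outermost kernel cells integrate to
±∞ and out-of-grid convolution mass is clamped to the edge cells, so each
transition is exactly stochastic — absorbed + surviving probability is 1 to
float rounding, which the suite asserts to 1e-6 over random draws.

*PUC (2-D).* The scalar DV is not Markov: each item's posterior mean
contracts toward its running average at an item-specific, count-dependent
rate. The minimal Markov state is the pair (μ_L, μ_R), so propagation runs
on a 2-D grid. A step measuring item i applies, along that axis only, the
affine map μ → α·μ followed by convolution with N(β·v_i, (β·σ)²), where
α = κ_T/κ_{T+1}, β = (1/σ²)/κ_{T+1} (note α + β = 1). The posterior sds
are deterministic given the counts, so absorption is a region test on the
grid. Before an item's first measurement its axis is an exact delta at
μ_p (μ_p is forced onto the grid). Each axis spans
[min(μ_p, r) − 4σ_p, max(μ_p, r) + 4σ_p] with 301 cells by default: the
posterior mean's marginal spread is below σ_p, so the 4σ_p buffer keeps
edge clamping below ~1e-4.

*Fractional absorption.* Mass in a cell cut by the bound is split by the
exact overlap of a within-cell uniform density with the absorbing region —
a clipped linear ramp in 1-D, and in 2-D the survival function of the sum
of two independent uniforms (trapezoidal), with per-cell widths taken from
the gradient of the utility along each axis (zero during an axis's delta
phase). This makes the truncation error second order in the cell size;
doubling the default grids moves total choice probabilities by < 1e-3, and
propagation matches independent Monte-Carlo simulation of the same step
dynamics within 3 binomial standard errors at 1e5 replicates. With 1 ms
steps, constant drift and a fixed bound, the propagation reproduces the
continuous-time Wiener absorption probability 1/(1+exp(−2vB/σ²)) within
0.01.

Correctness of the 2-D scheme is anchored to the Monte-Carlo oracle in the
test suite; an exact scalar-DV propagation is impossible for PUC precisely
because the DV alone is not a state.

## Fitting

Per subject, maximum likelihood over a box-constrained space mapped to the
unit cube (log-spaced coordinates for σ, d, B₀, k, λ, g; shifted-log for τ;
linear for A and θ). Default boxes: σ ∈ [0.01, 20] rating units,
A ∈ [−10, 10], B₀ ∈ [0.1, 100], k ∈ [0.2, 10], λ ∈ [0.1, 20] s,
g ∈ [1e-4, 0.5], τ ∈ [0, 1000] ms, d ∈ [1e-4, 5], θ ∈ [0, 1].

The two nuisance parameters that do not enter the propagation are profiled
out exactly: the likelihood is piecewise constant in τ (the decision bin is
a floor of (T_obs − τ)/step, so all non-guess trials share a 100 ms plateau
around the true value — τ is only ever identified up to that plateau), so τ
is maximized over a 10 ms candidate grid, and for each candidate the lapse
rate g solves a 1-D concave problem by golden section, vectorized over
candidates. The outer search over the propagation parameters (3 for the
aDDM, 5 otherwise) is two-phase: a Latin-hypercube pool (default 64 points)
is evaluated once and bounded Nelder-Mead (adaptive, with simplex restarts
at the incumbent) is launched from the best `n_starts` (default 20) points.
Derivative-free search suits the plateaued, softly-ridged surface, and the
screening phase avoids the broad spurious basin in which the model
component is negligible and the guessing mixture explains everything.
Propagation results are cached per outer point, so profiling costs one
vectorized pass over the absorption records.

Free-parameter counts are PUC 7 (σ, A, B₀, k, λ, g, τ; prior moments fixed
to the subject's empirical rating mean and standard deviation — the sample
estimator with n−1, both items of every trial pooled), acbDDM 7 (σ, d, θ,
k, λ, g, τ), aDDM 5 (σ, d, θ, g, τ). These counts make PUC and acbDDM
directly comparable (identical penalty terms, so ΔAICc = ΔBIC exactly).
Variants: free σ_p (+1), free μ_p and σ_p (+2), A pinned to zero (−1); the
counts feed AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) and BIC = −2lnL + k·ln n
with n the number of trials (the independent units of the likelihood sum).
Model comparison sums per-subject differences (first model minus second;
lower favors the first) and attaches percentile bootstrap 95% CIs from
10,000 subject-level resamples.

## Synthetic experiments

The generator emulates the study design the models target: 39 subjects ×
95 trials by default, items rated on the integer scale −10…10 (ratings
drawn uniformly; a truncated Gaussian is available), strictly alternating
left/right fixations with durations resampled from a log-normal pool
(median 400 ms, log-sd 0.5; real duration distributions are not published,
so this is a declared stand-in), and choices/total fixation times produced
by running a chosen model forward with per-subject parameters drawn from
declared ranges. The recorded fixation series of a trial is exactly the
series the simulated observer consumed, truncated at decision time + τ, so
refitting sees the same fixations that produced the choice. The PUC
generating prior is each synthetic subject's own empirical rating prior,
matching the fitting convention. Guess trials draw their response time from
a configured Weibull (shape 1.15, scale 1900 ms — median ≈ 1.4 s, mean
≈ 1.9 s, the scale of observed total fixation times). The default
generating ranges were calibrated jointly against two features of the data
the models describe: the total-fixation-time scale and the qualitative
fixation-bias signatures. These pull against each other for the PUC
generator — the last-fixation coupling lives in early decisions, where the
per-fixation uncertainty drop is still steep, so the measurement noise σ
must stay comparable to the prior sd (σ ∈ [5, 8] vs σ_p ≈ 6); with the
bound and collapse ranges chosen to slow decisions as far as the mechanism
allows, generated medians land around 0.8–1.3 s against the reported
≈ 1.4 s, a documented compromise. (With σ much larger than σ_p the times
can be matched exactly, but the uncertainty channel — the model's own
explanation of the fixation bias — is then switched off, which no emulation
of these data should do.) Undecided trials (bound never reached within
60 s) are re-simulated up to a retry cap.

What the generator does *not* emulate: empirical fixation durations are not
state-dependent (real final fixations are interrupted by the decision),
rating pairs are independent across trials rather than drawn from a menu of
70 items, and fixation timing does not react to the decision state (no
active-sampling policy — the models make no prediction about fixation
generation). Passing recovery tests on these data therefore demonstrates
that the fitting pipeline is self-consistent, not that the models are
identifiable on any particular real dataset.

## Problem sizes in the test suite

The suite favors sizes that exercise every claim at desk scale: parameter
recovery uses 8 subjects × 200 trials for the aDDM (core parameters σ, d,
θ must correlate with truth at r ≥ 0.7), and smaller runs for acbDDM
(3 × 120) and PUC (3 × 100, coarse 41-point grid, single-start search)
whose recovery is reported rather than gated — recovery is expected to be
weaker for the more flexible models, whose bound and noise parameters trade
off softly. Monte-Carlo oracle checks use 1e5 replicates at 10 random
parameter settings per family; conservation is checked on 100 random
draws per family.

## Numerical choices and edge cases

- Absorption is checked after each full step; no within-step interpolation
  (consistent with the 100 ms measurement discretization). No check occurs
  before the first step, so the first response bin is always step 1.
- σ for the diffusion models is parameterized per 100 ms step; λ and τ are
  in milliseconds everywhere.
- Degenerate inputs: a subject whose ratings are all identical has no
  empirical prior (error); constant total fixation times degrade the
  guess-time fit to a point mass with a warning; a fixation series shorter
  than half a step quantizes to a single step; an aDDM grid narrower than
  the bound is a configuration error.
- Ties at the bound absorb ("at or beyond"), matching the simulators.
- The PUC left/right exchange symmetry at equal ratings = μ_p is exact only
  when A = 0: with A > 0 an alternating schedule has momentarily unequal
  measurement counts after odd steps, and the deterministic −A·(σ_L − σ_R)
  term biases odd-step absorption toward the first-fixated side. The suite
  therefore checks exact symmetry in the A = 0 reduction and the
  directional uncertainty effect separately.

## Known limitations

- At a few hundred trials per subject the attentional discount θ is only
  weakly identified: its profile log-likelihood is nearly flat over ±0.1
  around the optimum, so true-vs-recovered correlations for θ are
  materially noisier than for σ and d even when the optimizer verifiably
  reaches likelihoods above the generating parameters'. The non-decision
  time τ is identified only up to its 100 ms plateau (all non-guess trials
  share the same decision bin for any τ within one step below the true
  value), and the lapse rate g trades off softly against the noise scale.

- The 2-D PUC propagation costs O(N³) per step; the default 301-point grid
  is accurate to ~5e-4 in total choice probability but fitting-time
  configurations trade resolution for speed (the `FitConfig` grid sizes).
- The threshold utility uses locally-linearized cell widths in the
  fractional absorption; it is exercised by unit tests but not by the
  recovery study.
- Bootstrap CIs are percentile CIs over subjects; with few subjects they
  are themselves noisy (the suite's coverage check runs at 39 subjects).
- Hierarchical (random-effects) model selection across subjects is out of
  scope; comparisons are fixed-effects sums over subjects.
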