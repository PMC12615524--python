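# Methods

`condlearn` models trial-level behaviour in a three-outcome human predictive
learning task built to compare single-cue, deepened- and super-extinction.
This note records the models, the numerical choices, and what the synthetic
data can and cannot show.

## Task and design

Each participant sees 179 trials in five phases: 144 acquisition trials in
context A: (4 blocks of 36; each block presents every cue four times, e.g.
3 A→X + 1 A→Z, 4 C→Y, 4 D→Z, 4 G→X, 4 KL→Y), two 16-trial extinction phases
in context B: (8 blocks of one target trial plus one C→Y trial), a 2-trial
summation test on G in context B:, and one recovery test of A in the novel
context C:. Groups differ only in the extinction target: A alone (control),
A then AB (deepened), AB throughout (super). X and Y are the two reinforced
outcome types, Z is non-reinforcement. Trial order is randomised within
block only, from a single per-participant generator consumed block by block,
so a seed pins the design exactly. Cue and context labels are abstract:
which food image or screen background realises them is cosmetic for the
models, as is the happy/sad-to-X/Y counterbalancing, so neither is
represented.

## Learning models

All three models share the delta rule ΔV = αβ(λ − ΣV), applied separately to
the two outcome dimensions X and Y (λ_k ∈ {0, 1}; both dimensions update on
every trial, with β = β_us on the dimension whose outcome occurred and
β = β_~us otherwise; a per-trial β variant is available behind the
`beta_mode` switch). The "no outcome" option Z never carries strength.

* **Elemental Rescorla–Wagner** (5 parameters: α_ctx, α_cue, β_us, β_~us,
  g). Units are the context plus each cue; the prediction is their summed
  strength; every present unit updates.
* **Configural Rescorla–Wagner** (6: adds α_cfg). Adds one conjunction unit
  per unordered pair of co-present units (a single-cue trial has 3 units,
  a two-cue trial 6), identical pairs mapping to the same unit throughout.
* **Pearce configural** (5: α_pat, β_us, β_~us, d, g). The whole stimulus
  pattern is one configural unit. The prediction is the similarity-weighted
  sum Σ S(c_i, c_j) V_j over every configuration encountered so far, with
  S(a,b) = (n_ab / √(n_a n_b))^d; only the current configuration updates.
  A pattern seen for the first time is registered at zero strength before
  predicting (self-similarity is 1, so registration is numerically neutral
  on that trial).

Strengths start at exactly 0, which forces the uniform prediction on trial
1. The asymptotic fixed points of the simplified two-cue procedure (A+, B+
to asymptote, then the extinction procedure to convergence, test on A) are
computed by iterating the actual update rule with αβ = 0.1 until no strength
moves by more than 1e-10 (cap 10^6 cycles). They reproduce the hand-solved
values — RW: 0 (super), −1/2 (deepened); configural RW: +1/3, −1/3; Pearce
(d = 2): +1/2, −1/4 — i.e. only the configural models leave residual
positive target strength after super-extinction, the basis for predicting
response recovery.

## Response model and fitting

Choice follows a SoftMax over (gV_X, gV_Y, 0); g → 0 gives guessing at 1/3
per option and large g maximisation. The likelihood of a response sequence
is one-step lookahead: the probability for trial n uses learning through
trial n−1, and the state advances on scheduled outcomes, never on observed
responses. The SoftMax is log-sum-exp stabilised (gV can reach ~45).

Per-participant fitting minimises L = −Σ ln P(R_i) with Nelder–Mead from
three starts: the best of 64 scrambled-Sobol samples of the parameter box
(a cheap, reproducible preliminary search), the canonical point (all
parameters 0.1, g = 2), and a uniform random draw. Boxes — learning rates
[0.0001, 0.75], g [0.0001, 15], d [0.0001, 20] — are enforced by an
invertible sigmoidal reparameterisation, so every evaluated vector is
strictly feasible. Convergence: relative tolerance 1e-6 on L, at most 2000
iterations per start; ties between starts break to the lowest start id;
non-convergence is reported, not raised. The trial loops are numba-compiled
(the pure-Python reference implementation is retained and the two are
asserted equal to machine precision in the tests); one fit takes on the
order of 0.1 s, which is what makes the recovery studies below tractable.

## Model comparison

AICc = 2L + 2V + 2V(V+1)/(n−V−1) per participant (n = 179). Akaike weights,
group AIC (Σ over participants of ln(w_model/w_guessing)) and the Dirichlet
summary (α_i = 1 + Σ_j w_ij, P(best_i) = α_i/Σα) are all computed in log
space; a floor of 1e-300 applies only at exponentiation, since deltas of a
few thousand are routine. Pooled AICc is reported under two conventions —
the formula applied to pooled L with V and n scaled by the cohort size, and
the sum of per-participant AICc — because they genuinely differ and no
single pooling convention is canonical. The best-model census breaks ties
in the fixed order guessing < RW < configural RW < Pearce.

## Synthetic cohorts

The generator stands in for the deposited human data: by default 174
participants (58 per group), each with their own design seed and responses
sampled trial-by-trial from a teacher model through the SoftMax
(full three-way categorical sampling; a Bernoulli X/not-X mode exists for
overlaying model traces on response curves). Teacher parameters are either
fixed or drawn uniformly inside each box; ground truth is retained on every
record. Per-participant seeds derive from `SeedSequence((master_seed, i))`.
Recovery studies use the mid-box teacher θ (all learning rates 0.3, g = 5,
and d = 2 for Pearce — d chosen at the value where element–compound
similarity is exactly ½, the canonical worked case, rather than the box
midpoint of 10, which would make configurations nearly orthogonal).

What the generator does not emulate: reaction times, within-deadline
omissions, attention shifts, or any behaviour outside the three response
symbols. Passing recovery tests therefore show the pipeline is correct and
well calibrated on model-generated behaviour, not that the models describe
human learners.

## Known limitations (measured, not assumed)

* **Learning-rate recoverability.** α and β enter the update rule only as
  products, so the likelihood has a ridge: fitted likelihoods are routinely
  *below* the generating parameters' likelihood while individual rates land
  0.15–0.3 away from truth (median, 50 participants at mid-box θ). This is
  a property of 179-trial data, not of the optimiser — heavier optimisation
  (256 coarse samples, 8000 iterations) leaves the medians unchanged — and
  is consistent with the sensitivity analysis: parameters that move L by
  well under 1% for 5% perturbations cannot be pinned tightly. g recovers to
  a median error well under 1 for the RW models, ~1.6 for Pearce.
* **cRW/Pearce mimicry.** In model-recovery cohorts the elemental RW and
  Pearce recover cleanly (mean P(best) 0.43 and 0.57 over 5 seeds), but
  configural-RW-generated cohorts are marginally attributed to Pearce
  (0.38 vs 0.35): the two configural models mimic each other on this design
  at mid-box θ, and AICc's penalty on cRW's sixth parameter tips the
  balance.
* **Inclusion-filter ceiling.** The inclusion test (one-sided rank-sum of
  X-responses on the last 4 cue-A acquisition trials against the last 4
  each of C/D/E; exact midrank permutation over the C(16,4) = 1820
  arrangements, with a normal-approximation option) cannot pass every
  perfect learner: with V_Z ≡ 0 a fully trained model still answers X with
  probability 1/3 on the never-reinforced D/E trials, capping the pass rate
  near 91% (≈78% observed for strong teachers; 0–3% for guessers). The
  ~16% exclusion the filter produces for strong learners is in the same
  regime as the human study's 33/207.
* **Sensitivity at box edges.** When fitted g sits at its ceiling, upward
  perturbations clip and its one-sided sensitivity halves; cohort-averaged
  sensitivity (used in the tests) restores the expected ordering: g most
  important, β_us more important than β_~us.

## Problem sizes

The test suite's recovery studies use the sizes stated above: 50
participants per model for parameter recovery, three 60-participant cohorts
per seed for five seeds for model recovery, 9-participant fitted cohorts for
sensitivity, 250 simulated participants per cell for the recovery-excess
contrast. `scripts/acceptance.py` recomputes the analytic quantities
exactly and the stochastic ones at 20–200 participants per quantity.
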