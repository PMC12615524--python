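# condlearn

Trial-by-trial associative-learning models of compound-cue extinction.

Cue-exposure treatments try to extinguish conditioned responses, but
extinguished responding often recovers outside the extinction context.
Two compound-cue procedures have been proposed to deepen extinction by
enlarging prediction error: **super-extinction** (extinguish the target A in
compound with a second excitor B from the outset) and **deepened-extinction**
(extinguish A alone first, then in compound with B). Whether these help — and
which learning model explains what happens — is an open empirical question.
`condlearn` is for researchers in associative learning and computational
modelling of behaviour who want to simulate, fit and compare the three
standard error-correction accounts of such designs at the level of
individual trials and participants.

## What it implements

* The full three-group, five-phase, 179-trial design (acquisition,
  two extinction phases, summation test, recovery test in a novel context),
  with seeded within-block randomisation.
* Three learning rules sharing the delta rule ΔV = αβ(λ − ΣV):
  * elemental **Rescorla–Wagner** — context and cue units sum and update;
  * **configural Rescorla–Wagner** — adds a conjunction unit per pair of
    co-present units;
  * **Pearce configural** — whole stimulus patterns are the associative
    units, generalising by S(a,b) = (n_ab/√(n_a n_b))^d; only the current
    pattern updates.
* A SoftMax response map P(R) = exp(gV_R)/Σ_k exp(gV_k) over the three
  response options (V_Z ≡ 0) and the one-step-lookahead sequence likelihood
  L = −Σ ln P(R_i).
* Per-participant constrained maximum-likelihood fitting (three-start
  Nelder–Mead inside the parameter boxes) exposed as scikit-learn style
  estimators, plus a zero-parameter uniform-guessing baseline.
* Model comparison: AICc, Akaike weights, group AIC against the guessing
  baseline, Dirichlet P(best) and a best-model census — all in log space.
* A synthetic-cohort generator (174 participants, 58 per group, by default)
  with retained ground truth, an acquisition-performance inclusion filter
  (exact midrank permutation rank-sum), response curves, recovery/summation
  summaries, and one-at-a-time likelihood sensitivity analysis.

See `docs/methods.md` for the models, numerical choices and measured
limitations.

## Worked example

```python
import condlearn as cl

# one super-extinction participant whose behaviour follows a Pearce teacher
design = cl.build_design("super", seed=7)
theta = {"alpha_pat": 0.3, "beta_us": 0.3, "beta_nous": 0.3, "d": 2.0, "g": 5.0}
responses = cl.simulate_responses("pearce", theta, design, seed=7)

est = cl.PearceConfigural(random_state=0).fit(design, responses)
print(round(est.nll_, 2))                    # 126.01
print({k: round(v, 3) for k, v in est.theta_.items()})
# {'alpha_pat': 0.127, 'beta_us': 0.636, 'beta_nous': 0.749, 'd': 1.896, 'g': 5.518}
print(est.predict_proba(design)[-1].round(3))  # [0.494 0.218 0.288]
```

The fitted likelihood 126.01 sits far below the guessing bound
179 ln 3 ≈ 196.65, so this participant is much better described as a Pearce
learner than a guesser (the fitted per-trial probability of the observed
response averages e^(−126/179) ≈ 0.49 against 1/3 for guessing). Individual
parameters trade off along the αβ ridge — the likelihood, not each
parameter, is what the data pin down. The last line is the model's response
distribution on the recovery test: it still predicts X almost half the time
after super-extinction, the residual-strength signature that separates the
configural models from elemental Rescorla–Wagner (whose target strength goes
to zero).

A whole study runs through the pipeline:

```python
report = cl.run_full_pipeline({
    "cohort": {"group_sizes": {"control": 10, "deepened": 10, "super": 10},
               "model": "pearce", "theta": theta},
    "seed": 1,
    "outdir": "out",
})
print(report["comparison_overall"][["model", "AICc_sum", "P_best"]])
```

or from the shell: `condlearn simulate … | condlearn fit … | condlearn
compare …`, and `condlearn pipeline --config config.yaml`.

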