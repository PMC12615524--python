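"""Corrected-AIC model comparison across participants.

Given per-participant minimised likelihoods for each candidate model
(including the zero-parameter guessing baseline), this module computes

* small-sample-corrected AIC: ``AICc = 2L + 2V + 2V(V+1)/(n - V - 1)``,
* Akaike weights ``w_i = exp(-Delta_i/2) / sum_k exp(-Delta_k/2)``,
* the group AIC — the product over participants of each model's weight
  ratio against the baseline, reported on the log scale,
* a Dirichlet summary: ``alpha_i = 1 + sum_j w_ij`` and
  ``P(best_i) = alpha_i / sum alpha``, the probability that model i is best
  for a randomly chosen participant,
* a best-model census (argmin AICc per participant).

Deltas of a few thousand make ``exp(-Delta/2)`` underflow, so weights and
group AIC are computed in log space; a floor of 1e-300 is applied only when
exponentiating for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

WEIGHT_FLOOR = 1e-300


def aicc(L: float, V: int, n: int) -> float:
    """Corrected Akaike information criterion from a minimised -log L."""
    if n <= V + 1:
        raise ValueError(f"AICc undefined for n={n} <= V+1={V + 1}")
    return 2.0 * L + 2.0 * V + 2.0 * V * (V + 1) / (n - V - 1)


def log_akaike_weights(aicc_values) -> np.ndarray:
    values = np.asarray(aicc_values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
        squeeze = True
    else:
        squeeze = False
    half_delta = -0.5 * (values - values.min(axis=1, keepdims=True))
    logw = half_delta - logsumexp(half_delta, axis=1, keepdims=True)
    return logw[0] if squeeze else logw


def akaike_weights(aicc_values) -> np.ndarray:
    """Evidence weights from AICc values; rows sum to 1."""
    return np.exp(np.maximum(log_akaike_weights(aicc_values), np.log(WEIGHT_FLOOR)))


def group_aic(weights, baseline: int = 0, log_input: bool = False) -> np.ndarray:
    """log gAIC per model: sum over participants of ln(w_model / w_baseline).

    ``weights`` is (n_participants, n_models).  Pass per-participant log
    weights with ``log_input=True`` to avoid the floor entirely; raw weights
    of zero are floored at 1e-300 (a warning-level situation the caller can
    detect from the magnitude).  The baseline column maps to exactly 0.
    """
    w = np.asarray(weights, dtype=float)
    logw = w if log_input else np.log(np.maximum(w, WEIGHT_FLOOR))
    return (logw - logw[:, [baseline]]).sum(axis=0)


def dirichlet_p_best(weights) -> tuple:
    """(alpha_i, P(best_i)) from per-participant Akaike weights."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    alpha = 1.0 + w.sum(axis=0)
    return alpha, alpha / alpha.sum()


def best_model_census(delta_aicc) -> np.ndarray:
    """Participants best fit per model; ties go to the lowest column index
    (canonical order guessing < RW < configural RW < Pearce)."""
    d = np.atleast_2d(np.asarray(delta_aicc, dtype=float))
    best = d.argmin(axis=1)
    return np.bincount(best, minlength=d.shape[1])


@dataclass
class ComparisonTable:
    """Per-participant and pooled comparison of a model set."""

    models: tuple
    participant: pd.DataFrame   # participant_id, model, L, AICc, delta_AICc, wAICc
    overall: pd.DataFrame       # per model pooled quantities


def compare_fits(fits: pd.DataFrame, n_trials: int = 179,
                 baseline: str = "guessing") -> ComparisonTable:
    """Build the full comparison from a tidy fit table.

    ``fits`` needs columns participant_id, model, L, n_params, one row per
    participant x model.  Pooled AICc is reported under two conventions —
    ``AICc_pooled`` applies the AICc formula to the summed L with
    V = n_params x participants and n = trials x participants, while
    ``AICc_sum`` sums per-participant AICc — because the two differ once V
    grows with the cohort.  Weights, group AIC and the Dirichlet summary are
    driven by the per-participant AICc values.
    """
    models = [m for m in fits["model"].unique()]
    if baseline in models:  # canonical position first
        models = [baseline] + [m for m in models if m != baseline]
    wide_L = fits.pivot(index="participant_id", columns="model", values="L")[models]
    n_params = fits.groupby("model")["n_params"].first()[models]
    n_participants = wide_L.shape[0]

    aicc_pp = np.column_stack(
        [aicc(wide_L[m].to_numpy(), int(n_params[m]), n_trials) for m in models]
    )
    delta_pp = aicc_pp - aicc_pp.min(axis=1, keepdims=True)
    logw_pp = log_akaike_weights(aicc_pp)
    w_pp = np.exp(np.maximum(logw_pp, np.log(WEIGHT_FLOOR)))

    participant = pd.DataFrame(
        {
            "participant_id": np.repeat(wide_L.index.to_numpy(), len(models)),
            "model": np.tile(models, n_participants),
            "L": wide_L.to_numpy().ravel(),
            "AICc": aicc_pp.ravel(),
            "delta_AICc": delta_pp.ravel(),
            "wAICc": w_pp.ravel(),
        }
    )

    total_L = wide_L.sum(axis=0).to_numpy()
    pooled = np.array(
        [
            aicc(total_L[i], int(n_params[m]) * n_participants,
                 n_trials * n_participants)
            for i, m in enumerate(models)
        ]
    )
    summed = aicc_pp.sum(axis=0)
    alpha, p_best = dirichlet_p_best(w_pp)
    baseline_idx = models.index(baseline) if baseline in models else 0
    overall = pd.DataFrame(
        {
            "model": models,
            "n_params": n_params.to_numpy(),
            "total_2L": 2.0 * total_L,
            "AICc_pooled": pooled,
            "delta_AICc_pooled": pooled - pooled.min(),
            "wAICc_pooled": akaike_weights(pooled),
            "AICc_sum": summed,
            "delta_AICc_sum": summed - summed.min(),
            "log_gAIC": group_aic(logw_pp, baseline=baseline_idx, log_input=True),
            "dirichlet_alpha": alpha,
            "P_best": p_best,
            "n_best": best_model_census(delta_pp),
        }
    )
    return ComparisonTable(models=tuple(models), participant=participant,
                           overall=overall)
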