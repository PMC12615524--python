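"""SoftMax response mapping and response-sequence likelihood.

Associative strength drives choice through
``P(R) = exp(g V_R) / sum_k exp(g V_k)`` over the three response options
(predict X, predict Y, predict no outcome Z), with V_Z fixed at 0.  The
sensitivity ``g`` spans uniform guessing (g -> 0, every option at 1/3) to
maximisation (large g).  The likelihood of an observed sequence is the
summed negative log probability of each response under the one-step-
lookahead prediction for that trial.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_softmax, softmax

from .core import MODELS, OutcomeStrengths, validate_params
from .design import Design
from ._kernels import (
    BETA_PER_OUTCOME,
    BETA_PER_TRIAL,
    compile_design,
    encode_responses,
    fast_nll,
)

_BETA_MODE_FLAG = {"per_outcome": BETA_PER_OUTCOME, "per_trial": BETA_PER_TRIAL}


def response_probabilities(strengths, g: float) -> np.ndarray:
    """(p_X, p_Y, p_Z) from summed strengths; V_Z is the constant 0 baseline."""
    if isinstance(strengths, OutcomeStrengths):
        v = np.array(strengths)
    else:
        v = np.asarray(strengths, dtype=float)
        if v.shape[-1] == 2:
            v = np.concatenate([v, np.zeros(v.shape[:-1] + (1,))], axis=-1)
    return softmax(g * v, axis=-1)


def log_response_probabilities(strengths, g: float) -> np.ndarray:
    v = np.asarray(strengths, dtype=float)
    if v.shape[-1] == 2:
        v = np.concatenate([v, np.zeros(v.shape[:-1] + (1,))], axis=-1)
    return log_softmax(g * v, axis=-1)


def negative_log_likelihood(
    model: str,
    params: dict,
    design: Design,
    responses,
    beta_mode: str = "per_outcome",
    compiled=None,
) -> float:
    """L = -sum_i ln P(observed response_i) over a design.

    The prediction for trial i uses learning from trials 1..i-1 only, and the
    state is advanced with the trial's scheduled outcome — observed responses
    never feed back into learning.  ``compiled`` may carry a pre-compiled
    design to amortise encoding across repeated evaluations.
    """
    if len(responses) != len(design):
        raise ValueError(
            f"got {len(responses)} responses for {len(design)} trials"
        )
    validate_params(model, params)
    if compiled is None:
        compiled = compile_design(design, model)
    theta = MODELS[model].to_vector(params)
    resp = encode_responses(responses)
    return fast_nll(compiled, theta, resp, _BETA_MODE_FLAG[beta_mode])


def guessing_nll(n_trials: int) -> float:
    """Likelihood of the zero-parameter uniform guesser: n ln 3."""
    return n_trials * float(np.log(3.0))
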