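"""Error-correction learning rules: elemental RW, configural RW, Pearce.

All three models share the delta-rule form ``dV = alpha * beta * (lambda - sum V)``
and differ in what carries associative strength:

* elemental Rescorla-Wagner (``"rw"``) — every context and cue unit present on
  a trial sums into the prediction and is updated;
* configural Rescorla-Wagner (``"crw"``) — as above, plus one conjunction unit
  per unordered pair of co-present units, learning with its own rate;
* Pearce (``"pearce"``) — the whole stimulus pattern is a single configural
  unit; the prediction is a similarity-weighted sum over every configuration
  encountered so far, and only the current configuration is updated.

Associative strength toward each of the two reinforced outcome types (X, Y)
is tracked for every unit; the "no outcome" option Z carries a constant
strength of 0 and is never learned.

This module is the readable reference implementation; ``_kernels`` holds the
numba fast path used for likelihood evaluation, and the two are cross-checked
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .design import (
    Design,
    TrialSpec,
    encode_configural_rw,
    encode_elemental,
    encode_pearce,
    is_conjunction_unit,
    is_context_unit,
)

MODEL_NAMES = ("rw", "crw", "pearce")

RATE_BOUNDS = (0.0001, 0.75)
G_BOUNDS = (0.0001, 15.0)
D_BOUNDS = (0.0001, 20.0)


@dataclass(frozen=True)
class ModelSpec:
    """Free-parameter layout of one model."""

    name: str
    param_names: tuple
    bounds: dict
    encoder: object

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[p][0] for p in self.param_names])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[p][1] for p in self.param_names])

    def to_vector(self, params: dict) -> np.ndarray:
        return np.array([float(params[p]) for p in self.param_names])

    def to_dict(self, vector) -> dict:
        return dict(zip(self.param_names, (float(v) for v in vector)))


MODELS = {
    "rw": ModelSpec(
        "rw",
        ("alpha_ctx", "alpha_cue", "beta_us", "beta_nous", "g"),
        {
            "alpha_ctx": RATE_BOUNDS,
            "alpha_cue": RATE_BOUNDS,
            "beta_us": RATE_BOUNDS,
            "beta_nous": RATE_BOUNDS,
            "g": G_BOUNDS,
        },
        encode_elemental,
    ),
    "crw": ModelSpec(
        "crw",
        ("alpha_ctx", "alpha_cue", "alpha_cfg", "beta_us", "beta_nous", "g"),
        {
            "alpha_ctx": RATE_BOUNDS,
            "alpha_cue": RATE_BOUNDS,
            "alpha_cfg": RATE_BOUNDS,
            "beta_us": RATE_BOUNDS,
            "beta_nous": RATE_BOUNDS,
            "g": G_BOUNDS,
        },
        encode_configural_rw,
    ),
    "pearce": ModelSpec(
        "pearce",
        ("alpha_pat", "beta_us", "beta_nous", "d", "g"),
        {
            "alpha_pat": RATE_BOUNDS,
            "beta_us": RATE_BOUNDS,
            "beta_nous": RATE_BOUNDS,
            "d": D_BOUNDS,
            "g": G_BOUNDS,
        },
        encode_pearce,
    ),
}


def validate_params(model: str, params: dict) -> dict:
    spec = MODELS[model]
    missing = set(spec.param_names) - set(params)
    if missing:
        raise ValueError(f"missing parameters for {model}: {sorted(missing)}")
    for name in spec.param_names:
        lo, hi = spec.bounds[name]
        value = float(params[name])
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside box [{lo}, {hi}]")
    return params


class OutcomeStrengths(NamedTuple):
    """Summed associative strength toward each response option (V_Z fixed 0)."""

    V_X: float
    V_Y: float
    V_Z: float = 0.0


def outcome_vector(outcome: str) -> tuple:
    """(lambda_X, lambda_Y) for a scheduled outcome; Z gives (0, 0)."""
    if outcome == "X":
        return (1.0, 0.0)
    if outcome == "Y":
        return (0.0, 1.0)
    if outcome == "Z":
        return (0.0, 0.0)
    raise ValueError(f"unknown outcome {outcome!r}")


@dataclass
class AssociativeState:
    """Per-unit (or per-configuration) strengths toward X and Y.

    Units absent from ``V`` are implicitly at zero.  For the Pearce model the
    insertion order of ``V`` is the registry of configurations encountered so
    far; it only ever grows.
    """

    V: dict = field(default_factory=dict)

    def strength(self, unit) -> np.ndarray:
        return self.V.get(unit, np.zeros(2))

    def copy(self) -> "AssociativeState":
        return AssociativeState({k: v.copy() for k, v in self.V.items()})


def similarity(a: frozenset, b: frozenset, d: float) -> float:
    """Pearce configuration similarity ``(n_ab / (sqrt(n_a) sqrt(n_b)))**d``."""
    if not a or not b:
        raise ValueError("configurations must be non-empty")
    if d <= 0:
        raise ValueError("d must be positive")
    n_ab = len(a & b)
    return (n_ab / math.sqrt(len(a) * len(b))) ** d


def _unit_alpha(unit: str, params: dict, model: str) -> float:
    if is_context_unit(unit):
        return params["alpha_ctx"]
    if is_conjunction_unit(unit):
        if model != "crw":
            raise ValueError("conjunction units only valid for configural RW")
        return params["alpha_cfg"]
    return params["alpha_cue"]


def predict(model: str, state: AssociativeState, encoding, params: dict) -> OutcomeStrengths:
    """Summed strength toward each outcome for the current stimulus.

    For the Pearce model a configuration never seen before is registered at
    zero strength first; with self-similarity 1 this leaves the prediction on
    its first encounter unchanged.
    """
    if model in ("rw", "crw"):
        total = np.zeros(2)
        for unit in encoding:
            total += state.strength(unit)
        return OutcomeStrengths(total[0], total[1])
    if model == "pearce":
        config = frozenset(encoding)
        if config not in state.V:
            state.V[config] = np.zeros(2)
        total = np.zeros(2)
        for other, v in state.V.items():
            total += similarity(config, other, params["d"]) * v
        return OutcomeStrengths(total[0], total[1])
    raise ValueError(f"unknown model {model!r}")


def prediction_error(strengths: OutcomeStrengths, outcome: str) -> tuple:
    """Per-outcome delta-rule error ``lambda_k - V_k`` for k in {X, Y}."""
    lam_x, lam_y = outcome_vector(outcome)
    return (lam_x - strengths.V_X, lam_y - strengths.V_Y)


def _betas(outcome: str, params: dict, beta_mode: str) -> tuple:
    lam_x, lam_y = outcome_vector(outcome)
    if beta_mode == "per_outcome":
        return (
            params["beta_us"] if lam_x else params["beta_nous"],
            params["beta_us"] if lam_y else params["beta_nous"],
        )
    if beta_mode == "per_trial":
        beta = params["beta_us"] if (lam_x or lam_y) else params["beta_nous"]
        return (beta, beta)
    raise ValueError(f"unknown beta_mode {beta_mode!r}")


def update(
    model: str,
    state: AssociativeState,
    encoding,
    outcome: str,
    params: dict,
    beta_mode: str = "per_outcome",
) -> AssociativeState:
    """Apply one trial's learning in place and return the state.

    RW / configural RW: every present unit j changes by
    ``alpha(j) * beta(k) * (lambda_k - sum V_k)`` on both outcome dimensions.
    Pearce: only the current configuration changes, by
    ``alpha_pat * beta(k) * (lambda_k - sum S * V_k)``; generalisation spares
    every other configuration.
    """
    strengths = predict(model, state, encoding, params)
    err = prediction_error(strengths, outcome)
    beta_x, beta_y = _betas(outcome, params, beta_mode)
    delta = np.array([beta_x * err[0], beta_y * err[1]])
    if model in ("rw", "crw"):
        for unit in encoding:
            if unit not in state.V:
                state.V[unit] = np.zeros(2)
            state.V[unit] += _unit_alpha(unit, params, model) * delta
    else:
        config = frozenset(encoding)
        state.V[config] += params["alpha_pat"] * delta
    return state


def run_sequence(
    model: str,
    params: dict,
    design: Design,
    beta_mode: str = "per_outcome",
) -> np.ndarray:
    """One-step-lookahead strength trajectory over a design.

    Row i holds (V_X, V_Y) for trial i computed from learning over trials
    1..i-1 only; the state is then updated with trial i's *scheduled* outcome
    (observed responses never feed back into learning).
    """
    validate_params(model, params)
    encoder = MODELS[model].encoder
    state = AssociativeState()
    out = np.zeros((len(design), 2))
    for i, trial in enumerate(design.trials):
        encoding = encoder(trial)
        strengths = predict(model, state, encoding, params)
        out[i] = (strengths.V_X, strengths.V_Y)
        update(model, state, encoding, trial.outcome, params, beta_mode)
    return out


def trajectory_frame(model, params, design, beta_mode="per_outcome"):
    """Per-trial trajectory with errors, in exportable form."""
    import pandas as pd

    traj = run_sequence(model, params, design, beta_mode)
    lam = np.array([outcome_vector(t.outcome) for t in design.trials])
    return pd.DataFrame(
        {
            "trial_index": [t.index_in_experiment for t in design.trials],
            "phase": [t.phase for t in design.trials],
            "V_X": traj[:, 0],
            "V_Y": traj[:, 1],
            "error_X": lam[:, 0] - traj[:, 0],
            "error_Y": lam[:, 1] - traj[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# Closed-form asymptotics on the simplified two-cue procedure
# ---------------------------------------------------------------------------

def _simple_params(model: str, d: float, alpha: float, beta: float) -> dict:
    if model == "rw":
        return {"alpha_ctx": alpha, "alpha_cue": alpha, "beta_us": beta,
                "beta_nous": beta, "g": 1.0}
    if model == "crw":
        return {"alpha_ctx": alpha, "alpha_cue": alpha, "alpha_cfg": alpha,
                "beta_us": beta, "beta_nous": beta, "g": 1.0}
    return {"alpha_pat": alpha, "beta_us": beta, "beta_nous": beta,
            "d": d, "g": 1.0}


def _run_phase_to_convergence(model, state, phase_trials, params, tol, max_iter):
    """Cycle a phase's trial list until no strength moves by more than tol."""
    for _ in range(max_iter):
        before = {k: v.copy() for k, v in state.V.items()}
        for encoding, outcome in phase_trials:
            update(model, state, encoding, outcome, params)
        moved = 0.0
        for k, v in state.V.items():
            prev = before.get(k, np.zeros(2))
            moved = max(moved, float(np.max(np.abs(v - prev))))
        if moved < tol:
            return
    raise RuntimeError(f"phase did not converge within {max_iter} cycles")


def asymptotic_test_strength(
    model: str,
    procedure: str,
    d: float = 2.0,
    alphabeta: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 10**6,
) -> float:
    """Fixed-point strength of the target cue A after a simplified procedure.

    The simplified design drops the context: A and B are separately trained
    toward outcome X to asymptote, then extinguished per procedure — ``super``:
    AB- throughout; ``deepened``: A- then AB-; ``control``: A- — each phase
    iterated to convergence.  The returned value is the strength toward X
    read out on a test presentation of A alone (for Pearce, the
    similarity-generalised sum over all configurations).
    """
    if procedure not in ("super", "deepened", "control"):
        raise ValueError(f"unknown procedure {procedure!r}")
    alpha, beta = 0.25, alphabeta / 0.25  # fixed split; only the product matters
    params = _simple_params(model, d, alpha, beta)
    encoder = {
        "rw": lambda cues: frozenset(cues),
        "crw": lambda cues: encode_configural_cues(cues),
        "pearce": lambda cues: frozenset(cues),
    }[model]

    state = AssociativeState()
    acquisition = [(encoder({"A"}), "X"), (encoder({"B"}), "X")]
    _run_phase_to_convergence(model, state, acquisition, params, tol, max_iter)
    if procedure == "super":
        phases = [[(encoder({"A", "B"}), "Z")]]
    elif procedure == "deepened":
        phases = [[(encoder({"A"}), "Z")], [(encoder({"A", "B"}), "Z")]]
    else:
        phases = [[(encoder({"A"}), "Z")]]
    for phase in phases:
        _run_phase_to_convergence(model, state, phase, params, tol, max_iter)
    test = predict(model, state, encoder({"A"}), params)
    return float(test.V_X)


def encode_configural_cues(cues: set) -> frozenset:
    """Pairwise-conjunction coding for a bare cue set (no context unit)."""
    import itertools as _it

    base = sorted(cues)
    conj = {"*".join(sorted(p)) for p in _it.combinations(base, 2)}
    return frozenset(base) | conj
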