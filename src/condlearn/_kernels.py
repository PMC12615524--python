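"""Numba-jitted trial loops for likelihood evaluation.

Maximum-likelihood fitting evaluates the 179-trial forward pass thousands of
times per participant, so the recursion is compiled once over integer-encoded
designs.  ``core`` keeps the readable reference implementation; the test
suite asserts the two agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import MODELS, outcome_vector
from .design import Design, is_conjunction_unit, is_context_unit

BETA_PER_OUTCOME = 0
BETA_PER_TRIAL = 1

RESPONSE_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass(frozen=True)
class CompiledDesign:
    """Integer-encoded design for one model family."""

    model: str
    n_trials: int
    lam: np.ndarray            # (n, 2) scheduled lambda_X, lambda_Y
    # RW family
    unit_idx: np.ndarray       # (n, max_units) padded unit indices
    unit_count: np.ndarray     # (n,)
    alpha_class: np.ndarray    # (n_units,) 0=context 1=cue 2=conjunction
    # Pearce
    config_idx: np.ndarray     # (n,)
    config_size: np.ndarray    # (n_configs,)
    shared: np.ndarray         # (n_configs, n_configs) member-set intersections


def compile_design(design: Design, model: str) -> CompiledDesign:
    spec = MODELS[model]
    n = len(design)
    lam = np.array([outcome_vector(t.outcome) for t in design.trials])
    if model in ("rw", "crw"):
        vocab: dict = {}
        trial_units = []
        for trial in design.trials:
            units = sorted(spec.encoder(trial))
            idx = []
            for u in units:
                if u not in vocab:
                    vocab[u] = len(vocab)
                idx.append(vocab[u])
            trial_units.append(idx)
        max_units = max(len(u) for u in trial_units)
        unit_idx = np.zeros((n, max_units), dtype=np.int64)
        unit_count = np.zeros(n, dtype=np.int64)
        for i, idx in enumerate(trial_units):
            unit_idx[i, : len(idx)] = idx
            unit_count[i] = len(idx)
        alpha_class = np.zeros(len(vocab), dtype=np.int64)
        for u, j in vocab.items():
            alpha_class[j] = 0 if is_context_unit(u) else 2 if is_conjunction_unit(u) else 1
        return CompiledDesign(
            model, n, lam, unit_idx, unit_count, alpha_class,
            np.zeros(n, dtype=np.int64), np.zeros(0, dtype=np.int64),
            np.zeros((0, 0), dtype=np.int64),
        )
    if model == "pearce":
        configs: dict = {}
        config_idx = np.zeros(n, dtype=np.int64)
        for i, trial in enumerate(design.trials):
            c = spec.encoder(trial)
            if c not in configs:
                configs[c] = len(configs)
            config_idx[i] = configs[c]
        members = list(configs)
        m = len(members)
        config_size = np.array([len(c) for c in members], dtype=np.int64)
        shared = np.zeros((m, m), dtype=np.int64)
        for i in range(m):
            for j in range(m):
                shared[i, j] = len(members[i] & members[j])
        return CompiledDesign(
            model, n, lam,
            np.zeros((n, 0), dtype=np.int64), np.zeros(n, dtype=np.int64),
            np.zeros(0, dtype=np.int64), config_idx, config_size, shared,
        )
    raise ValueError(f"unknown model {model!r}")


def similarity_matrix(compiled: CompiledDesign, d: float) -> np.ndarray:
    """Pearce similarity between every pair of configurations in the design."""
    size = compiled.config_size.astype(np.float64)
    denom = np.sqrt(np.outer(size, size))
    return (compiled.shared / denom) ** d


@njit(cache=False)
def _rw_trajectory(unit_idx, unit_count, alpha_class, lam,
                   alpha_ctx, alpha_cue, alpha_cfg, beta_us, beta_nous,
                   beta_mode):
    n = unit_idx.shape[0]
    n_units = alpha_class.shape[0]
    V = np.zeros((n_units, 2))
    traj = np.zeros((n, 2))
    alphas = np.empty(3)
    alphas[0], alphas[1], alphas[2] = alpha_ctx, alpha_cue, alpha_cfg
    for i in range(n):
        vx = 0.0
        vy = 0.0
        for u in range(unit_count[i]):
            j = unit_idx[i, u]
            vx += V[j, 0]
            vy += V[j, 1]
        traj[i, 0] = vx
        traj[i, 1] = vy
        lx = lam[i, 0]
        ly = lam[i, 1]
        if beta_mode == 0:
            bx = beta_us if lx > 0.5 else beta_nous
            by = beta_us if ly > 0.5 else beta_nous
        else:
            b = beta_us if (lx > 0.5 or ly > 0.5) else beta_nous
            bx = b
            by = b
        dx = bx * (lx - vx)
        dy = by * (ly - vy)
        for u in range(unit_count[i]):
            j = unit_idx[i, u]
            a = alphas[alpha_class[j]]
            V[j, 0] += a * dx
            V[j, 1] += a * dy
    return traj


@njit(cache=False)
def _pearce_trajectory(config_idx, S, lam, alpha_pat, beta_us, beta_nous,
                       beta_mode):
    n = config_idx.shape[0]
    m = S.shape[0]
    V = np.zeros((m, 2))
    seen = np.zeros(m, dtype=np.bool_)
    traj = np.zeros((n, 2))
    for i in range(n):
        c = config_idx[i]
        seen[c] = True  # registered at zero before predicting; neutral
        vx = 0.0
        vy = 0.0
        for j in range(m):
            if seen[j]:
                vx += S[c, j] * V[j, 0]
                vy += S[c, j] * V[j, 1]
        traj[i, 0] = vx
        traj[i, 1] = vy
        lx = lam[i, 0]
        ly = lam[i, 1]
        if beta_mode == 0:
            bx = beta_us if lx > 0.5 else beta_nous
            by = beta_us if ly > 0.5 else beta_nous
        else:
            b = beta_us if (lx > 0.5 or ly > 0.5) else beta_nous
            bx = b
            by = b
        V[c, 0] += alpha_pat * bx * (lx - vx)
        V[c, 1] += alpha_pat * by * (ly - vy)
    return traj


@njit(cache=False)
def _nll_from_trajectory(traj, g, responses):
    """-sum log softmax(g * [V_X, V_Y, 0])[response], log-sum-exp stabilised."""
    n = traj.shape[0]
    total = 0.0
    for i in range(n):
        ax = g * traj[i, 0]
        ay = g * traj[i, 1]
        az = 0.0
        m = ax
        if ay > m:
            m = ay
        if az > m:
            m = az
        logz = m + np.log(np.exp(ax - m) + np.exp(ay - m) + np.exp(az - m))
        r = responses[i]
        if r == 0:
            total += logz - ax
        elif r == 1:
            total += logz - ay
        else:
            total += logz - az
    return total


def fast_trajectory(compiled: CompiledDesign, theta: np.ndarray,
                    beta_mode: int = BETA_PER_OUTCOME) -> np.ndarray:
    """Pre-update (V_X, V_Y) per trial for a parameter vector in model order."""
    if compiled.model == "rw":
        a_ctx, a_cue, b_us, b_nous, _g = theta
        return _rw_trajectory(compiled.unit_idx, compiled.unit_count,
                              compiled.alpha_class, compiled.lam,
                              a_ctx, a_cue, 0.0, b_us, b_nous, beta_mode)
    if compiled.model == "crw":
        a_ctx, a_cue, a_cfg, b_us, b_nous, _g = theta
        return _rw_trajectory(compiled.unit_idx, compiled.unit_count,
                              compiled.alpha_class, compiled.lam,
                              a_ctx, a_cue, a_cfg, b_us, b_nous, beta_mode)
    a_pat, b_us, b_nous, d, _g = theta
    S = similarity_matrix(compiled, d)
    return _pearce_trajectory(compiled.config_idx, S, compiled.lam,
                              a_pat, b_us, b_nous, beta_mode)


def fast_nll(compiled: CompiledDesign, theta: np.ndarray,
             responses: np.ndarray, beta_mode: int = BETA_PER_OUTCOME) -> float:
    """Negative log-likelihood of a response sequence under theta."""
    traj = fast_trajectory(compiled, theta, beta_mode)
    return float(_nll_from_trajectory(traj, theta[-1], responses))


def encode_responses(responses) -> np.ndarray:
    out = np.empty(len(responses), dtype=np.int64)
    for i, r in enumerate(responses):
        try:
            out[i] = RESPONSE_INDEX[r]
        except KeyError:
            raise ValueError(f"invalid response symbol {r!r}") from None
    return out
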