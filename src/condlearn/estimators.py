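"""Scikit-learn-style estimators for the three learning models.

Each estimator couples a trial-by-trial learning rule with the SoftMax choice
rule and fits its free parameters to one participant's 179-trial response
sequence by constrained maximum likelihood:

* ``RescorlaWagner`` — 5 parameters (alpha_ctx, alpha_cue, beta_us,
  beta_nous, g),
* ``ConfiguralRescorlaWagner`` — 6 (adds alpha_cfg for conjunction units),
* ``PearceConfigural`` — 5 (alpha_pat, beta_us, beta_nous, d, g),
* ``UniformGuesser`` — 0 parameters, the fixed 1/3-per-option baseline.

Fitting minimises the negative log-likelihood with Nelder-Mead from three
starts: the best of a coarse quasi-random search, a fixed canonical point
(all rates 0.1, g = 2), and a uniform random draw inside the parameter box.
Box constraints (rates in [0.0001, 0.75], g in [0.0001, 15], d in
[0.0001, 20]) are enforced by an invertible sigmoidal reparameterisation, so
every evaluated parameter vector is strictly feasible.

``X`` is a :class:`~condlearn.design.Design` (or a trial-table DataFrame in
the package's CSV dialect) and ``y`` the aligned response sequence in
{"X", "Y", "Z"}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .core import MODELS, ModelSpec, validate_params
from .design import Design, design_from_frame
from .response import guessing_nll, response_probabilities
from ._kernels import (
    BETA_PER_OUTCOME,
    BETA_PER_TRIAL,
    compile_design,
    encode_responses,
    fast_nll,
    fast_trajectory,
)

_BETA_FLAG = {"per_outcome": BETA_PER_OUTCOME, "per_trial": BETA_PER_TRIAL}
_RESPONSE_SYMBOLS = np.array(["X", "Y", "Z"])


def _as_design(X) -> Design:
    if isinstance(X, Design):
        return X
    if isinstance(X, pd.DataFrame):
        return design_from_frame(X)
    raise TypeError(f"X must be a Design or trial DataFrame, got {type(X)!r}")


@dataclass
class FitResult:
    """Outcome of one participant-level maximum-likelihood fit."""

    model: str
    theta_hat: dict
    L_min: float
    start_id: int
    n_evaluations: int
    converged: bool
    start_nlls: tuple = ()
    starts: tuple = ()


def _to_unconstrained(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return logit((theta - lo) / (hi - lo))


def _to_box(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * expit(u)


def make_starts(model: str, design, responses, seed: int,
                n_coarse: int = 64, beta_mode: str = "per_outcome",
                compiled=None):
    """The three optimisation starting points for one participant.

    Start 0 is the best of ``n_coarse`` scrambled-Sobol samples of the box (a
    cheap, reproducible preliminary search); start 1 is the canonical point
    with every parameter 0.1 except g = 2; start 2 is a uniform random draw
    inside the box.  All draws are governed by ``seed``.
    """
    spec = MODELS[model]
    design = _as_design(design)
    if compiled is None:
        compiled = compile_design(design, model)
    resp = encode_responses(responses)
    lo, hi = spec.lower(), spec.upper()
    flag = _BETA_FLAG[beta_mode]

    ss = np.random.SeedSequence(seed)
    sobol_seed, draw_seed = ss.spawn(2)
    sampler = qmc.Sobol(d=spec.n_params, scramble=True,
                        seed=np.random.default_rng(sobol_seed))
    m = max(1, int(np.ceil(np.log2(n_coarse))))
    candidates = qmc.scale(sampler.random_base2(m)[:n_coarse], lo, hi)
    nlls = [fast_nll(compiled, theta, resp, flag) for theta in candidates]
    coarse = candidates[int(np.argmin(nlls))]

    fixed = np.full(spec.n_params, 0.1)
    fixed[spec.param_names.index("g")] = 2.0

    rng = np.random.default_rng(draw_seed)
    random_start = lo + (hi - lo) * rng.uniform(size=spec.n_params)

    return [spec.to_dict(v) for v in (coarse, fixed, random_start)]


def fit_participant(model: str, design, responses, seed: int,
                    beta_mode: str = "per_outcome", n_coarse: int = 64,
                    maxiter: int = 2000, compiled=None) -> FitResult:
    """Best-of-three-starts Nelder-Mead maximum-likelihood fit.

    Convergence uses a relative tolerance of 1e-6 on L (``fatol`` scaled to
    the guessing likelihood) and at most ``maxiter`` iterations per start;
    non-convergence is reported in the result, never raised.  Ties between
    starts break to the lowest start id.
    """
    spec = MODELS[model]
    design = _as_design(design)
    if len(responses) != len(design):
        raise ValueError(
            f"got {len(responses)} responses for {len(design)} trials"
        )
    if compiled is None:
        compiled = compile_design(design, model)
    resp = encode_responses(responses)
    lo, hi = spec.lower(), spec.upper()
    flag = _BETA_FLAG[beta_mode]

    def objective(u):
        return fast_nll(compiled, _to_box(u, lo, hi), resp, flag)

    starts = make_starts(model, design, responses, seed, n_coarse=n_coarse,
                         beta_mode=beta_mode, compiled=compiled)
    fatol = 1e-6 * guessing_nll(len(design))
    best = None
    n_evaluations = 0
    start_nlls = []
    for start_id, start in enumerate(starts):
        theta0 = spec.to_vector(start)
        start_nlls.append(fast_nll(compiled, theta0, resp, flag))
        res = minimize(
            objective,
            _to_unconstrained(theta0, lo, hi),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": fatol, "xatol": 1e-4},
        )
        n_evaluations += res.nfev
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), start_id, _to_box(res.x, lo, hi), bool(res.success))
    if best is None:
        raise RuntimeError("no start produced a finite likelihood")
    L_min, start_id, theta, converged = best
    return FitResult(
        model=model,
        theta_hat=spec.to_dict(theta),
        L_min=L_min,
        start_id=start_id,
        n_evaluations=n_evaluations,
        converged=converged,
        start_nlls=tuple(start_nlls),
        starts=tuple(starts),
    )


class _AssociativeEstimator(BaseEstimator):
    """Shared fit/predict machinery; subclasses pin the model family."""

    model_name: str = ""

    def __init__(self, beta_mode: str = "per_outcome", n_coarse: int = 64,
                 maxiter: int = 2000, random_state: int = 0):
        self.beta_mode = beta_mode
        self.n_coarse = n_coarse
        self.maxiter = maxiter
        self.random_state = random_state

    @property
    def spec(self) -> ModelSpec:
        return MODELS[self.model_name]

    def fit(self, X, y):
        design = _as_design(X)
        result = fit_participant(
            self.model_name, design, y, self.random_state,
            beta_mode=self.beta_mode, n_coarse=self.n_coarse,
            maxiter=self.maxiter,
        )
        self.theta_ = result.theta_hat
        self.nll_ = result.L_min
        self.start_id_ = result.start_id
        self.n_evaluations_ = result.n_evaluations
        self.converged_ = result.converged
        self.result_ = result
        return self

    def _check_theta(self):
        if not hasattr(self, "theta_"):
            raise AttributeError(
                "estimator is not fitted; call fit() or set_theta() first"
            )

    def set_theta(self, theta: dict):
        """Install parameters directly (e.g. ground truth for simulation)."""
        validate_params(self.model_name, theta)
        self.theta_ = dict(theta)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n_trials, 3) one-step-lookahead response probabilities."""
        self._check_theta()
        design = _as_design(X)
        compiled = compile_design(design, self.model_name)
        theta = self.spec.to_vector(self.theta_)
        traj = fast_trajectory(compiled, theta, _BETA_FLAG[self.beta_mode])
        return response_probabilities(traj, self.theta_["g"])

    def predict(self, X) -> np.ndarray:
        """Most probable response symbol per trial."""
        return _RESPONSE_SYMBOLS[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        """Log-likelihood of the responses (higher is better)."""
        self._check_theta()
        design = _as_design(X)
        compiled = compile_design(design, self.model_name)
        theta = self.spec.to_vector(self.theta_)
        resp = encode_responses(y)
        return -fast_nll(compiled, theta, resp, _BETA_FLAG[self.beta_mode])

    def sample(self, X, random_state=None) -> np.ndarray:
        """Draw one categorical response per trial from predict_proba."""
        rng = np.random.default_rng(random_state)
        proba = self.predict_proba(X)
        cum = np.cumsum(proba, axis=1)
        u = rng.uniform(size=(proba.shape[0], 1))
        return _RESPONSE_SYMBOLS[(u < cum).argmax(axis=1)]

    @property
    def n_free_params(self) -> int:
        return self.spec.n_params


class RescorlaWagner(_AssociativeEstimator):
    """Elemental Rescorla-Wagner learner with SoftMax choice."""

    model_name = "rw"


class ConfiguralRescorlaWagner(_AssociativeEstimator):
    """Rescorla-Wagner with pairwise conjunction units."""

    model_name = "crw"


class PearceConfigural(_AssociativeEstimator):
    """Pearce configural learner: whole-pattern units with similarity
    generalisation governed by the discrimination exponent d."""

    model_name = "pearce"


class UniformGuesser(BaseEstimator):
    """Zero-parameter baseline assigning 1/3 to every response option."""

    model_name = "guessing"
    n_free_params = 0

    def fit(self, X, y):
        design = _as_design(X)
        if len(y) != len(design):
            raise ValueError("responses do not align with design")
        self.theta_ = {}
        self.nll_ = guessing_nll(len(design))
        self.converged_ = True
        return self

    def predict_proba(self, X) -> np.ndarray:
        return np.full((len(_as_design(X)), 3), 1.0 / 3.0)

    def score(self, X, y) -> float:
        return -guessing_nll(len(_as_design(X)))

    def sample(self, X, random_state=None) -> np.ndarray:
        rng = np.random.default_rng(random_state)
        return rng.choice(_RESPONSE_SYMBOLS, size=len(_as_design(X)))


ESTIMATORS = {
    "guessing": UniformGuesser,
    "rw": RescorlaWagner,
    "crw": ConfiguralRescorlaWagner,
    "pearce": PearceConfigural,
}

#: canonical model order, also the census tie-break order
MODEL_ORDER = ("guessing", "rw", "crw", "pearce")
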