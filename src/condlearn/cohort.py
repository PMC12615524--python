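"""Synthetic participant cohorts.

Stands in for the deposited human dataset: 174 participants split over the
control, deepened-extinction and super-extinction groups, each running the
full 179-trial schedule, with responses sampled trial by trial from one of
the learning models (or the uniform guesser) through the SoftMax rule.
Ground-truth generating parameters are retained on every record so that
parameter- and model-recovery studies can score themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MODELS, validate_params
from .design import Design, build_design, design_from_frame
from .response import response_probabilities
from ._kernels import compile_design, fast_trajectory

RESPONSE_SYMBOLS = np.array(["X", "Y", "Z"])

#: default group sizes: 174 participants split as evenly as the study's
#: three-group structure allows
DEFAULT_GROUP_SIZES = {"control": 58, "deepened": 58, "super": 58}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort.

    ``model`` is one of {"guessing", "rw", "crw", "pearce"}; ``theta`` is a
    fixed parameter dict, or ``"uniform"`` to draw each participant's
    parameters independently and uniformly inside the parameter box (the
    guesser has no parameters and ignores it).
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    model: str = "pearce"
    theta: object = "uniform"
    seed: int = 0

    @property
    def n_participants(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class ParticipantRecord:
    """One simulated participant with retained ground truth."""

    participant_id: str
    group: str
    design: Design
    responses: np.ndarray
    model: str = ""
    theta: dict = field(default_factory=dict)


def participant_seeds(master_seed: int, index: int, n: int = 2) -> list:
    """Stable per-participant seed derivation: children of
    SeedSequence((master_seed, index))."""
    return list(np.random.SeedSequence((int(master_seed), int(index))).spawn(n))


def response_trajectory(model: str, params: dict, design: Design) -> np.ndarray:
    """(n_trials, 3) per-trial response probabilities for a teacher model."""
    if model == "guessing":
        return np.full((len(design), 3), 1.0 / 3.0)
    validate_params(model, params)
    compiled = compile_design(design, model)
    traj = fast_trajectory(compiled, MODELS[model].to_vector(params))
    return response_probabilities(traj, params["g"])


def simulate_responses(model: str, params: dict, design: Design, seed,
                       mode: str = "categorical") -> np.ndarray:
    """Sample a response sequence from a teacher model over a design.

    ``categorical`` draws the full X/Y/Z response from (p_X, p_Y, p_Z) — the
    form fitting needs.  ``bernoulli_x`` draws only the X/not-X indicator
    from P(R_x), the form used to overlay model traces on observed response
    curves.  The same seed always reproduces the same sequence.
    """
    proba = response_trajectory(model, params, design)
    rng = np.random.default_rng(seed)
    if mode == "categorical":
        cum = np.cumsum(proba, axis=1)
        u = rng.uniform(size=(proba.shape[0], 1))
        return RESPONSE_SYMBOLS[(u < cum).argmax(axis=1)]
    if mode == "bernoulli_x":
        return (rng.uniform(size=proba.shape[0]) < proba[:, 0]).astype(int)
    raise ValueError(f"unknown mode {mode!r}")


def draw_theta(model: str, rng: np.random.Generator) -> dict:
    """Uniform draw inside each parameter's constraint box."""
    if model == "guessing":
        return {}
    spec = MODELS[model]
    lo, hi = spec.lower(), spec.upper()
    return spec.to_dict(lo + (hi - lo) * rng.uniform(size=spec.n_params))


def simulate_cohort(spec: CohortSpec) -> list:
    """Simulate every participant of a cohort spec.

    Participant i's design-shuffling and response-sampling seeds both derive
    from ``SeedSequence((master_seed, i))``, so cohorts are reproducible and
    participants statistically independent.
    """
    records = []
    index = 0
    for group, size in spec.group_sizes.items():
        for _ in range(int(size)):
            design_ss, response_ss, theta_ss = participant_seeds(spec.seed, index, 3)
            design_seed = int(design_ss.generate_state(1)[0] % (2**31))
            design = build_design(group, design_seed)
            if spec.model == "guessing":
                theta = {}
            elif spec.theta == "uniform":
                theta = draw_theta(spec.model, np.random.default_rng(theta_ss))
            else:
                theta = dict(spec.theta)
            responses = simulate_responses(spec.model, theta, design, response_ss)
            records.append(
                ParticipantRecord(
                    participant_id=f"p{index:03d}",
                    group=group,
                    design=design,
                    responses=responses,
                    model=spec.model,
                    theta=theta,
                )
            )
            index += 1
    return records


# ---------------------------------------------------------------------------
# Trial-table round trip
# ---------------------------------------------------------------------------

def cohort_to_frame(records) -> pd.DataFrame:
    """All participants' trials in the design CSV dialect + response column."""
    frames = []
    for rec in records:
        frame = rec.design.to_frame(rec.participant_id)
        frame["response"] = rec.responses
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "group", "phase", "block", "trial_index",
                     "context", "cues", "outcome", "response"]
        )
    return pd.concat(frames, ignore_index=True)


def cohort_from_frame(frame: pd.DataFrame) -> list:
    """Rebuild participant records (without ground truth) from a trial table."""
    records = []
    for pid, sub in frame.groupby("participant_id", sort=False):
        sub = sub.sort_values("trial_index")
        design = design_from_frame(sub.drop(columns=["response"]))
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                group=design.group,
                design=design,
                responses=sub["response"].to_numpy(),
            )
        )
    return records


def ground_truth_sidecar(records) -> dict:
    """JSON-serialisable generating model and parameters per participant."""
    return {
        rec.participant_id: {"model": rec.model, "theta": rec.theta}
        for rec in records
    }


def write_cohort(records, trials_path, sidecar_path=None) -> None:
    cohort_to_frame(records).to_csv(trials_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(ground_truth_sidecar(records), fh, indent=1)
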