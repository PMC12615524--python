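"""Experimental design construction and stimulus encoding.

The task is a three-outcome human predictive-learning experiment with five
phases: a 144-trial acquisition phase in context ``A:``, two 16-trial
extinction phases and a 2-trial summation test in context ``B:``, and a
single recovery-test trial in context ``C:``.  Three groups differ only in
how the target cue A is treated during extinction:

* ``control`` — A extinguished alone in both extinction phases,
* ``deepened`` — A alone in extinction 1, then in compound with the still
  excitatory cue B in extinction 2,
* ``super`` — A extinguished in compound with B from the outset.

Cue labels are single uppercase letters; contexts are written ``A:``,
``B:``, ``C:`` and contribute the lowercase stimulus units ``a``, ``b``,
``c`` to every trial's encoding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PHASES = ("acquisition", "extinction1", "extinction2", "summation", "recovery")
GROUPS = ("control", "deepened", "super")
OUTCOMES = ("X", "Y", "Z")

#: context label -> lowercase stimulus unit
CONTEXT_UNIT = {"A:": "a", "B:": "b", "C:": "c"}

#: per-block trial types during acquisition: (cues, outcome, count).
#: Four such blocks give the full schedule (e.g. A->X x12, A->Z x4, KL->Y x16).
ACQUISITION_BLOCK = (
    (("A",), "X", 3),
    (("A",), "Z", 1),
    (("B",), "X", 3),
    (("B",), "Z", 1),
    (("C",), "Y", 4),
    (("D",), "Z", 4),
    (("E",), "Z", 4),
    (("G",), "X", 4),
    (("K",), "Y", 3),
    (("K",), "Z", 1),
    (("L",), "Y", 3),
    (("L",), "Z", 1),
    (("K", "L"), "Y", 4),
)

#: target-cue trial type during each extinction phase, per group
_EXTINCTION_TARGET = {
    "control": (("A",), ("A",)),
    "deepened": (("A",), ("A", "B")),
    "super": (("A", "B"), ("A", "B")),
}


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial.

    ``outcome`` is the scheduled outcome: ``X``/``Y`` are the two reinforced
    outcome types, ``Z`` codes non-reinforcement.
    """

    phase: str
    block: int
    index_in_experiment: int
    context: str
    cues: frozenset
    outcome: str

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.context not in CONTEXT_UNIT:
            raise ValueError(f"unknown context {self.context!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.cues:
            raise ValueError("cue set must be non-empty")

    @property
    def cue_string(self) -> str:
        return "+".join(sorted(self.cues))


@dataclass(frozen=True)
class Design:
    """Ordered 179-trial schedule for one participant."""

    group: str
    trials: tuple
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def phase_trials(self, phase: str) -> list:
        return [t for t in self.trials if t.phase == phase]

    def to_frame(self, participant_id: str = "p0") -> pd.DataFrame:
        """One row per trial, in the package's trial-CSV dialect."""
        return pd.DataFrame(
            {
                "participant_id": participant_id,
                "group": self.group,
                "phase": [t.phase for t in self.trials],
                "block": [t.block for t in self.trials],
                "trial_index": [t.index_in_experiment for t in self.trials],
                "context": [t.context for t in self.trials],
                "cues": [t.cue_string for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
            }
        )


def design_from_frame(frame: pd.DataFrame) -> Design:
    """Rebuild a :class:`Design` from the trial-CSV dialect (one participant)."""
    groups = frame["group"].unique()
    if len(groups) != 1:
        raise ValueError("frame must contain exactly one participant/group")
    trials = tuple(
        TrialSpec(
            phase=row.phase,
            block=int(row.block),
            index_in_experiment=int(row.trial_index),
            context=row.context,
            cues=frozenset(str(row.cues).split("+")),
            outcome=row.outcome,
        )
        for row in frame.itertuples()
    )
    return Design(group=groups[0], trials=trials, seed=-1)


def _block_trials(types, rng):
    """Expand (cues, outcome, count) triples and shuffle within the block."""
    expanded = []
    for cues, outcome, count in types:
        expanded.extend([(frozenset(cues), outcome)] * count)
    order = rng.permutation(len(expanded))
    return [expanded[i] for i in order]


def build_design(group: str, seed: int) -> Design:
    """Construct the full per-participant schedule for one group.

    Trial order is randomised independently within each block from a single
    participant-level generator (``numpy.random.default_rng(seed)``) consumed
    block by block in phase order: acquisition blocks 1-4, extinction-1 blocks
    1-8, extinction-2 blocks 1-8.  The summation and recovery phases have
    fixed order.  The same seed therefore reproduces the design bit-exactly.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    rng = np.random.default_rng(int(seed))
    ext1_target, ext2_target = _EXTINCTION_TARGET[group]

    trials = []
    index = itertools.count(1)

    def emit(phase, block, context, cues, outcome):
        trials.append(
            TrialSpec(
                phase=phase,
                block=block,
                index_in_experiment=next(index),
                context=context,
                cues=frozenset(cues),
                outcome=outcome,
            )
        )

    for block in range(1, 5):
        for cues, outcome in _block_trials(ACQUISITION_BLOCK, rng):
            emit("acquisition", block, "A:", cues, outcome)
    for phase, target in (("extinction1", ext1_target), ("extinction2", ext2_target)):
        for block in range(1, 9):
            types = ((target, "Z", 1), (("C",), "Y", 1))
            for cues, outcome in _block_trials(types, rng):
                emit(phase, block, "B:", cues, outcome)
    for block in (1, 2):
        emit("summation", block, "B:", ("G",), "Z")
    emit("recovery", 1, "C:", ("A",), "Z")

    return Design(group=group, trials=tuple(trials), seed=int(seed))


# ---------------------------------------------------------------------------
# Stimulus encodings
# ---------------------------------------------------------------------------

def encode_elemental(trial: TrialSpec) -> frozenset:
    """Elemental units for a trial: the context unit plus one unit per cue."""
    return frozenset({CONTEXT_UNIT[trial.context]} | trial.cues)


def _conjunction(u: str, v: str) -> str:
    return "*".join(sorted((u, v)))


def encode_configural_rw(trial: TrialSpec) -> frozenset:
    """Elemental units plus one conjunction unit per unordered pair.

    A single-cue trial yields 3 units (context, cue, their conjunction); a
    two-cue trial yields 6.  Conjunction identity is the sorted pair label,
    so the same pair maps to the same unit on every trial.
    """
    base = sorted(encode_elemental(trial))
    conj = {_conjunction(u, v) for u, v in itertools.combinations(base, 2)}
    return frozenset(base) | conj


def encode_pearce(trial: TrialSpec) -> frozenset:
    """The whole stimulus pattern (context + cues) as one configuration.

    Configuration identity is the member set itself, so repeated identical
    patterns map to the same configural unit.
    """
    return encode_elemental(trial)


def is_conjunction_unit(unit: str) -> bool:
    return "*" in unit


def is_context_unit(unit: str) -> bool:
    return unit in CONTEXT_UNIT.values()
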