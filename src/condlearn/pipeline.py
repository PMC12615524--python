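"""Study-level analysis stages around the models.

Covers the stages the modelling sits inside: the acquisition-performance
inclusion filter, descriptive response curves, recovery/summation summaries,
one-parameter-at-a-time likelihood sensitivity, and an end-to-end
orchestrator that runs inclusion -> per-participant fits (all models plus
the guessing baseline) -> model comparison -> curves -> sensitivity and
writes every artefact with a manifest.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from . import __version__ as _pkg_version
from .cohort import (
    CohortSpec,
    ParticipantRecord,
    cohort_from_frame,
    cohort_to_frame,
    ground_truth_sidecar,
    simulate_cohort,
)
from .comparison import compare_fits
from .design import Design
from .estimators import MODEL_ORDER, fit_participant
from .response import guessing_nll
from ._kernels import compile_design, encode_responses, fast_nll
from .core import MODELS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InclusionDecision:
    participant_id: str
    statistic: float
    p_value: float
    included: bool


def exact_rank_sum_greater(a, b) -> tuple:
    """One-sided rank-sum test that sample ``a`` stochastically exceeds ``b``.

    Exact permutation enumeration with midranks for ties: every C(n_a+n_b,
    n_a) assignment of the pooled midranks to the first sample is enumerated
    (1820 arrangements for the 4-vs-12 case) and the p-value is the fraction
    with rank sum at least as large as observed.  Written here because the
    samples are tiny and heavily tied, where normal approximations are at
    their worst.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    observed = ranks[: len(a)].sum()
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(pooled)), len(a)):
        total += 1
        if ranks[list(subset)].sum() >= observed - 1e-9:
            count += 1
    return float(observed), count / total


def _last_presentations(record: ParticipantRecord, cue: str, k: int = 4):
    """X-response indicators for the last k acquisition trials showing a cue alone."""
    idx = [
        i
        for i, t in enumerate(record.design.trials)
        if t.phase == "acquisition" and t.cues == frozenset({cue})
    ]
    if len(idx) < k:
        raise ValueError(f"fewer than {k} acquisition presentations of {cue}")
    return [1 if record.responses[i] == "X" else 0 for i in idx[-k:]]


def inclusion_filter(record: ParticipantRecord, method: str = "exact",
                     alpha: float = 0.05) -> InclusionDecision:
    """Did this participant learn to respond X to cue A during acquisition?

    Compares the X-response indicators on the last 4 cue-A acquisition
    trials against those on the last 4 presentations each of C, D and E
    (never paired with X) with a one-sided rank-sum test; the participant is
    included iff p < alpha.  ``method`` selects the exact permutation test
    or the normal approximation with continuity correction.
    """
    a_vec = _last_presentations(record, "A")
    cde_vec = sum((_last_presentations(record, c) for c in "CDE"), [])
    if method == "exact":
        statistic, p = exact_rank_sum_greater(a_vec, cde_vec)
    elif method == "normal":
        res = mannwhitneyu(a_vec, cde_vec, alternative="greater",
                           method="asymptotic", use_continuity=True)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return InclusionDecision(record.participant_id, statistic, p, bool(p < alpha))


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def response_curve(records, cue: str = "A", by_group: bool = True) -> pd.DataFrame:
    """Mean X-response proportion (with s.e.) at each aligned position of the
    trials containing ``cue``, per group.

    Positions count trials whose cue set includes the target (compound AB
    trials count as cue-A trials), so groups align on a common axis.  With a
    single participant the s.e. is reported as missing.
    """
    rows = []
    for rec in records:
        position = 0
        for i, t in enumerate(rec.design.trials):
            if cue in t.cues:
                position += 1
                rows.append(
                    {
                        "group": rec.group if by_group else "all",
                        "position": position,
                        "phase": t.phase,
                        "x": 1.0 if rec.responses[i] == "X" else 0.0,
                    }
                )
    if not rows:
        return pd.DataFrame(columns=["group", "position", "phase", "mean", "se", "n"])
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["group", "position", "phase"], sort=True)["x"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"sem": "se", "count": "n"})
    )
    return out


def recovery_and_summation_summary(records) -> dict:
    """Per-group recovery-test X rate and the cue-G summation-test X counts.

    The recovery rate is the proportion predicting X on the single cue-A
    test trial in the novel context.  The summation count (0-2 per
    participant, over the two non-reinforced G trials in the extinction
    context) indexes contextual inhibition and is summarised both by group
    and split by recovery responders vs non-responders.
    """
    per_participant = []
    for rec in records:
        recovery_trial = rec.design.phase_trials("recovery")
        summation = [
            i for i, t in enumerate(rec.design.trials) if t.phase == "summation"
        ]
        if not recovery_trial or not summation:
            raise ValueError("cohort lacks summation or recovery phase")
        i_recovery = rec.design.trials.index(recovery_trial[0])
        per_participant.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "recovered": rec.responses[i_recovery] == "X",
                "summation_x_count": int(
                    sum(rec.responses[i] == "X" for i in summation)
                ),
            }
        )
    frame = pd.DataFrame(per_participant)
    if frame.empty:
        return {"participants": frame, "recovery_rate": {}, "summation_by_group": {},
                "summation_by_recovery": {}}
    return {
        "participants": frame,
        "recovery_rate": frame.groupby("group")["recovered"].mean().to_dict(),
        "summation_by_group": frame.groupby("group")["summation_x_count"].mean().to_dict(),
        "summation_by_recovery": frame.groupby("recovered")["summation_x_count"].mean().to_dict(),
    }


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity(model: str, theta_hat: dict, design: Design, responses,
                fractions=(0.01, 0.05)) -> pd.DataFrame:
    """One-parameter-at-a-time relative likelihood change around an optimum.

    Each parameter is perturbed by +-fraction of its fitted value (clipped to
    its constraint box), the others held fixed, and
    ``|L_perturbed - L_min| / L_min`` recorded.  Zero perturbation gives zero
    change by construction.
    """
    spec = MODELS[model]
    compiled = compile_design(design, model)
    resp = encode_responses(responses)
    theta0 = spec.to_vector(theta_hat)
    L0 = fast_nll(compiled, theta0, resp)
    lo, hi = spec.lower(), spec.upper()
    rows = []
    for j, name in enumerate(spec.param_names):
        for fraction in fractions:
            for direction in (+1, -1):
                theta = theta0.copy()
                theta[j] = np.clip(theta0[j] * (1 + direction * fraction),
                                   lo[j], hi[j])
                L = fast_nll(compiled, theta, resp)
                rows.append(
                    {
                        "parameter": name,
                        "fraction": fraction,
                        "direction": direction,
                        "L": L,
                        "relative_change": abs(L - L0) / L0,
                    }
                )
    return pd.DataFrame(rows)


def cohort_sensitivity(fits: pd.DataFrame, records, fractions=(0.01, 0.05)) -> pd.DataFrame:
    """Mean relative likelihood change per model x parameter over a fitted cohort."""
    by_id = {rec.participant_id: rec for rec in records}
    frames = []
    for row in fits.itertuples():
        if row.model == "guessing":
            continue
        rec = by_id[row.participant_id]
        theta = json.loads(row.theta) if isinstance(row.theta, str) else row.theta
        report = sensitivity(row.model, theta, rec.design, rec.responses, fractions)
        report.insert(0, "participant_id", row.participant_id)
        report.insert(1, "model", row.model)
        frames.append(report)
    if not frames:
        return pd.DataFrame(
            columns=["participant_id", "model", "parameter", "fraction",
                     "direction", "L", "relative_change"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def fit_cohort(records, models=("rw", "crw", "pearce"), seed: int = 0,
               include_guessing: bool = True, **fit_kwargs) -> pd.DataFrame:
    """Tidy per-participant x model fit table for a cohort.

    The guessing baseline needs no optimisation: its likelihood is the
    closed form n ln 3.  Per-participant fit seeds derive from
    ``SeedSequence((seed, index))`` so the table is reproducible.
    """
    rows = []
    for index, rec in enumerate(records):
        n = len(rec.design)
        if include_guessing:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "group": rec.group,
                    "model": "guessing",
                    "L": guessing_nll(n),
                    "n_params": 0,
                    "theta": json.dumps({}),
                    "converged": True,
                    "start_id": -1,
                }
            )
        fit_seed = int(
            np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31)
        )
        for model in models:
            result = fit_participant(model, rec.design, rec.responses,
                                     fit_seed, **fit_kwargs)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "group": rec.group,
                    "model": model,
                    "L": result.L_min,
                    "n_params": MODELS[model].n_params,
                    "theta": json.dumps(result.theta_hat),
                    "converged": result.converged,
                    "start_id": result.start_id,
                }
            )
        logger.info("fitted participant %s (%d/%d)", rec.participant_id,
                    index + 1, len(records))
    return pd.DataFrame(rows)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_full_pipeline(config, outdir=None) -> dict:
    """Inclusion -> fits -> comparison -> curves -> sensitivity, with artefacts.

    ``config`` is a dict or YAML path with either a ``cohort`` section
    (CohortSpec fields) or a ``trials_csv`` path, plus optional ``models``,
    ``seed``, ``ranksum_method``, ``sensitivity_fractions``,
    ``sensitivity_participants`` (cap on how many fitted participants enter
    the sensitivity stage) and ``outdir``.  Returns the report bundle as a
    dict of DataFrames; writes CSVs and a manifest if an output directory is
    configured.  An empty cohort yields an empty report without error.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    models = tuple(cfg.get("models", ("rw", "crw", "pearce")))
    outdir = Path(outdir or cfg["outdir"]) if (outdir or cfg.get("outdir")) else None

    if "trials_csv" in cfg:
        records = cohort_from_frame(pd.read_csv(cfg["trials_csv"]))
        logger.info("loaded %d participants from %s", len(records), cfg["trials_csv"])
    else:
        spec = CohortSpec(seed=seed, **cfg.get("cohort", {}))
        records = simulate_cohort(spec)
        logger.info("simulated %d participants (model=%s)", len(records), spec.model)

    decisions = [
        inclusion_filter(rec, method=cfg.get("ranksum_method", "exact"))
        for rec in records
    ]
    inclusion = pd.DataFrame([asdict(d) for d in decisions])
    included = [rec for rec, d in zip(records, decisions) if d.included]
    logger.info("inclusion: %d/%d pass", len(included), len(records))

    report = {"inclusion": inclusion}
    if included:
        fits = fit_cohort(included, models=models, seed=seed)
        table = compare_fits(fits, n_trials=len(included[0].design))
        curves = response_curve(included)
        recovery = recovery_and_summation_summary(included)
        cap = int(cfg.get("sensitivity_participants", len(included)))
        sens = cohort_sensitivity(
            fits[fits["participant_id"].isin([r.participant_id for r in included[:cap]])],
            included,
            fractions=tuple(cfg.get("sensitivity_fractions", (0.01, 0.05))),
        )
        report.update(
            fits=fits,
            comparison_overall=table.overall,
            comparison_participants=table.participant,
            curves=curves,
            recovery=recovery["participants"],
            sensitivity=sens,
        )
    else:
        report.update(
            fits=pd.DataFrame(), comparison_overall=pd.DataFrame(),
            comparison_participants=pd.DataFrame(), curves=pd.DataFrame(),
            recovery=pd.DataFrame(), sensitivity=pd.DataFrame(),
        )

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        cohort_to_frame(records).to_csv(outdir / "trials.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth_sidecar(records), fh, indent=1)
        manifest = {
            "version": _pkg_version,
            "seed": seed,
            "models": list(models),
            "n_participants": len(records),
            "n_included": len(included),
            "rows": {k: int(len(v)) for k, v in report.items()},
            "parameter_boxes": {
                m: {p: list(MODELS[m].bounds[p]) for p in MODELS[m].param_names}
                for m in models
            },
        }
        for name, frame in report.items():
            frame.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        logger.info("artefacts written to %s", outdir)
    return report
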