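"""Synthetic cohort generation and round trips."""

import math

import numpy as np
import pytest

import condlearn as cl


class TestSimulateResponses:
    def test_seeded_determinism(self, designs, mid_theta):
        d = designs["super"]
        a = cl.simulate_responses("pearce", mid_theta["pearce"], d, 5)
        b = cl.simulate_responses("pearce", mid_theta["pearce"], d, 5)
        c = cl.simulate_responses("pearce", mid_theta["pearce"], d, 6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_guessing_rate_near_third(self, designs):
        responses = cl.simulate_responses("guessing", {}, designs["control"], 8)
        assert abs(np.mean(responses == "X") - 1 / 3) < 0.08

    def test_strong_teacher_maximises_on_late_A_trials(self, designs, mid_theta):
        d = designs["control"]
        theta = dict(mid_theta["rw"], g=15.0)
        responses = cl.simulate_responses("rw", theta, d, 9)
        late_A = [
            i for i, t in enumerate(d.trials)
            if t.phase == "acquisition" and t.cues == frozenset({"A"})
        ][-4:]
        assert np.mean([responses[i] == "X" for i in late_A]) >= 0.75

    def test_bernoulli_x_mode(self, designs, mid_theta):
        out = cl.simulate_responses("rw", mid_theta["rw"], designs["super"], 3,
                                    mode="bernoulli_x")
        assert set(np.unique(out)) <= {0, 1}
        assert out.shape == (179,)


class TestSimulateCohort:
    def test_study_sized_cohort(self):
        spec = cl.CohortSpec(model="guessing", seed=1)
        records = cl.simulate_cohort(spec)
        assert len(records) == 174
        assert all(len(r.responses) == 179 for r in records)
        groups = {g: sum(r.group == g for r in records)
                  for g in ("control", "deepened", "super")}
        assert groups == {"control": 58, "deepened": 58, "super": 58}
        pooled_2L = 2 * sum(cl.guessing_nll(179) for _ in records)
        assert pooled_2L == pytest.approx(68434.8, abs=0.05)

    def test_empty_cohort(self):
        spec = cl.CohortSpec(group_sizes={}, model="rw", theta="uniform", seed=0)
        assert cl.simulate_cohort(spec) == []

    def test_ground_truth_retained_and_boxed(self):
        spec = cl.CohortSpec(group_sizes={"super": 5}, model="pearce",
                             theta="uniform", seed=3)
        records = cl.simulate_cohort(spec)
        spec_p = cl.MODELS["pearce"]
        for rec in records:
            assert rec.model == "pearce"
            for name in spec_p.param_names:
                lo, hi = spec_p.bounds[name]
                assert lo <= rec.theta[name] <= hi
        # independent draws per participant
        assert records[0].theta != records[1].theta

    def test_reproducible_across_calls(self):
        spec = cl.CohortSpec(group_sizes={"control": 3}, model="rw",
                             theta="uniform", seed=9)
        a = cl.simulate_cohort(spec)
        b = cl.simulate_cohort(spec)
        assert all(np.array_equal(x.responses, y.responses) for x, y in zip(a, b))
        assert all(x.design.trials == y.design.trials for x, y in zip(a, b))


class TestRoundTrip:
    def test_frame_round_trip(self, mid_theta):
        spec = cl.CohortSpec(group_sizes={"control": 2, "super": 2},
                             model="crw", theta=mid_theta["crw"], seed=4)
        records = cl.simulate_cohort(spec)
        frame = cl.cohort_to_frame(records)
        assert len(frame) == 4 * 179
        rebuilt = cl.cohort_from_frame(frame)
        for orig, back in zip(records, rebuilt):
            assert orig.participant_id == back.participant_id
            assert orig.group == back.group
            assert np.array_equal(orig.responses, back.responses)
            assert all(a.cues == b.cues and a.outcome == b.outcome
                       for a, b in zip(orig.design.trials, back.design.trials))

    def test_sidecar_and_files(self, tmp_path, mid_theta):
        spec = cl.CohortSpec(group_sizes={"deepened": 2}, model="rw",
                             theta=mid_theta["rw"], seed=5)
        records = cl.simulate_cohort(spec)
        cl.write_cohort(records, tmp_path / "trials.csv", tmp_path / "gt.json")
        import json
        import pandas as pd

        assert len(pd.read_csv(tmp_path / "trials.csv")) == 2 * 179
        gt = json.loads((tmp_path / "gt.json").read_text())
        assert gt["p000"]["model"] == "rw"
        assert gt["p000"]["theta"]["g"] == 5.0

    def test_empty_frame(self):
        frame = cl.cohort_to_frame([])
        assert frame.empty
        assert cl.cohort_from_frame(frame) == []


def _recovery_rate(model, theta, group, n, seed):
    hits = 0
    for i in range(n):
        ss = np.random.SeedSequence((seed, i))
        design = cl.build_design(group, int(ss.generate_state(1)[0] % 2**31))
        responses = cl.simulate_responses(model, theta, design,
                                          np.random.SeedSequence((seed, i, 1)))
        hits += responses[-1] == "X"
    return hits / n


def test_super_extinction_recovery_excess_is_configural(mid_theta):
    """Configural teachers respond more on the recovery test after
    super-extinction than after single-cue extinction; the elemental RW
    teacher shows no such excess — the signature the three models disagree on."""
    n = 250
    theta = {m: dict(th, g=8.0) for m, th in mid_theta.items()}
    excess = {
        m: _recovery_rate(m, theta[m], "super", n, 21)
        - _recovery_rate(m, theta[m], "control", n, 22)
        for m in ("rw", "crw", "pearce")
    }
    assert excess["crw"] > 0.0
    assert excess["pearce"] > 0.0
    assert excess["rw"] < 0.02
    assert excess["pearce"] > excess["rw"]
    assert excess["crw"] > excess["rw"]
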