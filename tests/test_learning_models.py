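"""Learning rules: worked cases, closed forms, asymptotics, dual-route checks."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import condlearn as cl
from condlearn.core import AssociativeState, MODELS, encode_configural_cues
from condlearn._kernels import compile_design, fast_trajectory


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

class TestSimilarity:
    def test_identical_configurations(self):
        c = frozenset({"a", "A"})
        for d in (0.5, 1.0, 2.0, 20.0):
            assert cl.similarity(c, c, d) == 1.0

    def test_element_compound_half(self):
        # one shared member out of sizes 1 and 2, squared -> exactly 1/2
        assert cl.similarity(frozenset("A"), frozenset("AB"), 2.0) == pytest.approx(0.5)

    def test_cross_context_overlap(self):
        s = cl.similarity(frozenset({"a", "A"}), frozenset({"b", "A", "B"}), 1.0)
        assert s == pytest.approx(1 / math.sqrt(6))

    def test_invalid(self):
        with pytest.raises(ValueError):
            cl.similarity(frozenset(), frozenset("A"), 1.0)
        with pytest.raises(ValueError):
            cl.similarity(frozenset("A"), frozenset("A"), 0.0)

    @given(
        a=st.frozensets(st.sampled_from("abcABC"), min_size=1, max_size=4),
        b=st.frozensets(st.sampled_from("abcABC"), min_size=1, max_size=4),
        d=st.floats(0.1, 20.0),
    )
    def test_symmetric_bounded(self, a, b, d):
        s = cl.similarity(a, b, d)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(cl.similarity(b, a, d))
        if a == b:
            assert s == 1.0


# ---------------------------------------------------------------------------
# Predict / error / update worked cases
# ---------------------------------------------------------------------------

def test_empty_state_predicts_zero(mid_theta):
    for model in ("rw", "crw"):
        s = cl.predict(model, AssociativeState(), frozenset({"a", "A"}),
                       mid_theta[model])
        assert (s.V_X, s.V_Y, s.V_Z) == (0.0, 0.0, 0.0)
    s = cl.predict("pearce", AssociativeState(), frozenset({"a", "A"}),
                   mid_theta["pearce"])
    assert (s.V_X, s.V_Y) == (0.0, 0.0)


def test_rw_compound_error_minus_two(mid_theta):
    """Two separately trained excitors presented together double the
    extinction error (lambda - sum V -> -2)."""
    state = AssociativeState({"A": np.array([1.0, 0.0]), "B": np.array([1.0, 0.0])})
    s = cl.predict("rw", state, frozenset({"A", "B"}), mid_theta["rw"])
    assert s.V_X == pytest.approx(2.0)
    assert cl.prediction_error(s, "Z")[0] == pytest.approx(-2.0)


def test_pearce_compound_error_minus_one(mid_theta):
    """With element-compound similarity 1/2 the AB- error stays at -1."""
    state = AssociativeState({frozenset("A"): np.array([1.0, 0.0]),
                              frozenset("B"): np.array([1.0, 0.0])})
    s = cl.predict("pearce", state, frozenset("AB"), mid_theta["pearce"])
    assert s.V_X == pytest.approx(1.0)
    assert cl.prediction_error(s, "Z")[0] == pytest.approx(-1.0)


def test_prediction_error_signs():
    assert cl.prediction_error(cl.OutcomeStrengths(1.0, 0.0), "Z")[0] == -1.0
    assert cl.prediction_error(cl.OutcomeStrengths(0.0, 0.0), "X")[0] == +1.0
    assert cl.prediction_error(cl.OutcomeStrengths(0.3, 0.8), "Y") == \
        pytest.approx((-0.3, 0.2))


def test_update_zero_error_is_fixed_point(mid_theta):
    state = AssociativeState({"A": np.array([1.0, 0.0])})
    # lambda_X = 1 and sum V_X = 1, lambda_Y = 0 = sum V_Y -> no change
    cl.update("rw", state, frozenset({"A"}), "X", mid_theta["rw"])
    assert state.V["A"] == pytest.approx([1.0, 0.0])


def test_rw_hand_evaluated_delta():
    params = {"alpha_ctx": 0.2, "alpha_cue": 0.5, "beta_us": 0.9,
              "beta_nous": 0.4, "g": 1.0}
    state = AssociativeState({"A": np.array([1.0, 0.0])})
    cl.update("rw", state, frozenset({"a", "A"}), "Z", params)
    assert state.V["A"][0] == pytest.approx(1.0 - 0.2)          # 0.5*0.4*(-1)
    assert state.V["a"][0] == pytest.approx(-0.2 * 0.4 * 1.0)   # alpha_ctx branch


def test_pearce_update_spares_other_configurations(mid_theta):
    """Generalised extinction: only the present configuration changes."""
    state = AssociativeState({frozenset("A"): np.array([1.0, 0.0]),
                              frozenset("B"): np.array([1.0, 0.0])})
    cl.update("pearce", state, frozenset("AB"), "Z", mid_theta["pearce"])
    assert state.V[frozenset("A")][0] == 1.0
    assert state.V[frozenset("B")][0] == 1.0
    assert state.V[frozenset("AB")][0] < 0.0


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def test_run_sequence_starts_neutral_and_covers_design(designs, mid_theta):
    for model in MODELS:
        traj = cl.run_sequence(model, mid_theta[model], designs["control"])
        assert traj.shape == (179, 2)
        assert traj[0] == pytest.approx([0.0, 0.0])


def test_geometric_acquisition_closed_form():
    """Continuous single-cue reinforcement follows V_t = 1 - (1-ab)^t."""
    params = {"alpha_ctx": 0.5, "alpha_cue": 0.5, "beta_us": 0.5,
              "beta_nous": 0.5, "g": 1.0}  # alpha*beta = 0.25
    state = AssociativeState()
    values = []
    for _ in range(30):
        cl.update("rw", state, frozenset({"A"}), "X", params)
        values.append(state.V["A"][0])
    expected = 1.0 - 0.75 ** np.arange(1, 31)
    assert np.allclose(values, expected, atol=1e-12)
    assert np.all(np.diff(values) > 0)
    # and extinction decays geometrically back toward zero
    for _ in range(200):
        cl.update("rw", state, frozenset({"A"}), "Z", params)
    assert abs(state.V["A"][0]) < 1e-12


@pytest.mark.parametrize("model", ["rw", "crw", "pearce"])
@pytest.mark.parametrize("group", ["control", "super"])
def test_reference_and_kernel_agree(model, group, designs, mid_theta):
    """The numba fast path reproduces the pure-Python recursion exactly."""
    design = designs[group]
    ref = cl.run_sequence(model, mid_theta[model], design)
    fast = fast_trajectory(compile_design(design, model),
                           MODELS[model].to_vector(mid_theta[model]))
    assert np.allclose(ref, fast, atol=1e-12)


def test_beta_mode_variants_differ_only_where_expected(designs, mid_theta):
    """Per-trial beta selection equals per-outcome when beta_us == beta_nous
    and differs otherwise."""
    design = designs["super"]
    theta = dict(mid_theta["rw"])
    same = cl.run_sequence("rw", theta, design, beta_mode="per_trial")
    assert np.allclose(same, cl.run_sequence("rw", theta, design), atol=1e-12)
    theta["beta_nous"] = 0.1
    a = cl.run_sequence("rw", theta, design)
    b = cl.run_sequence("rw", theta, design, beta_mode="per_trial")
    assert not np.allclose(a, b)


def test_configural_rw_elemental_limit(designs, mid_theta):
    """With alpha_cfg at the box floor the configural RW collapses onto the
    elemental RW to within 10*alpha_cfg per trial."""
    design = designs["super"]
    theta_rw = mid_theta["rw"]
    theta_crw = dict(theta_rw, alpha_cfg=0.0001)
    rw = cl.run_sequence("rw", theta_rw, design)
    crw = cl.run_sequence("crw", theta_crw, design)
    assert np.max(np.abs(rw - crw)) < 10 * 0.0001


def test_pearce_high_d_approaches_identity(designs, mid_theta):
    """At the d ceiling, cross-context generalisation effectively vanishes."""
    assert cl.similarity(frozenset({"a", "A"}), frozenset({"b", "A", "B"}), 20.0) < 1e-7
    design = designs["super"]
    theta = dict(mid_theta["pearce"], d=20.0)
    state = AssociativeState()
    for trial in design.trials:
        enc = cl.encode_pearce(trial)
        cl.update("pearce", state, enc, trial.outcome, theta)
    # a trained configuration's prediction is dominated by its own strength;
    # the largest residual couplings (e.g. aK with aKL sharing 2 of 2/3
    # members) keep the gap above the fully-diagonal limit but tiny
    config = frozenset({"a", "A"})
    s = cl.predict("pearce", state, config, theta)
    assert abs(s.V_X - state.V[config][0]) < 1e-4
    assert abs(s.V_Y - state.V[config][1]) < 1e-4


# ---------------------------------------------------------------------------
# Asymptotic fixed points (simplified two-cue procedure)
# ---------------------------------------------------------------------------

EXPECTED_ASYMPTOTES = {
    ("rw", "control"): 0.0,
    ("rw", "super"): 0.0,
    ("rw", "deepened"): -0.5,
    ("crw", "control"): 0.0,
    ("crw", "super"): 1 / 3,
    ("crw", "deepened"): -1 / 3,
    ("pearce", "control"): 0.0,
    ("pearce", "super"): 0.5,
    ("pearce", "deepened"): -0.25,
}


@pytest.mark.parametrize(("model", "procedure"), sorted(EXPECTED_ASYMPTOTES))
def test_asymptotic_test_strength(model, procedure):
    value = cl.asymptotic_test_strength(model, procedure, d=2.0)
    assert value == pytest.approx(EXPECTED_ASYMPTOTES[(model, procedure)], abs=1e-6)


def test_asymptotic_ordering_matches_recovery_predictions():
    """Only the configural models leave residual target strength after
    super-extinction (the basis for predicting response recovery)."""
    for model in ("crw", "pearce"):
        super_ = cl.asymptotic_test_strength(model, "super", d=2.0)
        control = cl.asymptotic_test_strength(model, "control", d=2.0)
        deepened = cl.asymptotic_test_strength(model, "deepened", d=2.0)
        assert super_ > control > deepened
    assert cl.asymptotic_test_strength("rw", "super") == pytest.approx(0.0, abs=1e-6)
    assert cl.asymptotic_test_strength("rw", "control") == pytest.approx(0.0, abs=1e-6)
    assert cl.asymptotic_test_strength("rw", "deepened") < 0


def test_configural_cue_coding_helper():
    assert encode_configural_cues({"A", "B"}) == {"A", "B", "A*B"}
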