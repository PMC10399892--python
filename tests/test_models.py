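"""Core Q-learning mathematics against independent oracles."""

import zlib

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asymrl import models, tasks
from asymrl.models import AgentParams, choice_prob, get_variant, log_likelihood, q_trajectory, q_update

from conftest import random_sequence, replay_oracle


@pytest.mark.parametrize(
    "q, r, ap, an, expected",
    [
        (0.0, 1.0, 0.3, 0.9, 0.3),      # positive PE uses alpha_p
        (0.5, 0.5, 0.3, 0.9, 0.5),      # zero PE: positive branch, no change
        (1.0, 0.0, 0.3, 1.0, 0.0),      # full overwrite at alpha_n = 1
        (0.2, 1.0, 1.0, 0.0, 1.0),      # full overwrite at alpha_p = 1
        (1.0, 0.0, 0.3, 0.5, 0.5),      # negative PE uses alpha_n
    ],
)
def test_q_update_cases(q, r, ap, an, expected):
    assert q_update(q, r, ap, an) == pytest.approx(expected, abs=1e-15)


def test_q_update_tie_uses_positive_branch():
    # delta == 0 must not touch alpha_n even when alpha_n would matter
    assert q_update(0.7, 0.7, 0.1, 0.9) == 0.7


def test_choice_prob_values():
    assert choice_prob(0.3, 0.3, 7.0) == 0.5
    assert choice_prob(0.9, 0.1, 0.0) == 0.5
    # logistic at beta * dq = 10
    assert choice_prob(1.0, 0.0, 10.0) == pytest.approx(1.0 / (1.0 + np.exp(-10.0)), rel=1e-12)
    # extreme values stay finite and ordered
    assert 0.999999 <= choice_prob(1.0, 0.0, 20.0) < 1.0


@given(
    ql=st.floats(-1, 1), qr=st.floats(-1, 1), beta=st.floats(0, 20),
)
@settings(max_examples=200, deadline=None)
def test_choice_prob_complement(ql, qr, beta):
    assert choice_prob(ql, qr, beta) + choice_prob(qr, ql, beta) == pytest.approx(1.0, abs=1e-12)


def _random_params(rng, condition):
    lo, hi = tasks.Q0_BOUNDS[condition]
    return AgentParams(
        q0=float(rng.uniform(lo, hi)),
        alpha_p=float(rng.uniform(0.05, 0.95)),
        alpha_n=float(rng.uniform(0.05, 0.95)),
        beta=float(rng.uniform(0.5, 15.0)),
    )


@pytest.mark.parametrize("condition", ["gain", "loss", "mixed"])
def test_loglik_and_trajectory_match_recursion_oracle(condition):
    """Replay matches an independently coded recursion to 1e-12.

    100 random 50-trial sequences with random parameters; checks the
    total log likelihood, the per-trial prediction errors, the pre-update
    chosen values and the final Q pair.
    """
    rng = np.random.default_rng(zlib.crc32(condition.encode()))
    for _ in range(100):
        seq = random_sequence(rng, n_trials=50, n_blocks=2, condition=condition)
        p = _random_params(rng, condition)
        expected_ll, q_chosen, deltas, q_final = replay_oracle(
            p.q0, p.alpha_p, p.alpha_n, p.beta, seq
        )
        ll = log_likelihood(p, "A-VI", seq)
        traj = q_trajectory(p, "A-VI", seq)
        assert ll == pytest.approx(expected_ll, abs=1e-12)
        np.testing.assert_allclose(traj.q_chosen, q_chosen, atol=1e-12)
        np.testing.assert_allclose(traj.delta, deltas, atol=1e-12)
        np.testing.assert_allclose(traj.q_final, q_final, atol=1e-12)


def test_stacked_loglik_matches_scalar_path(rng):
    """Vectorised multi-subject likelihood equals the per-subject replay."""
    seqs = [random_sequence(rng, n_trials=40 + 5 * i, n_blocks=1) for i in range(6)]
    stacked = models.stack_sequences(seqs)  # ragged: exercises the mask
    q0 = rng.uniform(0, 1, 6)
    ap = rng.uniform(0, 1, 6)
    an = rng.uniform(0, 1, 6)
    beta = rng.uniform(0, 20, 6)
    ll_vec = models.loglik_subjects(stacked, q0, ap, an, beta)
    ll_np = models._loglik_subjects_numpy(stacked, q0, ap, an, beta)
    for i, s in enumerate(seqs):
        p = AgentParams(q0=q0[i], alpha_p=ap[i], alpha_n=an[i], beta=beta[i])
        expected = log_likelihood(p, "A-VI", s)
        assert ll_vec[i] == pytest.approx(expected, abs=1e-10)
        assert ll_np[i] == pytest.approx(expected, abs=1e-10)


def test_flat_softmax_likelihood_closed_form(rng):
    seq = random_sequence(rng, n_trials=48)
    p = AgentParams(q0=0.3, alpha_p=0.5, alpha_n=0.2, beta=0.0)
    assert log_likelihood(p, "A-VI", seq) == pytest.approx(48 * np.log(0.5), abs=1e-12)


def test_variant_nesting(rng):
    """A-VI reduces exactly to S-VI, A-FI and S-FI at shared points."""
    seq = random_sequence(rng, n_trials=64)
    sym = AgentParams(q0=0.2, alpha_p=0.4, alpha_n=0.4, beta=6.0)
    assert log_likelihood(sym, "A-VI", seq) == log_likelihood(sym, "S-VI", seq)
    pinned = AgentParams(q0=0.5, alpha_p=0.3, alpha_n=0.7, beta=6.0)
    assert log_likelihood(pinned, "A-VI", seq) == log_likelihood(pinned, "A-FI", seq)
    both = AgentParams(q0=0.5, alpha_p=0.4, alpha_n=0.4, beta=6.0)
    assert log_likelihood(both, "A-VI", seq) == log_likelihood(both, "S-FI", seq)
    zeroed = AgentParams(q0=0.0, alpha_p=0.3, alpha_n=0.7, beta=6.0)
    assert log_likelihood(zeroed, "A-VI", seq) == log_likelihood(zeroed, "A-FI'", seq)


def test_option_relabel_invariance(rng):
    """Swapping option labels (and choices with them) leaves LL unchanged."""
    seq = random_sequence(rng, n_trials=50)
    flipped = tasks.TrialSequence(
        subject=seq.subject, condition=seq.condition, block=seq.block,
        trial=seq.trial, choice=1 - seq.choice, outcome=seq.outcome,
        p0=seq.p1, p1=seq.p0,
    )
    p = _random_params(rng, "gain")
    assert log_likelihood(p, "A-VI", seq) == pytest.approx(
        log_likelihood(p, "A-VI", flipped), abs=1e-12
    )


def test_trajectory_constant_alpha_closed_form(rng):
    """For symmetric alpha, Q_T = Q0 (1−a)^T + sum a (1−a)^{T−k} r_k."""
    T, a, q0 = 30, 0.37, 0.6
    outcomes = rng.integers(0, 2, T).astype(float)
    seq = tasks.TrialSequence(
        subject=0, condition="gain", block=np.zeros(T, int), trial=np.arange(T),
        choice=np.zeros(T, int), outcome=outcomes,
        p0=np.full(T, 0.5), p1=np.full(T, 0.5),
    )
    p = AgentParams(q0=q0, alpha_p=a, alpha_n=a, beta=5.0)
    traj = q_trajectory(p, "A-VI", seq)
    closed = q0 * (1 - a) ** T + sum(
        a * (1 - a) ** (T - k - 1) * outcomes[k] for k in range(T)
    )
    assert traj.q_final[0] == pytest.approx(closed, abs=1e-12)


def test_trajectory_no_learning_and_delta_definition(rng):
    seq = random_sequence(rng, n_trials=40)
    p = AgentParams(q0=0.25, alpha_p=0.0, alpha_n=0.0, beta=3.0)
    traj = q_trajectory(p, "A-VI", seq)
    assert np.all(traj.q_chosen == 0.25)
    np.testing.assert_allclose(traj.delta, seq.outcome - traj.q_chosen, atol=0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_value_boundedness(seed):
    """With outcomes and Q0 inside [lo, hi], every Q stays inside."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, n_trials=60, condition="mixed")
    p = _random_params(rng, "mixed")
    traj = q_trajectory(p, "A-VI", seq)
    assert traj.q_pre.min() >= -1.0 - 1e-12
    assert traj.q_pre.max() <= 1.0 + 1e-12


def test_parameter_validation():
    with pytest.raises(ValueError, match="alpha_p"):
        AgentParams(0.5, 1.2, 0.5, 5.0).validate("gain")
    with pytest.raises(ValueError, match="beta"):
        AgentParams(0.5, 0.5, 0.5, 25.0).validate("gain")
    with pytest.raises(ValueError, match="q0"):
        AgentParams(-0.1, 0.5, 0.5, 5.0).validate("gain", "A-VI")
    # fixed-Q0 variants ignore the q0 field
    AgentParams(-0.1, 0.5, 0.5, 5.0).validate("gain", "A-FI")
    with pytest.raises(KeyError):
        get_variant("B-VI")


def test_illegal_outcome_codes_rejected(rng):
    seq = random_sequence(rng, n_trials=10, condition="gain")
    seq.condition = "mixed"  # gain codes {0,1} are illegal for mixed
    p = _random_params(rng, "mixed")
    with pytest.raises(ValueError, match="illegal"):
        log_likelihood(p, "A-VI", seq, condition="mixed")
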