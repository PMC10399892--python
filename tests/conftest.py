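"""Shared fixtures: small simulated datasets and fast sampler settings."""

from __future__ import annotations

import numpy as np
import pytest

from asymrl import hbayes, tasks


@pytest.fixture
def rng():
    return np.random.default_rng(20230724)


@pytest.fixture(scope="session")
def tiny_fit_config():
    """Very small sampler profile for smoke-level fits."""
    return hbayes.FitConfig(n_chains=2, n_warmup=300, n_keep_per_chain=300, seed=11)


@pytest.fixture(scope="session")
def gain_walk_dataset():
    """One 12-subject, 60-trial gain random-walk dataset from known truth."""
    design = tasks.RecoveryGridDesign(
        q0_levels=(0.25,), lr_pairs=((0.3, 0.5),),
        n_datasets_per_cell=1, n_subjects_per_dataset=12, n_trials=60,
    )
    return tasks.simulate_grid(design, seed=5)[0]


def random_sequence(rng, n_trials=50, n_blocks=2, condition="gain"):
    """A random (not model-generated) choice/outcome sequence for oracles."""
    reinforced, alternative = tasks.OUTCOME_CODES[condition]
    per = n_trials // n_blocks
    block = np.repeat(np.arange(n_blocks), per)
    trial = np.tile(np.arange(per), n_blocks)
    choice = rng.integers(0, 2, size=per * n_blocks)
    outcome = np.where(rng.random(per * n_blocks) < 0.5, reinforced, alternative)
    p = rng.uniform(0, 1, size=(per * n_blocks, 2))
    return tasks.TrialSequence(
        subject=0, condition=condition, block=block, trial=trial,
        choice=choice, outcome=outcome, p0=p[:, 0], p1=p[:, 1],
    )


def replay_oracle(q0, alpha_p, alpha_n, beta, seq):
    """Independent step-by-step recursion over a trial sequence.

    Deliberately written in plain Python with ``math`` only, so it shares
    no code with the package's likelihood path.  Returns (total log
    likelihood, list of pre-update chosen values, list of prediction
    errors, final [qa, qb]).
    """
    import math

    q = [q0, q0]
    total = 0.0
    q_chosen, deltas = [], []
    prev_block = None
    for b, c, r in zip(seq.block, seq.choice, seq.outcome):
        if b != prev_block:
            q = [q0, q0]
            prev_block = b
        x = beta * (q[c] - q[1 - c])
        total += -math.log1p(math.exp(-x)) if x >= 0 else x - math.log1p(math.exp(x))
        q_chosen.append(q[c])
        d = r - q[c]
        deltas.append(d)
        q[c] = q[c] + (alpha_p if d >= 0 else alpha_n) * d
    return total, q_chosen, deltas, q
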