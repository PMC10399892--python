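"""Two-armed bandit task schedules and synthetic choice data.

This module generates the experimental environments and the simulated
agents that play them:

* stable schedules — four mini-blocks with fixed per-option reinforcement
  probabilities (e.g. 40/60%, 25/75%, 25/25%, 75/75%), 32 trials each;
* restless schedules — a single long block whose two reinforcement
  probabilities follow independent reflecting random walks inside
  [0.25, 0.75] with ±0.05 steps;
* softmax Q-learning agents with parameters (Q0, alpha_p, alpha_n, beta)
  playing those schedules under partial feedback (only the chosen option's
  outcome is realised);
* the full factorial recovery grid (Q0 levels × learning-rate pairs ×
  replicate datasets) used for the parameter-recovery study.

Outcome coding is valence-dependent: in a gain environment the reinforced
event is +1 (a win) and the alternative 0; in a loss environment the
reinforced event is −1 (the penalty) and the alternative 0; in a mixed
environment outcomes are +1 or −1.  "Reinforcement probability" always
refers to the probability of the condition's salient event, so a
75%-reinforced loss option is a *bad* option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CONDITIONS = ("gain", "loss", "mixed")

#: (reinforced outcome code, alternative outcome code) per valence condition
OUTCOME_CODES: dict[str, tuple[float, float]] = {
    "gain": (1.0, 0.0),
    "loss": (-1.0, 0.0),
    "mixed": (1.0, -1.0),
}

#: legal initial-expectation range per condition: [worst outcome, best outcome]
Q0_BOUNDS: dict[str, tuple[float, float]] = {
    "gain": (0.0, 1.0),
    "loss": (-1.0, 0.0),
    "mixed": (-1.0, 1.0),
}

WALK_LO, WALK_HI, WALK_STEP = 0.25, 0.75, 0.05

#: the stable-task probability pairs used in the fixed-probability experiment
STANDARD_PAIRS: tuple[tuple[float, float], ...] = (
    (0.40, 0.60),
    (0.25, 0.75),
    (0.25, 0.25),
    (0.75, 0.75),
)


def _check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return condition


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One run of trials with a single cue pair.

    ``probs`` has shape (n_trials, 2): the per-trial reinforcement
    probability of each option.  Stable blocks have constant columns.
    """

    label: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 1:
            raise ValueError("block probs must have shape (n_trials >= 1, 2)")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError(f"block {self.label!r}: probabilities outside [0, 1]")
        object.__setattr__(self, "probs", p)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial reinforcement probabilities for a two-option task."""

    condition: str
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if not self.blocks:
            raise ValueError("schedule needs at least one block")
        object.__setattr__(self, "blocks", tuple(self.blocks))

    @property
    def magnitudes(self) -> tuple[float, float]:
        """(reinforced, alternative) outcome codes for this condition."""
        return OUTCOME_CODES[self.condition]

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    @property
    def probs(self) -> np.ndarray:
        """All blocks stacked, shape (n_trials, 2)."""
        return np.concatenate([b.probs for b in self.blocks], axis=0)

    @property
    def block_ids(self) -> np.ndarray:
        return np.concatenate(
            [np.full(b.n_trials, i, dtype=int) for i, b in enumerate(self.blocks)]
        )

    @property
    def trial_index(self) -> np.ndarray:
        """0-based trial index within each block, concatenated."""
        return np.concatenate([np.arange(b.n_trials) for b in self.blocks])


def make_stable_schedule(
    condition: str,
    pair_probs: Sequence[tuple[float, float]] = STANDARD_PAIRS,
    trials_per_block: int = 32,
    rng: np.random.Generator | None = None,
) -> TaskSchedule:
    """Build a fixed-probability schedule, one mini-block per pair.

    Block order is randomly permuted when ``rng`` is given (cue pairs were
    presented in randomised order); otherwise pairs appear as listed.
    """
    _check_condition(condition)
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    pairs = [tuple(map(float, p)) for p in pair_probs]
    for p in pairs:
        if len(p) != 2 or not all(0.0 <= x <= 1.0 for x in p):
            raise ValueError(f"invalid probability pair {p!r}: entries must lie in [0, 1]")
    order = np.arange(len(pairs))
    if rng is not None:
        order = rng.permutation(len(pairs))
    blocks = []
    for i in order:
        p0, p1 = pairs[i]
        label = f"{100 * p0:g}-{100 * p1:g}"
        blocks.append(Block(label, np.tile([p0, p1], (trials_per_block, 1))))
    return TaskSchedule(condition, tuple(blocks))


def _reflect(p: np.ndarray) -> np.ndarray:
    """Reflect a walk value back inside [WALK_LO, WALK_HI].

    A single bounce suffices because steps are 0.05 and walks start inside
    the interval; a value exactly on a boundary is legal and untouched.
    """
    p = np.where(p > WALK_HI, 2.0 * WALK_HI - p, p)
    p = np.where(p < WALK_LO, 2.0 * WALK_LO - p, p)
    return p


def random_walk_probs(
    n_walks: int, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Reflecting ±0.05 random walks in [0.25, 0.75], shape (n_walks, n_trials, 2).

    Each of the two options follows an independent walk started from an
    independent Uniform(0.25, 0.75) draw.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = np.empty((n_walks, n_trials, 2))
    p[:, 0, :] = rng.uniform(WALK_LO, WALK_HI, size=(n_walks, 2))
    steps = np.where(rng.random(size=(n_walks, n_trials - 1, 2)) < 0.5, WALK_STEP, -WALK_STEP)
    for t in range(1, n_trials):
        p[:, t, :] = _reflect(p[:, t - 1, :] + steps[:, t - 1, :])
    return p


def make_random_walk_schedule(
    condition: str, n_trials: int, rng: np.random.Generator
) -> TaskSchedule:
    """One-block restless schedule with independent reflecting walks."""
    _check_condition(condition)
    probs = random_walk_probs(1, n_trials, rng)[0]
    return TaskSchedule(condition, (Block("walk", probs),))


def sample_outcome(
    schedule: TaskSchedule,
    block: int,
    trial: int,
    option: int,
    rng: np.random.Generator,
) -> float:
    """Draw the outcome of pulling ``option`` at (block, trial).

    Only the queried option's outcome is realised (partial feedback).
    """
    if not 0 <= block < len(schedule.blocks):
        raise IndexError(f"block {block} out of range")
    blk = schedule.blocks[block]
    if not 0 <= trial < blk.n_trials:
        raise IndexError(f"trial {trial} out of range for block {block}")
    if option not in (0, 1):
        raise IndexError(f"option must be 0 or 1, got {option}")
    reinforced, alternative = schedule.magnitudes
    p = blk.probs[trial, option]
    return reinforced if rng.random() < p else alternative


# ---------------------------------------------------------------------------
# Trial sequences
# ---------------------------------------------------------------------------

@dataclass
class TrialSequence:
    """One subject's ordered choices and outcomes in one condition.

    All arrays are aligned per trial.  ``trial`` is the 0-based index
    within its block.  ``q`` (pre-update value of the chosen option) and
    ``delta`` (prediction error r_t − Q_t) are optional derived columns
    filled in by the simulator or by a model replay.
    """

    subject: int | str
    condition: str
    block: np.ndarray
    trial: np.ndarray
    choice: np.ndarray
    outcome: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    q: np.ndarray | None = None
    delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        self.block = np.asarray(self.block, dtype=int)
        self.trial = np.asarray(self.trial, dtype=int)
        self.choice = np.asarray(self.choice, dtype=int)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        n = len(self.choice)
        for name in ("block", "trial", "outcome", "p0", "p1"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if not np.isin(self.choice, [0, 1]).all():
            raise ValueError("choices must be coded 0/1")
        legal = set(OUTCOME_CODES[self.condition])
        if not set(np.unique(self.outcome)) <= legal:
            raise ValueError(
                f"outcome codes {sorted(set(self.outcome) - legal)} illegal for "
                f"{self.condition!r} (legal: {sorted(legal)})"
            )

    def __len__(self) -> int:
        return len(self.choice)

    @property
    def new_block(self) -> np.ndarray:
        """Boolean mask: True where value estimates re-initialise to Q0."""
        return self.trial == 0


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

def simulate_agent(
    params,
    variant,
    schedule: TaskSchedule,
    rng: np.random.Generator,
    subject: int | str = 0,
) -> TrialSequence:
    """Play ``schedule`` with a softmax Q-learning agent.

    Per trial: the choice is drawn from the softmax over current Q values,
    only the chosen option's outcome is drawn, and only the chosen option's
    value is updated.  Both options re-initialise to Q0 at each block start
    (a new cue pair carries no learned value).  Records the pre-update
    chosen value and the prediction error.
    """
    from . import models  # local import to avoid a cycle

    variant = models.get_variant(variant)
    params.validate(schedule.condition, variant)
    q0 = variant.resolve_q0(params, schedule.condition)
    alpha_p = params.alpha_p
    alpha_n = params.alpha_p if not variant.asymmetric else params.alpha_n
    reinforced, alternative = schedule.magnitudes

    probs = schedule.probs
    n = schedule.n_trials
    choice = np.empty(n, dtype=int)
    outcome = np.empty(n)
    q_pre = np.empty(n)
    delta = np.empty(n)
    new_block = (schedule.trial_index == 0)

    q = np.array([q0, q0])
    for t in range(n):
        if new_block[t]:
            q[:] = q0
        p_left = models.choice_prob(q[0], q[1], params.beta)
        c = 0 if rng.random() < p_left else 1
        r = reinforced if rng.random() < probs[t, c] else alternative
        choice[t] = c
        outcome[t] = r
        q_pre[t] = q[c]
        delta[t] = r - q[c]
        q[c] += (alpha_p if delta[t] >= 0 else alpha_n) * delta[t]

    return TrialSequence(
        subject=subject,
        condition=schedule.condition,
        block=schedule.block_ids,
        trial=schedule.trial_index,
        choice=choice,
        outcome=outcome,
        p0=probs[:, 0],
        p1=probs[:, 1],
        q=q_pre,
        delta=delta,
    )


def simulate_agents(
    q0: np.ndarray,
    alpha_p: np.ndarray,
    alpha_n: np.ndarray,
    beta: np.ndarray,
    probs: np.ndarray,
    new_block: np.ndarray,
    condition: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised agent simulation over subjects.

    ``probs`` has shape (S, T, 2) and ``new_block`` (T,) or (S, T); the
    parameter vectors broadcast over S subjects.  Returns (choices,
    outcomes), each (S, T).  Identical trial-by-trial dynamics to
    :func:`simulate_agent`; the scalar path is the reference in tests.
    """
    from . import models

    _check_condition(condition)
    S, T, _ = probs.shape
    q0, alpha_p, alpha_n, beta = (
        np.broadcast_to(np.asarray(a, dtype=float), (S,)).copy()
        for a in (q0, alpha_p, alpha_n, beta)
    )
    new_block = np.broadcast_to(np.asarray(new_block, dtype=bool), (S, T)) \
        if np.ndim(new_block) > 1 else np.broadcast_to(new_block, (S, T))
    reinforced, alternative = OUTCOME_CODES[condition]

    choices = np.empty((S, T), dtype=int)
    outcomes = np.empty((S, T))
    q = np.empty((S, 2))
    rows = np.arange(S)
    u = rng.random(size=(S, T, 2))  # u[...,0] drives choice, u[...,1] outcome
    for t in range(T):
        reset = new_block[:, t]
        if reset.any():
            q[reset, 0] = q0[reset]
            q[reset, 1] = q0[reset]
        p_left = models.choice_prob(q[:, 0], q[:, 1], beta)
        c = (u[:, t, 0] >= p_left).astype(int)
        p_rein = probs[rows, t, c]
        r = np.where(u[:, t, 1] < p_rein, reinforced, alternative)
        d = r - q[rows, c]
        q[rows, c] += np.where(d >= 0.0, alpha_p, alpha_n) * d
        choices[:, t] = c
        outcomes[:, t] = r
    return choices, outcomes


# ---------------------------------------------------------------------------
# Recovery grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryGridDesign:
    """Factorial design for the parameter-recovery simulation.

    Defaults follow the recovery study's gain-condition grid: five Q0
    levels crossed with seven (alpha_p, alpha_n) pairs, 30 datasets per
    cell, 30 subjects per dataset, beta fixed at 10, on the 100-trial
    restless task.
    """

    q0_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    lr_pairs: tuple[tuple[float, float], ...] = (
        (0.1, 0.7), (0.2, 0.6), (0.3, 0.5), (0.4, 0.4),
        (0.5, 0.3), (0.6, 0.2), (0.7, 0.1),
    )
    n_datasets_per_cell: int = 30
    n_subjects_per_dataset: int = 30
    beta: float = 10.0
    task: str = "random_walk"  # "random_walk" (one 100-trial block) or "stable"
    condition: str = "gain"
    n_trials: int = 100          # random-walk task length
    trials_per_block: int = 32   # stable task mini-block length

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if self.task not in ("random_walk", "stable"):
            raise ValueError("task must be 'random_walk' or 'stable'")
        if min(self.n_datasets_per_cell, self.n_subjects_per_dataset) < 1:
            raise ValueError("dataset and subject counts must be >= 1")
        if not self.q0_levels or not self.lr_pairs:
            raise ValueError("design needs at least one q0 level and one learning-rate pair")
        lo, hi = Q0_BOUNDS[self.condition]
        for q0 in self.q0_levels:
            if not lo <= q0 <= hi:
                raise ValueError(f"q0 level {q0} outside {self.condition} bounds [{lo}, {hi}]")
        for ap, an in self.lr_pairs:
            if not (0.0 <= ap <= 1.0 and 0.0 <= an <= 1.0):
                raise ValueError(f"learning-rate pair ({ap}, {an}) outside [0, 1]")
        if not 0.0 <= self.beta <= 20.0:
            raise ValueError("beta outside [0, 20]")

    @property
    def n_cells(self) -> int:
        return len(self.q0_levels) * len(self.lr_pairs)

    @property
    def n_datasets(self) -> int:
        return self.n_cells * self.n_datasets_per_cell


@dataclass
class SimulatedDataset:
    """One simulated dataset plus its generating-parameter tag."""

    q0: float
    alpha_p: float
    alpha_n: float
    beta: float
    condition: str
    cell: tuple[int, int]      # (q0 level index, lr pair index)
    dataset: int               # replicate index within the cell
    seed: int                  # integer seed of the dataset's own stream
    sequences: list[TrialSequence] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.sequences)


def _dataset_from_arrays(condition, choices, outcomes, probs, block_ids, trial_idx):
    seqs = []
    for s in range(choices.shape[0]):
        seqs.append(
            TrialSequence(
                subject=s,
                condition=condition,
                block=block_ids,
                trial=trial_idx,
                choice=choices[s],
                outcome=outcomes[s],
                p0=probs[s, :, 0],
                p1=probs[s, :, 1],
            )
        )
    return seqs


def simulate_dataset(
    q0: float,
    alpha_p: float,
    alpha_n: float,
    beta: float,
    design: RecoveryGridDesign,
    rng: np.random.Generator,
) -> list[TrialSequence]:
    """Simulate one dataset of ``design.n_subjects_per_dataset`` agents.

    Every subject gets a fresh schedule (its own random walks, or its own
    block-order permutation of the stable pairs).
    """
    S = design.n_subjects_per_dataset
    cond = design.condition
    if design.task == "random_walk":
        probs = random_walk_probs(S, design.n_trials, rng)
        T = design.n_trials
        block_ids = np.zeros(T, dtype=int)
        trial_idx = np.arange(T)
        new_block = trial_idx == 0
        choices, outcomes = simulate_agents(
            q0, alpha_p, alpha_n, beta, probs, new_block, cond, rng
        )
        return _dataset_from_arrays(cond, choices, outcomes, probs, block_ids, trial_idx)
    # stable task: per-subject block order permutations
    seqs = []
    from . import models
    params_proto = models.AgentParams(q0=q0, alpha_p=alpha_p, alpha_n=alpha_n, beta=beta)
    for s in range(S):
        sched = make_stable_schedule(cond, STANDARD_PAIRS, design.trials_per_block, rng)
        seqs.append(simulate_agent(params_proto, "A-VI", sched, rng, subject=s))
    return seqs


def simulate_grid(
    design: RecoveryGridDesign, seed: int | np.random.SeedSequence = 0
) -> list[SimulatedDataset]:
    """Simulate every cell of the factorial recovery grid.

    Output length is exactly |q0_levels| × |lr_pairs| × n_datasets_per_cell.
    Each dataset runs on its own child stream spawned deterministically from
    ``seed``, so re-running with the same seed reproduces identical tables.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(design.n_datasets)
    out: list[SimulatedDataset] = []
    k = 0
    for i, q0 in enumerate(design.q0_levels):
        for j, (ap, an) in enumerate(design.lr_pairs):
            for d in range(design.n_datasets_per_cell):
                child = children[k]
                k += 1
                ds_seed = int(child.generate_state(1)[0] % (2**31))
                rng = np.random.default_rng(np.random.SeedSequence(ds_seed))
                seqs = simulate_dataset(q0, ap, an, design.beta, design, rng)
                out.append(
                    SimulatedDataset(
                        q0=q0, alpha_p=ap, alpha_n=an, beta=design.beta,
                        condition=design.condition, cell=(i, j), dataset=d,
                        seed=ds_seed, sequences=seqs,
                    )
                )
    return out
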