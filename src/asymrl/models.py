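"""Asymmetric Q-learning: value update, softmax choice rule, likelihood.

The learner keeps one value estimate per option.  After each trial the
chosen option's value moves toward the obtained outcome by a learning rate
that depends on the sign of the prediction error delta = r − Q:

    Q <- Q + alpha_p * delta   if delta >= 0
    Q <- Q + alpha_n * delta   if delta <  0

(the tie delta = 0 takes the positive branch).  Choices follow a softmax
on the left-right value difference with inverse temperature beta:

    P(left) = 1 / (1 + exp(-beta * (Q_left − Q_right)))

Model variants cross two binary factors — asymmetric vs symmetric learning
rates, and a free vs fixed initial expectation Q0:

===========  ==========  =======  =================================
name         asymmetric  free Q0  fixed Q0 rule (per condition)
===========  ==========  =======  =================================
``A-VI``     yes         yes      —
``A-FI``     yes         no       gain 0.5, loss −0.5, mixed 0
``S-VI``     no          yes      —
``S-FI``     no          no       gain 0.5, loss −0.5, mixed 0
``A-FI0``    yes         no       0 in every condition
``S-FI0``    no          no       0 in every condition
===========  ==========  =======  =================================

``A-FI'``/``S-FI'`` are accepted as aliases of the zero-initialised
variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, NamedTuple

import numpy as np
from scipy.special import expit

from .tasks import OUTCOME_CODES, Q0_BOUNDS

if TYPE_CHECKING:  # pragma: no cover
    from .tasks import TrialSequence

BETA_BOUNDS = (0.0, 20.0)
ALPHA_BOUNDS = (0.0, 1.0)

MEAN_OUTCOME_Q0 = {"gain": 0.5, "loss": -0.5, "mixed": 0.0}
ZERO_Q0 = {"gain": 0.0, "loss": 0.0, "mixed": 0.0}


@dataclass(frozen=True)
class AgentParams:
    """Natural-scale learner parameters (Q0, alpha_p, alpha_n, beta)."""

    q0: float
    alpha_p: float
    alpha_n: float
    beta: float

    def validate(self, condition: str, variant: "ModelVariant | str" = "A-VI") -> None:
        variant = get_variant(variant)
        if not ALPHA_BOUNDS[0] <= self.alpha_p <= ALPHA_BOUNDS[1]:
            raise ValueError(f"alpha_p={self.alpha_p} outside [0, 1]")
        if variant.asymmetric and not ALPHA_BOUNDS[0] <= self.alpha_n <= ALPHA_BOUNDS[1]:
            raise ValueError(f"alpha_n={self.alpha_n} outside [0, 1]")
        if not BETA_BOUNDS[0] <= self.beta <= BETA_BOUNDS[1]:
            raise ValueError(f"beta={self.beta} outside {list(BETA_BOUNDS)}")
        if variant.free_q0:
            lo, hi = Q0_BOUNDS[condition]
            if not lo <= self.q0 <= hi:
                raise ValueError(f"q0={self.q0} outside {condition} bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class ModelVariant:
    """One cell of the asymmetric × free-initial-value model family."""

    name: str
    asymmetric: bool
    free_q0: bool
    fixed_q0_rule: Mapping[str, float] | None = None

    def resolve_q0(self, params: AgentParams, condition: str) -> float:
        if self.free_q0:
            return params.q0
        assert self.fixed_q0_rule is not None
        return self.fixed_q0_rule[condition]

    def effective_alpha_n(self, params: AgentParams) -> float:
        return params.alpha_n if self.asymmetric else params.alpha_p


VARIANTS: dict[str, ModelVariant] = {
    "A-VI": ModelVariant("A-VI", asymmetric=True, free_q0=True),
    "A-FI": ModelVariant("A-FI", asymmetric=True, free_q0=False, fixed_q0_rule=MEAN_OUTCOME_Q0),
    "S-VI": ModelVariant("S-VI", asymmetric=False, free_q0=True),
    "S-FI": ModelVariant("S-FI", asymmetric=False, free_q0=False, fixed_q0_rule=MEAN_OUTCOME_Q0),
    "A-FI0": ModelVariant("A-FI0", asymmetric=True, free_q0=False, fixed_q0_rule=ZERO_Q0),
    "S-FI0": ModelVariant("S-FI0", asymmetric=False, free_q0=False, fixed_q0_rule=ZERO_Q0),
}
_ALIASES = {"A-FI'": "A-FI0", "S-FI'": "S-FI0", "A-FI′": "A-FI0", "S-FI′": "S-FI0"}


def get_variant(variant: ModelVariant | str) -> ModelVariant:
    """Look up a variant by canonical name (or pass one through)."""
    if isinstance(variant, ModelVariant):
        return variant
    key = _ALIASES.get(variant, variant)
    try:
        return VARIANTS[key]
    except KeyError:
        raise KeyError(
            f"unknown model variant {variant!r}; known: {sorted(VARIANTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def q_update(q, r, alpha_p, alpha_n):
    """One asymmetric value update; broadcasts over array inputs."""
    delta = np.asarray(r, dtype=float) - q
    return q + np.where(delta >= 0.0, alpha_p, alpha_n) * delta


def choice_prob(q_left, q_right, beta):
    """Softmax probability of choosing the left option."""
    return expit(np.asarray(beta, dtype=float) * (np.asarray(q_left) - np.asarray(q_right)))


def _log_expit(x: np.ndarray) -> np.ndarray:
    """log(1/(1+exp(-x))), stable over the full float range."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Sequence replay
# ---------------------------------------------------------------------------

class Trajectory(NamedTuple):
    """Per-trial internals of a model replay."""

    q_pre: np.ndarray      # (T, 2) values before the trial's update
    q_chosen: np.ndarray   # (T,) pre-update value of the chosen option
    delta: np.ndarray      # (T,) prediction errors r_t − Q_t
    logp_choice: np.ndarray  # (T,) log probability of the observed choice
    q_final: np.ndarray    # (2,) values after the last update


def _check_outcomes(trials: "TrialSequence", condition: str) -> None:
    legal = set(OUTCOME_CODES[condition])
    seen = set(np.unique(trials.outcome))
    if not seen <= legal:
        raise ValueError(
            f"outcome codes {sorted(seen - legal)} illegal for condition {condition!r}"
        )


def q_trajectory(
    params: AgentParams,
    variant: ModelVariant | str,
    trials: "TrialSequence",
    condition: str | None = None,
) -> Trajectory:
    """Replay a choice/outcome sequence and expose the update internals.

    Both options re-initialise to the variant's Q0 at every block start.
    Only the chosen option's value is ever updated.
    """
    variant = get_variant(variant)
    condition = condition or trials.condition
    params.validate(condition, variant)
    _check_outcomes(trials, condition)
    q0 = variant.resolve_q0(params, condition)
    alpha_p = params.alpha_p
    alpha_n = variant.effective_alpha_n(params)
    beta = params.beta

    T = len(trials)
    new_block = trials.new_block
    q = np.array([q0, q0])
    q_pre = np.empty((T, 2))
    q_chosen = np.empty(T)
    delta = np.empty(T)
    logp = np.empty(T)
    for t in range(T):
        if new_block[t]:
            q[:] = q0
        c = trials.choice[t]
        q_pre[t] = q
        q_chosen[t] = q[c]
        # observed choice as chosen-vs-unchosen logistic (left/right symmetric)
        logp[t] = _log_expit(beta * (q[c] - q[1 - c]))
        delta[t] = trials.outcome[t] - q[c]
        q[c] += (alpha_p if delta[t] >= 0 else alpha_n) * delta[t]
    return Trajectory(q_pre, q_chosen, delta, logp, q.copy())


def log_likelihood(
    params: AgentParams,
    variant: ModelVariant | str,
    trials: "TrialSequence",
    condition: str | None = None,
) -> float:
    """Total log probability of a subject's observed choices."""
    return float(q_trajectory(params, variant, trials, condition).logp_choice.sum())


# ---------------------------------------------------------------------------
# Stacked multi-subject arrays (sampler hot path)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackedData:
    """Trial sequences stacked into (S, T) arrays, padded where ragged."""

    condition: str
    choice: np.ndarray     # (S, T) int
    outcome: np.ndarray    # (S, T) float
    new_block: np.ndarray  # (S, T) bool — True where Q resets to Q0
    mask: np.ndarray       # (S, T) bool — False on padding
    subjects: tuple       # original subject ids, in row order

    @property
    def n_subjects(self) -> int:
        return self.choice.shape[0]

    @property
    def n_trials(self) -> np.ndarray:
        return self.mask.sum(axis=1)


def stack_sequences(sequences: Iterable["TrialSequence"]) -> StackedData:
    """Stack per-subject sequences for vectorised likelihood evaluation."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to stack")
    cond = seqs[0].condition
    for s in seqs:
        if s.condition != cond:
            raise ValueError("all sequences must share one condition")
        _check_outcomes(s, cond)
    T = max(len(s) for s in seqs)
    S = len(seqs)
    choice = np.zeros((S, T), dtype=np.int64)
    outcome = np.zeros((S, T))
    new_block = np.zeros((S, T), dtype=bool)
    mask = np.zeros((S, T), dtype=bool)
    for i, s in enumerate(seqs):
        n = len(s)
        choice[i, :n] = s.choice
        outcome[i, :n] = s.outcome
        new_block[i, :n] = s.new_block
        mask[i, :n] = True
    return StackedData(cond, choice, outcome, new_block, mask,
                       tuple(s.subject for s in seqs))


try:  # optional compiled kernel; the numpy path below is the reference
    import numba as _numba

    @_numba.njit(cache=False, fastmath=False)
    def _loglik_kernel(choice, outcome, new_block, mask, q0, alpha_p, alpha_n, beta):  # pragma: no cover - exercised via loglik_subjects
        S, T = choice.shape
        out = np.empty(S)
        for s in range(S):
            q0v = q0[s]
            qa = q0v
            qb = q0v
            ll = 0.0
            for t in range(T):
                if new_block[s, t]:
                    qa = q0v
                    qb = q0v
                if not mask[s, t]:
                    continue
                c = choice[s, t]
                if c == 0:
                    qc, qu = qa, qb
                else:
                    qc, qu = qb, qa
                x = beta[s] * (qc - qu)
                if x >= 0.0:
                    ll += -np.log1p(np.exp(-x))
                else:
                    ll += x - np.log1p(np.exp(x))
                d = outcome[s, t] - qc
                a = alpha_p[s] if d >= 0.0 else alpha_n[s]
                if c == 0:
                    qa = qc + a * d
                else:
                    qb = qc + a * d
            out[s] = ll
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def loglik_subjects(
    data: StackedData,
    q0: np.ndarray,
    alpha_p: np.ndarray,
    alpha_n: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Per-subject total choice log likelihood, vectorised over subjects.

    Parameter vectors have shape (S,).  Same dynamics as
    :func:`q_trajectory`, which serves as the scalar reference.  Uses a
    compiled kernel when numba is importable; the numpy path is the
    always-available reference implementation.
    """
    if _HAVE_NUMBA:
        return _loglik_kernel(
            data.choice, data.outcome, data.new_block, data.mask,
            np.ascontiguousarray(q0, dtype=np.float64),
            np.ascontiguousarray(alpha_p, dtype=np.float64),
            np.ascontiguousarray(alpha_n, dtype=np.float64),
            np.ascontiguousarray(beta, dtype=np.float64),
        )
    return _loglik_subjects_numpy(data, q0, alpha_p, alpha_n, beta)


def _loglik_subjects_numpy(
    data: StackedData,
    q0: np.ndarray,
    alpha_p: np.ndarray,
    alpha_n: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    S, T = data.choice.shape
    q = np.empty((S, 2))
    q[:, 0] = q0
    q[:, 1] = q0
    rows = np.arange(S)
    ll = np.zeros(S)
    for t in range(T):
        reset = data.new_block[:, t]
        if reset.any():
            q[reset, 0] = q0[reset]
            q[reset, 1] = q0[reset]
        c = data.choice[:, t]
        qc = q[rows, c]
        qu = q[rows, 1 - c]
        lp = _log_expit(beta * (qc - qu))
        m = data.mask[:, t]
        ll += np.where(m, lp, 0.0)
        d = data.outcome[:, t] - qc
        step = np.where(d >= 0.0, alpha_p, alpha_n) * d
        q[rows, c] = qc + np.where(m, step, 0.0)
    return ll
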