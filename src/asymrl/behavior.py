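"""Model-free behavioral summaries for bandit choice data.

Sanity checks used alongside the model-based analyses: learning curves
(correct-choice rate by trial position), a win-stay regression (logistic
regression of repeating the previous choice on the previous outcome),
the preferred-response rate (PRR — the choice rate of whichever option a
subject picked most often in a block), and the association between PRR
and the fitted initial expectation Q0.

The inferential primitives here (IRLS logistic regression, Pearson
correlation, paired t test) are implemented from their closed formulas
so that these sanity checks carry no black boxes; scipy supplies only
the reference distributions for p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .tasks import TaskSchedule, TrialSequence


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

def _better_option(block_probs: np.ndarray, condition: str) -> int | None:
    """Index of the higher-expected-value option, or None if equal.

    In gain/mixed conditions the richer (more often reinforced) option is
    better; in the loss condition the reinforced event is the penalty, so
    the *less* often reinforced option is better.
    """
    p0, p1 = block_probs.mean(axis=0)
    if p0 == p1:
        return None
    if condition == "loss":
        return int(p0 > p1)
    return int(p0 < p1)


def correct_choice_rate(
    sequences: Iterable[TrialSequence], schedule: TaskSchedule
) -> dict[str, np.ndarray | None]:
    """Rate of choosing the better option, by within-block trial position.

    Returns ``{block label: rates array}`` averaged across subjects.
    Equal-probability blocks have no defined correct option and map to
    ``None`` (an explicit undefined marker, not a number).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    out: dict[str, np.ndarray | None] = {}
    for b, block in enumerate(schedule.blocks):
        best = _better_option(block.probs, schedule.condition)
        if best is None:
            out[block.label] = None
            continue
        per_subject = []
        for s in seqs:
            in_block = s.block == b
            if not in_block.any():
                continue
            order = np.argsort(s.trial[in_block])
            per_subject.append((s.choice[in_block][order] == best).astype(float))
        if not per_subject:
            raise ValueError(f"no trials found for block {b}")
        out[block.label] = np.mean(per_subject, axis=0)
    return out


# ---------------------------------------------------------------------------
# Win-stay regression
# ---------------------------------------------------------------------------

@dataclass
class StayRegression:
    """Fixed-effects logistic regression of staying on the last outcome."""

    coef: float        # effect of a reinforced previous outcome on staying
    se: float
    intercept: float
    n: int
    separated: bool    # perfect separation: coef reported at boundary

    @property
    def z(self) -> float:
        return self.coef / self.se if self.se > 0 else np.inf


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-10, bound: float = 15.0):
    """Logistic fit by iteratively reweighted least squares.

    Returns (beta, standard errors, separated flag); coefficients are
    clipped at ±``bound`` on divergence, the signature of separation.
    """
    beta = np.zeros(X.shape[1])
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        try:
            delta = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + delta
        if np.abs(beta).max() > bound:
            beta = np.clip(beta, -bound, bound)
            separated = True
            break
        if np.abs(delta).max() < tol:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-10, None)
    cov = np.linalg.pinv((X * w[:, None]).T @ X)
    return beta, np.sqrt(np.diag(cov)), separated


def stay_probability_regression(
    sequences: Iterable[TrialSequence],
) -> StayRegression:
    """Regress staying (choice_t == choice_{t−1}) on the previous outcome.

    The previous outcome is coded 1 for the condition's reinforced event
    and 0 otherwise... for gain data that is win vs no-win; for loss data
    penalty vs nothing (a positive learner then yields a *negative*
    penalty-stay effect).  Trials are pooled within blocks across
    subjects (fixed effects, no random slopes).
    """
    stays, prev = [], []
    for s in sequences:
        for b in np.unique(s.block):
            m = s.block == b
            c = s.choice[m][np.argsort(s.trial[m])]
            r = s.outcome[m][np.argsort(s.trial[m])]
            if len(c) < 2:
                continue
            stays.append((c[1:] == c[:-1]).astype(float))
            prev.append((r[:-1] != 0).astype(float))
    if not stays:
        raise ValueError("need at least one block with >= 2 trials")
    y = np.concatenate(stays)
    x = np.concatenate(prev)
    X = np.column_stack([np.ones_like(x), x])
    beta, se, separated = _irls_logistic(X, y)
    return StayRegression(
        coef=float(beta[1]), se=float(se[1]), intercept=float(beta[0]),
        n=len(y), separated=separated,
    )


# ---------------------------------------------------------------------------
# Preferred response rate
# ---------------------------------------------------------------------------

def preferred_response_rate(choices: Sequence[int]) -> float:
    """Choice rate of the option chosen most often; in [0.5, 1]."""
    c = np.asarray(choices)
    if c.size == 0:
        raise ValueError("empty choice list")
    n1 = int((c == 1).sum())
    return max(n1, c.size - n1) / c.size


def prr_by_block(sequences: Iterable[TrialSequence]) -> pd.DataFrame:
    """PRR per subject and block, as a tidy table."""
    rows = []
    for s in sequences:
        for b in np.unique(s.block):
            rows.append(
                dict(subject=s.subject, condition=s.condition, block=int(b),
                     prr=preferred_response_rate(s.choice[s.block == b]))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Association and test statistics
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Pearson correlation via the sums-of-products formulation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = (dx * dx).sum()
    syy = (dy * dy).sum()
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float((dx * dy).sum() / np.sqrt(sxx * syy))


def prr_q0_association(prr, q0) -> tuple[float, float]:
    """Pearson correlation between per-subject PRR and fitted Q0.

    Significance comes from the exact t transform
    t = r sqrt((n−2)/(1−r²)) against a t(n−2) reference.
    """
    prr = np.asarray(prr, dtype=float)
    q0 = np.asarray(q0, dtype=float)
    n = prr.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    r = pearson_r(prr, q0)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def paired_ttest(a, b) -> tuple[float, float]:
    """Paired t statistic on the differences a − b, with two-sided p."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance in differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
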