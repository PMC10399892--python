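"""Model comparison: DIC and group-level Bayesian model selection.

DIC for the hierarchical fits focuses on the individual-level parameters:
the mean posterior deviance D-bar is averaged over retained draws of the
subject-level natural parameters, and the plug-in deviance D-hat is
evaluated at each subject's trimmed-mean natural parameters, so

    p_D = D-bar − D-hat,     DIC = D-bar + p_D = 2 D-bar − D-hat.

Both quantities decompose additively over subjects, which yields the
subject-wise approximate log model evidence  −DIC_i / 2  feeding the
group-level random-effects model selection.

The group scheme treats the model identity of each subject as a random
effect with a Dirichlet prior over population model frequencies, fits the
frequency posterior variationally, estimates each model's exceedance
probability (EP — the probability that it is the most frequent) by
Monte-Carlo over the Dirichlet posterior, and protects it against the
chance hypothesis that all models are equally frequent via the Bayes
omnibus risk (BOR):

    PXP_k = EP_k * (1 − BOR) + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from . import models
from .hbayes import FitConfig, PosteriorDraws, sample_posterior
from .models import ModelVariant, StackedData, get_variant, stack_sequences


# ---------------------------------------------------------------------------
# Deviance / DIC
# ---------------------------------------------------------------------------

def deviance(params: models.AgentParams, data, variant: ModelVariant | str) -> float:
    """−2 × choice log likelihood of one subject's sequence."""
    return -2.0 * models.log_likelihood(params, variant, data)


@dataclass
class DevianceSummary:
    """Hierarchical DIC decomposition for one fitted model."""

    model: str
    d_bar: float
    d_hat: float
    per_subject: pd.DataFrame  # columns: subject, d_bar, d_hat, p_d, dic

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_hat

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d


def dic(
    draws: PosteriorDraws,
    data: Iterable | StackedData | None = None,
    variant: ModelVariant | str | None = None,
) -> DevianceSummary:
    """DIC from a posterior fit.

    ``data``/``variant`` default to what the fit already carries; passing
    them allows recomputation from exported draws.  The per-subject
    deviance trace comes from the sampler's stored data log likelihoods.
    """
    variant = get_variant(variant or draws.variant)
    if data is None:
        d_bar_i = -2.0 * draws.loglik.reshape(-1, draws.loglik.shape[-1]).mean(axis=0)
        stacked = None
    else:
        stacked = data if isinstance(data, StackedData) else stack_sequences(data)
        # recompute the deviance trace from the draws themselves
        nat = draws.natural_draws()
        C, K, S = nat["alpha_p"].shape
        tot = np.zeros(S)
        for c in range(C):
            for k in range(K):
                tot += models.loglik_subjects(
                    stacked,
                    np.asarray(nat["q0"][c, k], float),
                    nat["alpha_p"][c, k],
                    nat["alpha_n"][c, k],
                    nat["beta"][c, k],
                )
        d_bar_i = -2.0 * tot / (C * K)

    est = draws.subject_estimates()
    point_q0 = est["q0"].to_numpy()
    point_ap = est["alpha_p"].to_numpy()
    point_an = est["alpha_n"].to_numpy()
    point_beta = est["beta"].to_numpy()
    if stacked is None:
        if draws._stacked is None:
            raise ValueError("pass `data` explicitly: this fit carries no data copy")
        stacked = draws._stacked
    d_hat_i = -2.0 * models.loglik_subjects(
        stacked, point_q0, point_ap, point_an, point_beta
    )
    per = pd.DataFrame(
        {
            "subject": list(draws.subjects),
            "d_bar": d_bar_i,
            "d_hat": d_hat_i,
            "p_d": d_bar_i - d_hat_i,
            "dic": 2.0 * d_bar_i - d_hat_i,
        }
    )
    return DevianceSummary(
        model=variant.name,
        d_bar=float(d_bar_i.sum()),
        d_hat=float(d_hat_i.sum()),
        per_subject=per,
    )


def subject_evidence(
    draws: PosteriorDraws,
    data: Iterable | StackedData | None = None,
    variant: ModelVariant | str | None = None,
) -> np.ndarray:
    """Per-subject approximate log model evidence: −DIC_i / 2."""
    summary = dic(draws, data, variant)
    return -0.5 * summary.per_subject["dic"].to_numpy()


# ---------------------------------------------------------------------------
# Group-level random-effects Bayesian model selection
# ---------------------------------------------------------------------------

@dataclass
class BmsResult:
    """Random-effects model-selection output over K candidate models."""

    models: list[str]
    alpha: np.ndarray            # Dirichlet posterior concentrations (K,)
    expected_freq: np.ndarray    # posterior mean model frequencies (K,)
    assignment: np.ndarray       # subject × model posterior assignments
    ep: np.ndarray               # exceedance probabilities (K,)
    bor: float                   # Bayes omnibus risk
    pxp: np.ndarray              # protected exceedance probabilities (K,)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
        }


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    a_s, a0_s = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_s) - gammaln(alpha).sum()
        - gammaln(a0_s) + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_s))).sum()
    )


def group_bms(
    evidence: np.ndarray,
    n_mc: int = 1_000_000,
    rng: np.random.Generator | int | None = None,
    model_names: Sequence[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BmsResult:
    """Random-effects model selection from an N-subject × K-model evidence matrix.

    Variational iteration: subject-wise posterior model assignments g_nk ∝
    exp(lme_nk + digamma(alpha_k) − digamma(sum alpha)) against a Dirichlet
    posterior alpha = alpha0 + sum_n g_nk, to convergence.  EP is estimated
    by ``n_mc`` Monte-Carlo draws from the Dirichlet posterior.  BOR
    compares the variational free energy of the random-effects model with
    the null model of equal frequencies.
    """
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("evidence must be a 2-D subjects × models array")
    N, K = lme.shape
    if K < 1 or N < 1:
        raise ValueError("need at least one subject and one model")
    if not np.isfinite(lme).all():
        raise ValueError("evidence matrix contains non-finite entries")
    names = list(model_names) if model_names is not None else [f"M{k}" for k in range(K)]
    if K == 1:
        return BmsResult(names, np.array([N + 1.0]), np.array([1.0]),
                         np.ones((N, 1)), np.array([1.0]), 0.0, np.array([1.0]))

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    alpha0 = np.ones(K)
    alpha = alpha0.copy()
    g = np.full((N, K), 1.0 / K)
    for _ in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        g_new = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g_new.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha, g = alpha_new, g_new
            break
        alpha, g = alpha_new, g_new
    else:
        raise RuntimeError(f"group BMS did not converge in {max_iter} iterations")

    # exceedance probabilities by Monte-Carlo over the Dirichlet posterior
    draws = rng.dirichlet(alpha, size=n_mc)
    ep = np.bincount(draws.argmax(axis=1), minlength=K) / n_mc

    # free energy of the random-effects model
    logu = lme + digamma(alpha) - digamma(alpha.sum())
    f1 = float((g * (logu - np.log(np.clip(g, 1e-300, None)))).sum()
               - _dirichlet_kl(alpha, alpha0))
    # null model: every subject's data averaged over equally likely models
    f0 = float((logsumexp(lme, axis=1) - np.log(K)).sum())
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = ep * (1.0 - bor) + bor / K
    return BmsResult(names, alpha, alpha / alpha.sum(), g, ep, bor, pxp)


# ---------------------------------------------------------------------------
# End-to-end variant comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    bms: BmsResult
    dic_table: pd.DataFrame      # one row per model, sorted by DIC
    posteriors: dict[str, PosteriorDraws]

    @property
    def best_by_dic(self) -> str:
        return str(self.dic_table.iloc[0]["model"])

    @property
    def best_by_pxp(self) -> str:
        return self.bms.models[int(np.argmax(self.bms.pxp))]


def compare_variants(
    data: Iterable | StackedData,
    variants: Sequence[ModelVariant | str] = ("A-VI", "A-FI", "S-VI", "S-FI"),
    fit_config: FitConfig = FitConfig(),
    condition: str | None = None,
    n_mc: int = 1_000_000,
) -> ComparisonReport:
    """Fit every candidate variant and rank them by DIC and PXP."""
    stacked = data if isinstance(data, StackedData) else stack_sequences(data)
    condition = condition or stacked.condition
    variants = [get_variant(v) for v in variants]
    root = np.random.SeedSequence(fit_config.seed)
    children = root.spawn(len(variants) + 1)

    posteriors: dict[str, PosteriorDraws] = {}
    summaries: list[DevianceSummary] = []
    evidences = []
    for v, child in zip(variants, children[:-1]):
        cfg = replace(fit_config, seed=int(child.generate_state(1)[0] % (2**31)))
        post = sample_posterior(stacked, v, condition, cfg)
        posteriors[v.name] = post
        summary = dic(post)
        summaries.append(summary)
        evidences.append(-0.5 * summary.per_subject["dic"].to_numpy())

    table = pd.DataFrame(
        [
            dict(model=s.model, dic=s.dic, d_bar=s.d_bar, d_hat=s.d_hat, p_d=s.p_d)
            for s in summaries
        ]
    ).sort_values("dic", ignore_index=True)
    bms_rng = np.random.default_rng(children[-1])
    bms = group_bms(
        np.column_stack(evidences), n_mc=n_mc, rng=bms_rng,
        model_names=[v.name for v in variants],
    )
    return ComparisonReport(bms=bms, dic_table=table, posteriors=posteriors)
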