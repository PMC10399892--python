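"""Hierarchical Bayesian estimation of Q-learning parameters.

Model structure (per outcome-valence condition, conditions fitted
separately): each subject i has unbounded raw parameters theta'_i drawn
from group-level normal distributions,

    theta'_i ~ Normal(mu_theta', sigma_theta'),
    mu_theta' ~ Normal(0, 2),   sigma_theta' ~ half-Cauchy(0, 5),

and natural-scale parameters obtained with the probit transform
Phi (standard normal CDF):

    theta = theta_min + Phi(theta') * (theta_max − theta_min).

The negative learning rate is tied to the positive one through the
asymmetry offset delta:  alpha_n = Phi(alpha_p' + delta),  so the hyper
mean mu_delta directly measures the group's learning asymmetry
(mu_delta > 0 ⇔ alpha_n > alpha_p).

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme that
exploits the conditional structure of the hierarchy:

1. subject blocks — given the hypers, subjects are conditionally
   independent; each subject's raw vector takes a joint random-walk
   Metropolis step with a per-subject scale adapted during warmup;
2. hyper means — conjugate normal Gibbs draws;
3. hyper standard deviations — random-walk Metropolis on log(sigma)
   with a Jacobian correction, scale adapted during warmup;
4. an interweaving step — a joint Metropolis update of all (mu, log
   sigma) in the non-centered parameterization (standardised subject
   scores held fixed), which restores mixing in the low-heterogeneity
   "funnel" regime where purely centered updates stall.

The default chain geometry retains 4 chains × 6000 draws after 4000
warmup iterations each (24,000 draws per parameter); point estimates are
10%-per-side trimmed means.  Convergence is monitored with split-R-hat
and effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import models
from .models import ModelVariant, StackedData, get_variant, stack_sequences
from .tasks import Q0_BOUNDS

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def phi(x):
    """Standard normal CDF (the probit squashing function)."""
    return ndtr(np.asarray(x, dtype=float))


def phi_inv(p):
    """Inverse standard normal CDF."""
    return ndtri(np.asarray(p, dtype=float))


def to_natural(raw, lo: float, hi: float):
    """Map an unbounded raw parameter into (lo, hi): lo + Phi(raw)(hi−lo)."""
    if lo >= hi:
        raise ValueError(f"invalid bounds: lo={lo} must be < hi={hi}")
    return lo + phi(raw) * (hi - lo)


def from_natural(value, lo: float, hi: float):
    """Numerical inverse of :func:`to_natural`."""
    if lo >= hi:
        raise ValueError(f"invalid bounds: lo={lo} must be < hi={hi}")
    return phi_inv((np.asarray(value, dtype=float) - lo) / (hi - lo))


def neg_lr_from_offset(alpha_p_raw, asym_offset):
    """Negative learning rate alpha_n = Phi(alpha_p' + delta)."""
    return phi(np.asarray(alpha_p_raw, dtype=float) + asym_offset)


def trimmed_mean(samples, trim_fraction: float = 0.10) -> float:
    """Mean after dropping floor(trim*n) smallest and largest values."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("trimmed_mean of empty sample")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = int(np.floor(trim_fraction * x.size))
    return float(x[k: x.size - k].mean())


# ---------------------------------------------------------------------------
# Configuration and parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Sampler settings; the default is the full-scale chain geometry."""

    n_chains: int = 4
    n_warmup: int = 4000
    n_keep_per_chain: int = 6000
    trim_fraction: float = 0.10
    rhat_threshold: float = 1.05
    mu_prior_sd: float = 2.0       # hyper-mean prior Normal(0, 2)
    sigma_prior_scale: float = 5.0  # hyper-sd prior half-Cauchy(0, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_keep_per_chain) < 1:
            raise ValueError("chain counts must be positive")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.mu_prior_sd <= 0 or self.sigma_prior_scale <= 0:
            raise ValueError("prior scales must be positive")

    @property
    def total_draws(self) -> int:
        """Retained draws per parameter across chains."""
        return self.n_chains * self.n_keep_per_chain

    @classmethod
    def paper(cls, **kw) -> "FitConfig":
        """Full-scale profile: 4 chains × 4000 warmup × 6000 kept."""
        return cls(**kw)

    @classmethod
    def reduced(cls, **kw) -> "FitConfig":
        """Desk-scale profile for exploratory runs."""
        kw = {"n_chains": 4, "n_warmup": 2000, "n_keep_per_chain": 2000, **kw}
        return cls(**kw)

    @classmethod
    def test(cls, **kw) -> "FitConfig":
        """Small profile for automated test runs."""
        kw = {"n_chains": 2, "n_warmup": 1500, "n_keep_per_chain": 1500, **kw}
        return cls(**kw)


def param_names(variant: ModelVariant | str) -> list[str]:
    """Raw (transformed-scale) parameter names a variant estimates."""
    variant = get_variant(variant)
    names = []
    if variant.free_q0:
        names.append("q0_raw")
    names.append("alpha_p_raw")
    if variant.asymmetric:
        names.append("asym_offset")
    names.append("beta_raw")
    return names


def natural_params(
    raw: np.ndarray, variant: ModelVariant | str, condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Convert raw draws (..., P) to natural (q0, alpha_p, alpha_n, beta)."""
    variant = get_variant(variant)
    names = param_names(variant)
    ix = {n: i for i, n in enumerate(names)}
    raw = np.asarray(raw, dtype=float)
    ap_raw = raw[..., ix["alpha_p_raw"]]
    alpha_p = phi(ap_raw)
    if variant.asymmetric:
        alpha_n = neg_lr_from_offset(ap_raw, raw[..., ix["asym_offset"]])
    else:
        alpha_n = alpha_p
    beta = to_natural(raw[..., ix["beta_raw"]], *models.BETA_BOUNDS)
    if variant.free_q0:
        q0 = to_natural(raw[..., ix["q0_raw"]], *Q0_BOUNDS[condition])
    else:
        q0 = np.full(np.shape(alpha_p), variant.fixed_q0_rule[condition])
    return q0, alpha_p, alpha_n, beta


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def _normal_logpdf(x, mu, sigma):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -0.5 * (_LOG_2PI + z * z) - np.log(sigma)


def _half_cauchy_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2)
    return np.where(x > 0, out, -np.inf)


def _rl_loglik_fn(
    data: StackedData, variant: ModelVariant, condition: str
) -> Callable[[np.ndarray], np.ndarray]:
    def loglik(raw: np.ndarray) -> np.ndarray:
        q0, ap, an, beta = natural_params(raw, variant, condition)
        return models.loglik_subjects(data, np.asarray(q0, float), ap, an, beta)

    return loglik


def joint_log_density(
    mu: np.ndarray,
    sigma: np.ndarray,
    subjects_raw: np.ndarray,
    data: Sequence | StackedData | None,
    variant: ModelVariant | str,
    condition: str,
    config: FitConfig = FitConfig(),
) -> float:
    """Log joint density of hypers, subject raw parameters and data.

    ``subjects_raw`` has shape (S, P) in the variant's parameter order;
    ``data`` may be None / empty (prior-only reduction).
    """
    variant = get_variant(variant)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("hyper standard deviations must be positive")
    P = len(param_names(variant))
    if mu.shape != (P,) or sigma.shape != (P,):
        raise ValueError(f"expected {P} hyper parameters for {variant.name}")
    raw = np.asarray(subjects_raw, dtype=float).reshape(-1, P)

    total = float(
        _normal_logpdf(mu, 0.0, config.mu_prior_sd).sum()
        + _half_cauchy_logpdf(sigma, config.sigma_prior_scale).sum()
    )
    total += float(_normal_logpdf(raw, mu, sigma).sum())
    if data is not None:
        stacked = data if isinstance(data, StackedData) else stack_sequences(data)
        if stacked.n_subjects != raw.shape[0]:
            raise ValueError(
                f"{raw.shape[0]} subject parameter rows but "
                f"{stacked.n_subjects} subjects in data"
            )
        total += float(_rl_loglik_fn(stacked, variant, condition)(raw).sum())
    return total


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class ChainDraws:
    raw: np.ndarray     # (K, S, P)
    mu: np.ndarray      # (K, P)
    sigma: np.ndarray   # (K, P)
    loglik: np.ndarray  # (K, S) per-subject data log likelihood


def _run_chain(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    n_subjects: int,
    n_params: int,
    config: FitConfig,
    rng: np.random.Generator,
    fixed_hypers: tuple[np.ndarray, np.ndarray] | None = None,
) -> ChainDraws:
    S, P = n_subjects, n_params
    mu0_sd = config.mu_prior_sd
    hc_scale = config.sigma_prior_scale

    if fixed_hypers is not None:
        mu = np.asarray(fixed_hypers[0], dtype=float).copy()
        sigma = np.asarray(fixed_hypers[1], dtype=float).copy()
    else:
        mu = rng.normal(0.0, 0.5, size=P)
        sigma = np.exp(rng.normal(0.0, 0.3, size=P))

    raw = mu + sigma * rng.normal(0.0, 0.5, size=(S, P))
    ll = loglik_fn(raw)
    for _ in range(50):
        bad = ~np.isfinite(ll)
        if not bad.any():
            break
        raw[bad] = mu + sigma * rng.normal(0.0, 0.5, size=(int(bad.sum()), P))
        ll = loglik_fn(raw)
    else:
        raise RuntimeError(
            "could not initialise: data log likelihood is non-finite for "
            f"subjects {np.flatnonzero(~np.isfinite(ll)).tolist()}"
        )

    log_step = np.full(S, np.log(0.4))       # subject RW scale
    log_sstep = np.full(P, np.log(0.5))      # log-sigma RW scale
    log_astep = np.full(P, np.log(0.2))      # interweaving RW scales

    # adaptive-Metropolis moments for the subject proposals: the subject
    # posteriors are strongly correlated across parameters, so an isotropic
    # walk crawls; warmup learns a per-subject proposal covariance.
    am_start = min(max(100, config.n_warmup // 8), config.n_warmup)
    am_n = 0
    am_mean = np.zeros((S, P))
    am_m2 = np.zeros((S, P, P))   # running sum of outer-product deviations
    chol = None                    # (S, P, P) proposal Cholesky factors
    # joint group-translation move: learned covariance of the hyper means
    mu_n = 0
    mu_mean = np.zeros(P)
    mu_m2 = np.zeros((P, P))
    mu_chol = None
    log_tstep = np.log(2.38 / np.sqrt(P))
    n_iter = config.n_warmup + config.n_keep_per_chain
    out = ChainDraws(
        raw=np.empty((config.n_keep_per_chain, S, P)),
        mu=np.empty((config.n_keep_per_chain, P)),
        sigma=np.empty((config.n_keep_per_chain, P)),
        loglik=np.empty((config.n_keep_per_chain, S)),
    )

    for it in range(n_iter):
        warm = it < config.n_warmup
        gamma = (it + 1) ** -0.6  # Robbins-Monro adaptation rate

        # -- subject-level joint random-walk Metropolis, vectorised over S
        z = rng.standard_normal((S, P))
        if chol is None:
            step = np.exp(log_step)[:, None] * z
        else:
            step = np.exp(log_step)[:, None] * np.einsum("spq,sq->sp", chol, z)
        prop = raw + step
        ll_prop = loglik_fn(prop)
        prior_cur = _normal_logpdf(raw, mu, sigma).sum(axis=1)
        prior_prop = _normal_logpdf(prop, mu, sigma).sum(axis=1)
        logr = np.where(np.isfinite(ll_prop), ll_prop + prior_prop - ll - prior_cur, -np.inf)
        accept = np.log(rng.random(S)) < logr
        raw[accept] = prop[accept]
        ll[accept] = ll_prop[accept]
        if warm:
            log_step += gamma * (accept.astype(float) - 0.28)
            # accumulate per-subject posterior moments (Welford update)
            am_n += 1
            d0 = raw - am_mean
            am_mean += d0 / am_n
            am_m2 += np.einsum("sp,sq->spq", d0, raw - am_mean)
            if it >= am_start and am_n > 2 * P and it % 25 == 0:
                cov = am_m2 / (am_n - 1)
                cov[:, np.arange(P), np.arange(P)] += 1e-6
                try:
                    new_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    new_chol = None
                if new_chol is not None:
                    if chol is None:
                        log_step[:] = np.log(2.38 / np.sqrt(P))
                    chol = new_chol

        if fixed_hypers is None:
            # -- hyper means: conjugate normal Gibbs step
            prec = 1.0 / mu0_sd**2 + S / sigma**2
            mean = (raw.sum(axis=0) / sigma**2) / prec
            mu = mean + rng.standard_normal(P) / np.sqrt(prec)

            # -- hyper sds: random-walk Metropolis on log(sigma)
            ls = np.log(sigma)
            ls_prop = ls + np.exp(log_sstep) * rng.standard_normal(P)
            s_prop = np.exp(ls_prop)
            dev = raw - mu
            sse = (dev * dev).sum(axis=0)
            def _sigma_logpost(s, lsv):
                # sum_i N(raw_i; mu, s) + half-Cauchy(s) + log-Jacobian
                return (
                    -S * lsv - 0.5 * sse / s**2
                    + _half_cauchy_logpdf(s, hc_scale) + lsv
                )
            logr_s = _sigma_logpost(s_prop, ls_prop) - _sigma_logpost(sigma, ls)
            acc_s = np.log(rng.random(P)) < logr_s
            sigma = np.where(acc_s, s_prop, sigma)
            if warm:
                log_sstep += gamma * (acc_s.astype(float) - 0.44)

            # -- interweaving: per-parameter (mu_p, log sigma_p) moves at
            # fixed z-scores.  In the non-centered parameterization
            # raw = mu + sigma * z with z ~ N(0,1); holding z fixed, the
            # acceptance ratio involves the data likelihood, the hyper
            # priors and the log-sigma Jacobian — no raw-prior term.
            # Restores mixing when sigma is small (the funnel regime).
            for p in range(P):
                z_p = (raw[:, p] - mu[p]) / sigma[p]
                eps = np.exp(log_astep[p])
                mu_prop = mu[p] + eps * rng.standard_normal()
                sig_prop2 = sigma[p] * np.exp(eps * rng.standard_normal())
                raw_prop = raw.copy()
                raw_prop[:, p] = mu_prop + sig_prop2 * z_p
                ll_prop2 = loglik_fn(raw_prop)
                logr_a = (
                    np.where(np.isfinite(ll_prop2), ll_prop2, -np.inf).sum()
                    - ll.sum()
                    + _normal_logpdf(mu_prop, 0.0, mu0_sd)
                    - _normal_logpdf(mu[p], 0.0, mu0_sd)
                    + _half_cauchy_logpdf(sig_prop2, hc_scale) + np.log(sig_prop2)
                    - _half_cauchy_logpdf(sigma[p], hc_scale) - np.log(sigma[p])
                )
                acc_a = np.log(rng.random()) < logr_a
                if acc_a:
                    mu[p] = mu_prop
                    sigma[p] = sig_prop2
                    raw = raw_prop
                    ll = ll_prop2
                if warm:
                    log_astep[p] += gamma * (float(acc_a) - 0.234)

            # -- joint group translation: shift mu and every subject's raw
            # together along directions learned from the mu posterior, again
            # at fixed z-scores (sigma unchanged, so only the likelihood and
            # the mu prior enter the ratio).
            if warm:
                mu_n += 1
                d1 = mu - mu_mean
                mu_mean += d1 / mu_n
                mu_m2 += np.outer(d1, mu - mu_mean)
                if it >= am_start and mu_n > 2 * P and it % 25 == 0:
                    cov_mu = mu_m2 / (mu_n - 1) + 1e-8 * np.eye(P)
                    try:
                        mu_chol = np.linalg.cholesky(cov_mu)
                    except np.linalg.LinAlgError:
                        pass
            if mu_chol is not None:
                dmu = np.exp(log_tstep) * (mu_chol @ rng.standard_normal(P))
                raw_prop = raw + dmu
                ll_prop3 = loglik_fn(raw_prop)
                logr_t = (
                    np.where(np.isfinite(ll_prop3), ll_prop3, -np.inf).sum()
                    - ll.sum()
                    + _normal_logpdf(mu + dmu, 0.0, mu0_sd).sum()
                    - _normal_logpdf(mu, 0.0, mu0_sd).sum()
                )
                acc_t = np.log(rng.random()) < logr_t
                if acc_t:
                    mu = mu + dmu
                    raw = raw_prop
                    ll = ll_prop3
                if warm:
                    log_tstep += gamma * (float(acc_t) - 0.234)

        if not warm:
            k = it - config.n_warmup
            out.raw[k] = raw
            out.mu[k] = mu
            out.sigma[k] = sigma
            out.loglik[k] = ll
    return out


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus diagnostics for one fitted model."""

    variant: ModelVariant
    condition: str
    param_names: list[str]
    subjects: tuple
    raw: np.ndarray      # (C, K, S, P)
    mu: np.ndarray       # (C, K, P)
    sigma: np.ndarray    # (C, K, P)
    loglik: np.ndarray   # (C, K, S)
    config: FitConfig
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    _stacked: StackedData | None = None  # data the fit was run on

    @property
    def n_draws(self) -> int:
        return self.raw.shape[0] * self.raw.shape[1]

    @property
    def converged(self) -> bool:
        return not self.warnings

    def natural_draws(self) -> dict[str, np.ndarray]:
        """Per-draw natural-scale subject parameters, each (C, K, S)."""
        q0, ap, an, beta = natural_params(self.raw, self.variant, self.condition)
        return {"q0": np.asarray(q0), "alpha_p": ap, "alpha_n": an, "beta": beta}

    def subject_estimates(self) -> pd.DataFrame:
        """Trimmed-mean natural-scale point estimates per subject."""
        nat = self.natural_draws()
        trim = self.config.trim_fraction
        rows = {}
        for name, draws in nat.items():
            flat = draws.reshape(-1, draws.shape[-1])
            rows[name] = [trimmed_mean(flat[:, s], trim) for s in range(flat.shape[1])]
        df = pd.DataFrame(rows)
        df.insert(0, "subject", list(self.subjects))
        return df

    def hyper_natural_estimates(self) -> dict[str, float]:
        """Group-level natural-scale estimates from the hyper-mean draws."""
        ix = {n: i for i, n in enumerate(self.param_names)}
        trim = self.config.trim_fraction
        mu = self.mu.reshape(-1, self.mu.shape[-1])
        out: dict[str, float] = {}
        ap_raw = mu[:, ix["alpha_p_raw"]]
        out["alpha_p"] = trimmed_mean(phi(ap_raw), trim)
        if self.variant.asymmetric:
            out["alpha_n"] = trimmed_mean(
                neg_lr_from_offset(ap_raw, mu[:, ix["asym_offset"]]), trim
            )
        else:
            out["alpha_n"] = out["alpha_p"]
        out["beta"] = trimmed_mean(
            to_natural(mu[:, ix["beta_raw"]], *models.BETA_BOUNDS), trim
        )
        if self.variant.free_q0:
            out["q0"] = trimmed_mean(
                to_natural(mu[:, ix["q0_raw"]], *Q0_BOUNDS[self.condition]), trim
            )
        else:
            out["q0"] = self.variant.fixed_q0_rule[self.condition]
        return out

    def mu_delta_draws(self) -> np.ndarray:
        """Flattened posterior draws of the asymmetry hyper mean mu_delta."""
        if "asym_offset" not in self.param_names:
            raise ValueError(f"{self.variant.name} has no asymmetry offset")
        return self.mu[..., self.param_names.index("asym_offset")].ravel()

    def summary(self) -> pd.DataFrame:
        """Hyper-parameter table: trimmed mean, sd, split-R-hat, ESS."""
        trim = self.config.trim_fraction
        rows = []
        for i, name in enumerate(self.param_names):
            for kind, arr in (("mu", self.mu), ("sigma", self.sigma)):
                key = f"{kind}_{name}"
                draws = arr[..., i]
                rows.append(
                    dict(
                        parameter=key,
                        trimmed_mean=trimmed_mean(draws, trim),
                        sd=float(draws.std()),
                        rhat=self.rhat.get(key, np.nan),
                        ess=self.ess.get(key, np.nan),
                    )
                )
        return pd.DataFrame(rows)

    def to_tidy(self) -> pd.DataFrame:
        """Hyper draws as a tidy (chain, iteration, parameter, value) table."""
        C, K, P = self.mu.shape
        frames = []
        for i, name in enumerate(self.param_names):
            for kind, arr in (("mu", self.mu), ("sigma", self.sigma)):
                frames.append(
                    pd.DataFrame(
                        {
                            "chain": np.repeat(np.arange(C), K),
                            "iteration": np.tile(np.arange(K), C),
                            "parameter": f"{kind}_{name}",
                            "value": arr[..., i].ravel(),
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat for draws of shape (C, K)."""
    C, K = draws.shape
    half = K // 2
    if half < 2:
        return np.nan
    x = draws[:, : 2 * half].reshape(C * 2, half)
    m = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = half * m.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _diagnostics(post: PosteriorDraws) -> None:
    import arviz as az

    for i, name in enumerate(post.param_names):
        for kind, arr in (("mu", post.mu), ("sigma", post.sigma)):
            key = f"{kind}_{name}"
            d = arr[..., i]
            post.rhat[key] = _split_rhat(d)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post.ess[key] = float(az.ess(np.ascontiguousarray(d)))
    bad = {k: v for k, v in post.rhat.items()
           if np.isfinite(v) and v > post.config.rhat_threshold}
    if bad:
        msg = ("convergence warning: split-R-hat above "
               f"{post.config.rhat_threshold} for {sorted(bad)}")
        post.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)


def sample_hierarchy(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    n_subjects: int,
    n_params: int,
    config: FitConfig,
    fixed_hypers: tuple | None = None,
) -> list[ChainDraws]:
    """Run the Metropolis-within-Gibbs sampler on a generic hierarchy.

    ``loglik_fn`` maps an (S, P) raw-parameter matrix to per-subject data
    log likelihoods; any likelihood with this signature can be plugged in,
    which is how the sampler is validated against conjugate closed forms.
    """
    root = np.random.SeedSequence(config.seed)
    chains = []
    for child in root.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        chains.append(
            _run_chain(loglik_fn, n_subjects, n_params, config, rng, fixed_hypers)
        )
    return chains


def sample_posterior(
    data: Iterable | StackedData,
    variant: ModelVariant | str,
    condition: str | None = None,
    config: FitConfig = FitConfig(),
) -> PosteriorDraws:
    """Fit one model variant to a group of subjects.

    Returns the retained draws (config.n_chains × config.n_keep_per_chain
    per parameter) with split-R-hat / ESS diagnostics; a convergence
    warning is raised (and recorded) when any R-hat exceeds the threshold.
    Fully reproducible for a given config (the seed lives in the config).
    """
    variant = get_variant(variant)
    stacked = data if isinstance(data, StackedData) else stack_sequences(data)
    condition = condition or stacked.condition
    if condition != stacked.condition:
        raise ValueError(
            f"data condition {stacked.condition!r} != requested {condition!r}"
        )
    names = param_names(variant)
    loglik_fn = _rl_loglik_fn(stacked, variant, condition)
    chains = sample_hierarchy(loglik_fn, stacked.n_subjects, len(names), config)
    post = PosteriorDraws(
        variant=variant,
        condition=condition,
        param_names=names,
        subjects=stacked.subjects,
        raw=np.stack([c.raw for c in chains]),
        mu=np.stack([c.mu for c in chains]),
        sigma=np.stack([c.sigma for c in chains]),
        loglik=np.stack([c.loglik for c in chains]),
        config=config,
        _stacked=stacked,
    )
    _diagnostics(post)
    return post
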