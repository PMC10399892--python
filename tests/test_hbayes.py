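"""Transforms, joint density and sampler correctness."""

import numpy as np
import pytest
from scipy import stats

from asymrl import hbayes, models, tasks
from asymrl.hbayes import (
    FitConfig,
    from_natural,
    joint_log_density,
    neg_lr_from_offset,
    phi,
    sample_hierarchy,
    sample_posterior,
    to_natural,
    trimmed_mean,
)

from conftest import random_sequence


# -- transforms -------------------------------------------------------------

def test_phi_values():
    assert phi(0.0) == 0.5
    assert phi(1.959964) == pytest.approx(0.975, abs=1e-6)
    x = np.linspace(-8, 8, 41)
    np.testing.assert_allclose(phi(x) + phi(-x), 1.0, atol=1e-12)


def test_to_natural_midpoints_and_limits():
    assert to_natural(0.0, 0.0, 20.0) == 10.0
    assert to_natural(0.0, -1.0, 0.0) == -0.5
    assert to_natural(-40.0, 0.0, 1.0) == 0.0
    assert to_natural(40.0, 0.0, 1.0) == 1.0
    with pytest.raises(ValueError):
        to_natural(0.0, 1.0, 1.0)


def test_transform_round_trip():
    raw = np.linspace(-6, 6, 121)
    for lo, hi in [(0.0, 1.0), (-1.0, 0.0), (0.0, 20.0), (-1.0, 1.0)]:
        back = from_natural(to_natural(raw, lo, hi), lo, hi)
        np.testing.assert_allclose(back, raw, atol=1e-8)
        nat = to_natural(raw, lo, hi)
        assert np.all(np.diff(nat) > 0)  # strictly monotone


def test_neg_lr_from_offset():
    assert neg_lr_from_offset(0.3, 0.0) == pytest.approx(phi(0.3))
    assert neg_lr_from_offset(0.0, 1.959964) == pytest.approx(0.975, abs=1e-6)
    # positive offset => alpha_n > alpha_p, for any alpha_p_raw
    for ar in [-2.0, 0.0, 2.0]:
        assert neg_lr_from_offset(ar, 0.5) > phi(ar)


@pytest.mark.parametrize(
    "samples, trim, expected",
    [
        (list(range(1, 11)), 0.10, 5.5),
        ([7.0] * 9, 0.2, 7.0),
        ([3.0, 1.0, 2.0], 0.0, 2.0),
    ],
)
def test_trimmed_mean_cases(samples, trim, expected):
    assert trimmed_mean(samples, trim) == pytest.approx(expected)


def test_trimmed_mean_errors():
    with pytest.raises(ValueError):
        trimmed_mean([], 0.1)
    with pytest.raises(ValueError):
        trimmed_mean([1.0], 0.5)


# -- joint density ----------------------------------------------------------

def test_joint_log_density_term_oracle(rng):
    """Matches an independently assembled prior + likelihood sum."""
    seqs = [random_sequence(rng, n_trials=20), random_sequence(rng, n_trials=20)]
    mu = np.array([0.1, -0.2, 0.3, 0.0])
    sigma = np.array([0.5, 1.0, 2.0, 0.8])
    raw = rng.normal(size=(2, 4))
    got = joint_log_density(mu, sigma, raw, seqs, "A-VI", "gain")

    expected = stats.norm.logpdf(mu, 0, 2).sum()
    expected += stats.halfcauchy.logpdf(sigma, scale=5).sum()
    for i in range(2):
        expected += stats.norm.logpdf(raw[i], mu, sigma).sum()
        p = models.AgentParams(
            q0=float(to_natural(raw[i, 0], 0, 1)),
            alpha_p=float(phi(raw[i, 1])),
            alpha_n=float(neg_lr_from_offset(raw[i, 1], raw[i, 2])),
            beta=float(to_natural(raw[i, 3], 0, 20)),
        )
        expected += models.log_likelihood(p, "A-VI", seqs[i])
    assert got == pytest.approx(expected, abs=1e-10)


def test_joint_log_density_edge_cases(rng):
    # zero subjects: hyper-prior only
    mu = np.zeros(4)
    sigma = np.ones(4)
    got = joint_log_density(mu, sigma, np.zeros((0, 4)), None, "A-VI", "gain")
    expected = stats.norm.logpdf(mu, 0, 2).sum() + stats.halfcauchy.logpdf(sigma, scale=5).sum()
    assert got == pytest.approx(expected, abs=1e-10)
    # flat-choice limit: beta_raw -> -inf makes the data term T log 0.5
    seq = random_sequence(rng, n_trials=30)
    raw = np.array([[0.0, 0.0, 0.0, -40.0]])
    with_data = joint_log_density(mu, sigma, raw, [seq], "A-VI", "gain")
    without = joint_log_density(mu, sigma, raw, None, "A-VI", "gain")
    assert with_data - without == pytest.approx(30 * np.log(0.5), abs=1e-10)
    with pytest.raises(ValueError, match="positive"):
        joint_log_density(mu, np.zeros(4), raw, None, "A-VI", "gain")


# -- sampler ----------------------------------------------------------------

def test_conjugate_posterior_oracle():
    """With fixed hypers and a normal likelihood the sampler must match
    the normal-normal closed form posterior per subject."""
    prior_mu, prior_sd = 0.4, 0.8
    lik_sd = 0.5
    y = np.array([1.2, -0.3, 0.7, 2.0, 0.0])
    S = len(y)

    def loglik(raw):
        return stats.norm.logpdf(y, raw[:, 0], lik_sd)

    cfg = FitConfig(n_chains=2, n_warmup=500, n_keep_per_chain=2000, seed=4)
    chains = sample_hierarchy(
        loglik, S, 1, cfg, fixed_hypers=(np.array([prior_mu]), np.array([prior_sd]))
    )
    draws = np.concatenate([c.raw[:, :, 0] for c in chains], axis=0)  # (draws, S)

    post_prec = 1 / prior_sd**2 + 1 / lik_sd**2
    post_mean = (prior_mu / prior_sd**2 + y / lik_sd**2) / post_prec
    post_sd = np.sqrt(1 / post_prec)
    # MCMC error allowance: generous multiple of the naive MC s.e.
    assert np.abs(draws.mean(axis=0) - post_mean).max() < 6 * post_sd / np.sqrt(200)
    np.testing.assert_allclose(draws.std(axis=0), post_sd, rtol=0.12)


def test_prior_only_hyper_marginals():
    """With a flat likelihood the hyper-mean marginal is its prior N(0, 2)."""
    def loglik(raw):
        return np.zeros(raw.shape[0])

    cfg = FitConfig(n_chains=2, n_warmup=1000, n_keep_per_chain=3000, seed=8)
    chains = sample_hierarchy(loglik, 3, 1, cfg)
    mu = np.concatenate([c.mu[:, 0] for c in chains])
    assert abs(np.mean(mu)) < 0.35
    assert 1.6 < np.std(mu) < 2.5


def test_fit_is_deterministic_and_counts_draws(gain_walk_dataset, tiny_fit_config):
    post1 = sample_posterior(gain_walk_dataset.sequences, "A-VI", config=tiny_fit_config)
    post2 = sample_posterior(gain_walk_dataset.sequences, "A-VI", config=tiny_fit_config)
    np.testing.assert_array_equal(post1.mu, post2.mu)
    np.testing.assert_array_equal(post1.raw, post2.raw)
    assert post1.n_draws == tiny_fit_config.total_draws == 600
    assert post1.raw.shape == (2, 300, 12, 4)
    # natural-scale draws respect their bounds
    nat = post1.natural_draws()
    assert nat["q0"].min() >= 0.0 and nat["q0"].max() <= 1.0
    assert nat["alpha_p"].min() >= 0.0 and nat["alpha_p"].max() <= 1.0
    assert nat["beta"].min() >= 0.0 and nat["beta"].max() <= 20.0
    # summaries carry diagnostics for every hyper parameter
    summary = post1.summary()
    assert set(summary["parameter"]) == {
        f"{kind}_{name}" for kind in ("mu", "sigma")
        for name in ("q0_raw", "alpha_p_raw", "asym_offset", "beta_raw")
    }
    assert summary["rhat"].notna().all()


def test_default_chain_geometry_arithmetic():
    cfg = FitConfig()
    assert (cfg.n_chains, cfg.n_warmup, cfg.n_keep_per_chain) == (4, 4000, 6000)
    assert cfg.total_draws == 24_000
    with pytest.raises(ValueError):
        FitConfig(n_chains=0)
    with pytest.raises(ValueError):
        FitConfig(trim_fraction=0.6)


def test_subject_recovery_rank_order(tiny_fit_config):
    """Subject-level estimates track heterogeneous true learning rates."""
    rng = np.random.default_rng(17)
    true_ap = np.linspace(0.1, 0.8, 16)
    seqs = []
    for i, ap in enumerate(true_ap):
        sched = tasks.make_random_walk_schedule("gain", 100, rng)
        p = models.AgentParams(q0=0.2, alpha_p=float(ap), alpha_n=float(ap), beta=8.0)
        seqs.append(tasks.simulate_agent(p, "A-VI", sched, rng, subject=i))
    cfg = hbayes.FitConfig(n_chains=2, n_warmup=600, n_keep_per_chain=600, seed=2)
    post = sample_posterior(seqs, "S-VI", config=cfg)
    est = post.subject_estimates()["alpha_p"].to_numpy()
    r = np.corrcoef(true_ap, est)[0, 1]
    assert r > 0.5


def test_symmetric_data_covers_zero_asymmetry(gain_walk_dataset):
    """A-VI's mu_delta interval covers 0 when alpha_p == alpha_n... but the
    fixture's truth is asymmetric (0.3, 0.5), so the check runs on fresh
    symmetric data."""
    design = tasks.RecoveryGridDesign(
        q0_levels=(0.25,), lr_pairs=((0.4, 0.4),), n_datasets_per_cell=1,
    )
    ds = tasks.simulate_grid(design, seed=21)[0]
    post = sample_posterior(ds.sequences, "A-VI", config=hbayes.FitConfig.test(seed=5))
    lo, hi = np.quantile(post.mu_delta_draws(), [0.025, 0.975])
    assert lo <= 0.0 <= hi
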