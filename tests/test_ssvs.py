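"""Spike-and-slab Gibbs sampler: PG moments, conjugate and exact-posterior
oracles, prior recovery, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from dapsel import (
    Comparison,
    SSVSConfig,
    SSVSDraws,
    compute_pip,
    run_gibbs,
    sample_polya_gamma,
)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# Polya-Gamma sampler moments
# ---------------------------------------------------------------------------

def test_pg_mean_at_zero_tilt():
    x = sample_polya_gamma(1, 0.0, size=100_000, seed=1)
    se = x.std(ddof=1) / math.sqrt(len(x))
    assert abs(x.mean() - 0.25) < 3 * se


def test_pg_mean_at_tilt_two():
    x = sample_polya_gamma(1, 2.0, size=100_000, seed=2)
    se = x.std(ddof=1) / math.sqrt(len(x))
    assert abs(x.mean() - 0.25 * math.tanh(1.0)) < 3 * se


@pytest.mark.parametrize("c", [0.5, 3.0])
def test_pg_additivity_in_shape(c):
    x1 = sample_polya_gamma(1, c, size=60_000, seed=3)
    x2 = sample_polya_gamma(2, c, size=60_000, seed=4)
    se = math.sqrt(x1.var() / len(x1) + x2.var() / len(x2))
    assert abs(x2.mean() - 2 * x1.mean()) < 4 * se


def test_pg_large_tilt_and_symmetry():
    x = sample_polya_gamma(1, 12.0, size=50_000, seed=5)
    xm = sample_polya_gamma(1, -12.0, size=50_000, seed=5)
    assert np.array_equal(x, xm)  # law depends on |c|; same seed, same draws
    se = x.std(ddof=1) / math.sqrt(len(x))
    assert abs(x.mean() - math.tanh(6.0) / 24.0) < 3 * se


def test_pg_shape_validation():
    with pytest.raises(ValueError):
        sample_polya_gamma(0, 1.0)
    with pytest.raises(ValueError):
        sample_polya_gamma(-1, 1.0)
    with pytest.raises(ValueError):
        sample_polya_gamma(1.5, 1.0)


# ---------------------------------------------------------------------------
# Gibbs sampler oracles
# ---------------------------------------------------------------------------

def _two_class_matrix(X, y):
    groups = ["A" if v else "B" for v in y]
    return make_matrix(X.T, groups), Comparison("A_vs_B", "A", "B")


def test_w_zero_reduces_to_intercept_only_logistic():
    """With zero prior inclusion probability no feature ever enters, and the
    intercept chain matches the exact intercept-only posterior (quadrature)."""
    rng = np.random.default_rng(0)
    y = np.array([1.0] * 8 + [0.0] * 4)
    X = rng.normal(size=(12, 5))
    data, cmp = _two_class_matrix(X, y)
    cfg = SSVSConfig(w_prior=0.0, n_iter=20_000, n_burnin=2_000, seed=7)
    draws = run_gibbs(data, cmp, cfg)
    assert np.all(draws.gamma == 0)
    assert np.all(draws.beta == 0.0)

    # exact intercept-only posterior: N(0, 100) prior, Bernoulli likelihood
    b0 = np.linspace(-8, 8, 4001)
    loglik = 8 * b0 - 12 * np.logaddexp(0, b0)
    logpost = loglik - 0.5 * b0**2 / 100.0
    w = np.exp(logpost - logpost.max())
    exact_mean = (b0 * w).sum() / w.sum()
    chain = draws.beta0[2_000:]
    mc_se = 3 * chain.std() / math.sqrt(len(chain) / 10)  # conservative ESS
    assert abs(chain.mean() - exact_mean) < max(mc_se, 0.05)


def test_w_one_single_feature_sign():
    y = np.array([1.0] * 6 + [0.0] * 6)
    X = (2.0 * y - 1.0 + 0.1 * np.random.default_rng(1).normal(size=12)).reshape(-1, 1)
    data, cmp = _two_class_matrix(X, y)
    cfg = SSVSConfig(w_prior=1.0, n_iter=4_000, n_burnin=1_000, seed=3)
    summary = compute_pip(run_gibbs(data, cmp, cfg), cfg)
    assert summary.pip.iloc[0] == 1.0
    assert summary.post_mean_beta.iloc[0] > 0


def test_fixed_phi_matches_conjugate_normal_posterior():
    """Freezing the PG latents makes the model linear-Gaussian; with w = 1,
    p = 1 and a near-degenerate slab the (beta0, beta) draws must match the
    closed-form normal posterior."""
    rng = np.random.default_rng(5)
    y = np.array([1.0] * 6 + [0.0] * 6)
    X = rng.normal(size=(12, 1))
    X[:, 0] += y
    data, cmp = _two_class_matrix(X, y)
    phi = np.full(12, 0.3)
    s2 = 1.0
    cfg = SSVSConfig(
        w_prior=1.0, a_hyper=5e4, b_hyper=5e4 - 1, n_iter=40_000, n_burnin=2_000,
        seed=11, intercept_var=100.0,
    )
    draws = run_gibbs(data, cmp, cfg, fixed_phi=phi)

    xs = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std()
    kappa = y - 0.5
    A = np.array(
        [
            [phi.sum() + 1 / 100.0, (phi * xs).sum()],
            [(phi * xs).sum(), (phi * xs * xs).sum() + 1 / s2],
        ]
    )
    S = np.array([kappa.sum(), (xs * kappa).sum()])
    mean = np.linalg.solve(A, S)
    cov = np.linalg.inv(A)

    sample = np.column_stack([draws.beta0[2_000:], draws.beta[2_000:, 0]])
    got_mean = sample.mean(axis=0)
    got_cov = np.cov(sample.T)
    assert np.abs(got_mean - mean).max() < 0.04
    assert np.abs(got_cov - cov).max() < 0.06 * max(1.0, np.abs(cov).max())


def test_pips_match_exact_enumeration_posterior():
    """Two features, near-fixed slab variance: Gibbs inclusion probabilities
    agree with the exact posterior obtained by enumerating the four models
    and integrating (beta0, betas) on a dense grid."""
    rng = np.random.default_rng(42)
    n, p = 12, 2
    y = np.array([1.0] * 6 + [0.0] * 6)
    X = rng.normal(size=(n, p))
    X[:, 0] += y * 1.5
    Xs = (X - X.mean(0)) / X.std(0)
    w, s2, icpt_var = 0.2, 1.0, 100.0

    from numpy.polynomial.legendre import leggauss
    from itertools import product

    g, wts = leggauss(60)
    pts = 12.0 * g
    wq = 12.0 * wts

    def marg_lik(active):
        dims = 1 + len(active)
        grids = np.meshgrid(*([pts] * dims), indexing="ij")
        ll = np.zeros(grids[0].shape)
        for i in range(n):
            eta = grids[0] + sum(Xs[i, a] * grids[1 + j] for j, a in enumerate(active))
            ll += -(np.logaddexp(0, eta) - y[i] * eta)
        lp = ll - 0.5 * grids[0] ** 2 / icpt_var - 0.5 * np.log(2 * np.pi * icpt_var)
        for j in range(len(active)):
            lp += -0.5 * grids[1 + j] ** 2 / s2 - 0.5 * np.log(2 * np.pi * s2)
        wgrid = np.ones_like(grids[0])
        for d in range(dims):
            shape = [1] * dims
            shape[d] = -1
            wgrid = wgrid * wq.reshape(shape)
        m = lp.max()
        return m + np.log((np.exp(lp - m) * wgrid).sum())

    logpost = {}
    for r in product([0, 1], repeat=p):
        act = [i for i in range(p) if r[i]]
        logpost[r] = marg_lik(act) + sum(
            np.log(w) if ri else np.log(1 - w) for ri in r
        )
    mx = max(logpost.values())
    Z = sum(np.exp(v - mx) for v in logpost.values())
    exact_pip = np.array(
        [sum(np.exp(v - mx) / Z for r, v in logpost.items() if r[j]) for j in range(p)]
    )

    data, cmp = _two_class_matrix(X, y)
    pips = []
    for seed in (0, 1, 2):
        cfg = SSVSConfig(
            w_prior=w, a_hyper=400.0, b_hyper=399.0, n_iter=30_000, n_burnin=3_000,
            seed=seed,
        )
        pips.append(compute_pip(run_gibbs(data, cmp, cfg), cfg).pip.to_numpy())
    got = np.mean(pips, axis=0)
    assert np.abs(got - exact_pip).max() < 0.03


def test_prior_recovery_under_diffuse_likelihood():
    """Tiny n, null data: the average inclusion probability returns the
    Bernoulli prior w."""
    rng = np.random.default_rng(8)
    y = np.array([1.0, 1.0, 0.0, 0.0])
    X = rng.normal(size=(4, 50))
    data, cmp = _two_class_matrix(X, y)
    means = []
    for seed in (1, 2, 3):
        cfg = SSVSConfig(n_iter=4_000, n_burnin=1_000, seed=seed)
        means.append(compute_pip(run_gibbs(data, cmp, cfg), cfg).pip.mean())
    assert abs(np.mean(means) - 0.05) < 0.015


def test_spike_is_exact_zero_and_chain_deterministic(corrected_two_group):
    adj, cmp, _ = corrected_two_group
    cfg = SSVSConfig(n_iter=400, n_burnin=100, seed=13)
    d1 = run_gibbs(adj, cmp, cfg)
    d2 = run_gibbs(adj, cmp, cfg)
    assert np.array_equal(d1.beta, d2.beta)
    assert np.array_equal(d1.gamma, d2.gamma)
    assert np.array_equal(d1.sigma2, d2.sigma2)
    # bitwise spike: excluded coefficient is exactly zero in every sweep
    assert np.all(d1.beta[d1.gamma == 0] == 0.0)
    assert np.all(d1.beta[d1.gamma == 1] != 0.0)
    assert np.all(d1.sigma2 > 0)


def test_intercept_chain_geweke_stationarity(corrected_two_group):
    adj, cmp, _ = corrected_two_group
    cfg = SSVSConfig(n_iter=5_000, n_burnin=1_000, seed=21)
    draws = run_gibbs(adj, cmp, cfg)
    from dapsel.ssvs import _ess_columns

    chain = draws.beta0[1_000:]
    a = chain[: len(chain) // 10]
    b = chain[len(chain) // 2:]
    # autocorrelation-adjusted variances (Geweke's spectral estimate)
    ess_a = _ess_columns(a[:, None])[0]
    ess_b = _ess_columns(b[:, None])[0]
    z = (a.mean() - b.mean()) / math.sqrt(a.var() / ess_a + b.var() / ess_b)
    assert abs(z) < 3.0


def test_constant_feature_excluded_with_warning(caplog):
    rng = np.random.default_rng(2)
    X = rng.normal(size=(8, 4))
    X[:, 2] = 5.0
    y = np.array([1.0] * 4 + [0.0] * 4)
    data, cmp = _two_class_matrix(X, y)
    cfg = SSVSConfig(n_iter=300, n_burnin=100, seed=1)
    with caplog.at_level("WARNING", logger="dapsel"):
        draws = run_gibbs(data, cmp, cfg)
    assert len(draws.feature_ids) == 3
    assert draws.excluded_ids == ["f2"]
    assert "constant" in caplog.text


def test_compute_pip_arithmetic_and_errors():
    gamma = np.array([[1, 1], [0, 1], [1, 1], [0, 1]], dtype=np.int8)
    beta = np.array([[2.0, 1.0], [0.0, 1.0], [4.0, 1.0], [0.0, 1.0]])
    draws = SSVSDraws(
        feature_ids=["a", "b"],
        excluded_ids=[],
        beta0=np.zeros(4),
        beta=beta,
        gamma=gamma,
        sigma2=np.ones((4, 2)),
        phi=np.ones(2),
    )
    cfg = SSVSConfig(n_iter=4, n_burnin=0, seed=0)
    s = compute_pip(draws, cfg)
    assert s.pip["a"] == pytest.approx(0.5)
    assert s.pip["b"] == pytest.approx(1.0)
    assert s.post_mean_beta["a"] == pytest.approx(3.0)  # mean over included draws
    with pytest.raises(ValueError):
        compute_pip(draws, SSVSConfig(n_iter=5, n_burnin=4, seed=0))


def test_config_validation():
    with pytest.raises(ValueError):
        SSVSConfig(seed=None)
    with pytest.raises(ValueError):
        SSVSConfig(w_prior=1.2, seed=1)
    with pytest.raises(ValueError):
        SSVSConfig(n_iter=100, n_burnin=100, seed=1)
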