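"""Bayesian spike-and-slab logistic regression (stochastic search variable
selection) with Polya-Gamma data augmentation.

Model, per comparison with binary response y and standardized features x:

    logit P(y_i = 1) = beta_0 + sum_j x_ij beta_j
    beta_j | r_j  ~ (1 - r_j) * delta_0 + r_j * N(0, sigma_j^2)
    r_j | w       ~ Bernoulli(w)            (w fixed, default 0.05)
    sigma_j^2     ~ Inverse-Gamma(a, b)     (default a = b = 0.1)

Polya-Gamma augmentation introduces one latent phi_i ~ PG(1, v_i) per
sample (v_i the linear predictor), under which the conditional model is
Gaussian in the working response kappa_i = y_i - 1/2 with per-sample
precision phi_i.  The Gibbs sweep is then exact: (1) draw each phi_i from
PG(1, v_i) by Devroye rejection sampling; (2) update the intercept from its
Gaussian conditional; (3) sweep features in fixed index order, drawing each
(r_j, beta_j) jointly from the exact spike-and-slab conditional (the
inclusion odds marginalize beta_j analytically); (4) draw sigma_j^2 from
Inverse-Gamma(a + r_j/2, b + r_j beta_j^2 / 2) -- the prior itself when the
feature is excluded, keeping the chain irreducible.  The posterior mean of
the r_j chain is the feature's posterior inclusion probability (PIP).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .data import Comparison, IntensityMatrix

logger = logging.getLogger("dapsel")

_TRUNC = 0.64
_PI = math.pi


@dataclass
class SSVSConfig:
    w_prior: float = 0.05
    a_hyper: float = 0.1
    b_hyper: float = 0.1
    n_iter: int = 5000
    n_burnin: int = 1000
    thin: int = 1
    seed: int | None = None
    intercept_var: float = 100.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SSVSConfig.seed is required")
        if not 0.0 <= self.w_prior <= 1.0:
            raise ValueError("w_prior must lie in [0, 1]")
        if self.a_hyper <= 0 or self.b_hyper <= 0:
            raise ValueError("Inverse-Gamma hyperparameters must be > 0")
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")


@dataclass
class SSVSDraws:
    feature_ids: list[str]        # features actually sampled
    excluded_ids: list[str]       # constant features dropped before sampling
    beta0: np.ndarray             # iteration vector
    beta: np.ndarray              # iteration x feature
    gamma: np.ndarray             # iteration x feature, {0,1}
    sigma2: np.ndarray            # iteration x feature
    phi: np.ndarray               # final-state PG latents per sample
    config: SSVSConfig | None = None


@dataclass
class SSVSSummary:
    pip: pd.Series                # posterior inclusion probability
    post_mean_beta: pd.Series     # mean beta over included draws (0 if never)
    ess: pd.Series                # effective sample size of each gamma chain


# ---------------------------------------------------------------------------
# Polya-Gamma PG(1, c) sampling: exact Devroye rejection sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _a_coef(n, x):
    # alternating-series coefficients of the Jacobi J*(1, .) density
    nph = n + 0.5
    if x <= _TRUNC:
        return _PI * nph * (2.0 / (_PI * x)) ** 1.5 * math.exp(-2.0 * nph * nph / x)
    return _PI * nph * math.exp(-0.5 * nph * nph * _PI * _PI * x)


@njit(cache=True)
def _rtigauss(z, t):
    # inverse-Gaussian(mu=1/z, lambda=1) restricted to (0, t]
    X = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from the scaled inverse-chi-square tail
        alpha = 0.0
        while np.random.uniform(0.0, 1.0) > alpha:
            E1 = np.random.exponential(1.0)
            E2 = np.random.exponential(1.0)
            while E1 * E1 > 2.0 * E2 / t:
                E1 = np.random.exponential(1.0)
                E2 = np.random.exponential(1.0)
            X = t / ((1.0 + t * E1) * (1.0 + t * E1))
            alpha = math.exp(-0.5 * z * z * X)
    else:
        mu = 1.0 / z
        while X > t:
            Y = np.random.normal(0.0, 1.0)
            Y = Y * Y
            muY = mu * Y
            X = mu + 0.5 * mu * muY - 0.5 * mu * math.sqrt(4.0 * muY + muY * muY)
            if np.random.uniform(0.0, 1.0) > mu / (mu + X):
                X = mu * mu / X
    return X


@njit(cache=True)
def _mass_texpon(z):
    # probability of proposing from the (truncated-exponential) right piece
    t = _TRUNC
    K = 0.125 * _PI * _PI + 0.5 * z * z
    sqt = math.sqrt(t)
    cb = _norm_cdf((t * z - 1.0) / sqt)
    ca = _norm_cdf(-(t * z + 1.0) / sqt)
    x0 = math.log(K) + K * t
    xb = x0 - z + (math.log(cb) if cb > 0.0 else -np.inf)
    xa = x0 + z + (math.log(ca) if ca > 0.0 else -np.inf)
    qdivp = 4.0 / _PI * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _sample_pg1(c):
    # PG(1, c) = J*(1, c/2) / 4
    z = 0.5 * abs(c)
    K = 0.125 * _PI * _PI + 0.5 * z * z
    p_right = _mass_texpon(z)
    while True:
        if np.random.uniform(0.0, 1.0) < p_right:
            X = _TRUNC + np.random.exponential(1.0) / K
        else:
            X = _rtigauss(z, _TRUNC)
        S = _a_coef(0, X)
        Y = np.random.uniform(0.0, 1.0) * S
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                S -= _a_coef(n, X)
                if Y <= S:
                    return 0.25 * X
            else:
                S += _a_coef(n, X)
                if Y > S:
                    break


@njit(cache=True)
def _pg_batch(b, c, m, seed):
    np.random.seed(seed)
    out = np.empty(m)
    for i in range(m):
        acc = 0.0
        for _ in range(b):
            acc += _sample_pg1(c)
        out[i] = acc
    return out


def sample_polya_gamma(b: int, c: float, size: int | None = None, seed: int = 0):
    """Draw from the Polya-Gamma PG(b, c) law (b a positive integer).

    PG(b, c) is the b-fold convolution of PG(1, c); E[PG(b, c)] =
    (b / 2c) tanh(c / 2), and b/4 at c = 0.
    """
    if not (isinstance(b, (int, np.integer)) and b > 0):
        raise ValueError("b must be a positive integer")
    m = 1 if size is None else int(size)
    out = _pg_batch(int(b), float(c), m, int(seed))
    return float(out[0]) if size is None else out


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_core(X, kappa, w, a, b, n_iter, intercept_var, seed, fixed_phi, use_fixed_phi):
    np.random.seed(seed)
    n, p = X.shape
    beta = np.zeros(p)
    gamma = np.zeros(p, dtype=np.int8)
    sigma2 = np.ones(p)
    beta0 = 0.0
    v = np.zeros(n)
    phi = np.full(n, 0.25)

    out_beta0 = np.zeros(n_iter)
    out_beta = np.zeros((n_iter, p))
    out_gamma = np.zeros((n_iter, p), dtype=np.int8)
    out_sigma2 = np.zeros((n_iter, p))

    for it in range(n_iter):
        # (1) Polya-Gamma latents from the current linear predictor
        if use_fixed_phi:
            for i in range(n):
                phi[i] = fixed_phi[i]
        else:
            for i in range(n):
                phi[i] = _sample_pg1(v[i])

        # (2) intercept from its Gaussian conditional
        prec0 = 1.0 / intercept_var
        S0 = 0.0
        for i in range(n):
            prec0 += phi[i]
            S0 += kappa[i] - phi[i] * (v[i] - beta0)
        new0 = S0 / prec0 + np.random.normal(0.0, 1.0) / math.sqrt(prec0)
        for i in range(n):
            v[i] += new0 - beta0
        beta0 = new0

        # (3) spike-and-slab feature updates, fixed index order
        for j in range(p):
            bj_old = beta[j]
            S = 0.0
            tau0 = 0.0
            for i in range(n):
                vm = v[i] - X[i, j] * bj_old
                S += X[i, j] * (kappa[i] - phi[i] * vm)
                tau0 += phi[i] * X[i, j] * X[i, j]
            tau = tau0 + 1.0 / sigma2[j]
            if w <= 0.0:
                include = False
            elif w >= 1.0:
                include = True
            else:
                log_odds = (
                    math.log(w / (1.0 - w))
                    - 0.5 * math.log(sigma2[j] * tau)
                    + 0.5 * S * S / tau
                )
                if log_odds > 35.0:
                    include = True
                elif log_odds < -35.0:
                    include = False
                else:
                    pr = 1.0 / (1.0 + math.exp(-log_odds))
                    include = np.random.uniform(0.0, 1.0) < pr
            if include:
                bj = S / tau + np.random.normal(0.0, 1.0) / math.sqrt(tau)
                gamma[j] = 1
            else:
                bj = 0.0
                gamma[j] = 0
            if bj != bj_old:
                for i in range(n):
                    v[i] += X[i, j] * (bj - bj_old)
            beta[j] = bj

            # (4) slab variance: conditional when included, prior otherwise
            if gamma[j] == 1:
                shape = a + 0.5
                rate = b + 0.5 * bj * bj
            else:
                shape = a
                rate = b
            sigma2[j] = rate / np.random.gamma(shape, 1.0)

        out_beta0[it] = beta0
        for j in range(p):
            out_beta[it, j] = beta[j]
            out_gamma[it, j] = gamma[j]
            out_sigma2[it, j] = sigma2[j]

        # NaN guard on the linear predictor
        for i in range(n):
            if not np.isfinite(v[i]):
                return out_beta0[: it + 1], out_beta[: it + 1], out_gamma[: it + 1], out_sigma2[: it + 1], phi, it
    return out_beta0, out_beta, out_gamma, out_sigma2, phi, -1


def run_gibbs(
    data: IntensityMatrix,
    cmp: Comparison,
    cfg: SSVSConfig,
    fixed_phi: np.ndarray | None = None,
) -> SSVSDraws:
    """Run the spike-and-slab Gibbs sampler for one comparison.

    Features are standardized within the comparison; constant features are
    excluded with a warning.  ``fixed_phi`` freezes the Polya-Gamma latents
    (the conditional model is then linear-Gaussian), used for conjugate
    cross-checks.
    """
    X, y, feature_ids = cmp.subset(data)
    std = X.std(axis=0)
    keep = std > 0
    if not keep.all():
        logger.warning(
            "%s: excluding %d constant feature(s) from SSVS", cmp.name, int((~keep).sum())
        )
    kept_ids = [f for f, k in zip(feature_ids, keep) if k]
    excluded = [f for f, k in zip(feature_ids, keep) if not k]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    kappa = y - 0.5

    use_fixed = fixed_phi is not None
    phi_arr = np.asarray(fixed_phi, dtype=float) if use_fixed else np.zeros(len(y))
    b0, bdraws, gdraws, s2draws, phi, bad_it = _gibbs_core(
        np.ascontiguousarray(Xs),
        kappa,
        float(cfg.w_prior),
        float(cfg.a_hyper),
        float(cfg.b_hyper),
        int(cfg.n_iter),
        float(cfg.intercept_var),
        int(cfg.seed),
        phi_arr,
        use_fixed,
    )
    if bad_it >= 0:
        raise RuntimeError(f"non-finite linear predictor at Gibbs iteration {bad_it}")
    return SSVSDraws(
        feature_ids=kept_ids,
        excluded_ids=excluded,
        beta0=b0,
        beta=bdraws,
        gamma=gdraws,
        sigma2=s2draws,
        phi=phi,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _ess_columns(chains: np.ndarray) -> np.ndarray:
    """Effective sample size per column via the initial-positive-sequence
    truncation of the FFT autocorrelation."""
    T, p = chains.shape
    x = chains - chains.mean(axis=0, keepdims=True)
    var = (x**2).mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * T)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:T].real / T
    out = np.empty(p)
    for j in range(p):
        if var[j] <= 0:
            out[j] = float(T)
            continue
        rho = acov[:, j] / acov[0, j]
        s = 0.0
        for t in range(1, T):
            if rho[t] <= 0:
                break
            s += rho[t]
        out[j] = T / (1.0 + 2.0 * s)
    return out


def compute_pip(draws: SSVSDraws, cfg: SSVSConfig | None = None) -> SSVSSummary:
    """Posterior inclusion probabilities and conditional posterior means."""
    cfg = cfg or draws.config
    retained = slice(cfg.n_burnin, None, cfg.thin)
    g = draws.gamma[retained].astype(float)
    b = draws.beta[retained]
    if g.shape[0] == 0:
        raise ValueError("no retained draws after burn-in/thinning")
    pip = g.mean(axis=0)
    n_inc = g.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pm = np.where(n_inc > 0, (b * g).sum(axis=0) / np.maximum(n_inc, 1.0), 0.0)
    ess = _ess_columns(g)
    idx = draws.feature_ids
    return SSVSSummary(
        pip=pd.Series(pip, index=idx),
        post_mean_beta=pd.Series(pm, index=idx),
        ess=pd.Series(ess, index=idx),
    )


def ssvs_table(summary: SSVSSummary, selected_ids: list[str] | None = None) -> pd.DataFrame:
    sel = set(selected_ids or [])
    return pd.DataFrame(
        {
            "feature_id": summary.pip.index,
            "pip": summary.pip.to_numpy(),
            "post_mean_beta": summary.post_mean_beta.to_numpy(),
            "selected": [f in sel for f in summary.pip.index],
            "direction": [
                ("up" if summary.post_mean_beta[f] > 0 else "down") if f in sel else ""
                for f in summary.pip.index
            ],
        }
    )
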