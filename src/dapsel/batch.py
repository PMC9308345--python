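"""Batch-effect correction by a crossed-random-effects linear mixed model.

Model (per feature k, group g, replicate j; one observation per cell):

    y_kgj = mu_kg + b_j + s_kj + e_kgj,
    b_j ~ N(0, var_r),  s_kj ~ N(0, var_s),  e ~ N(0, var_e),

where mu_kg is a fixed per-(feature, group) mean, b_j a replicate (batch)
effect shared by all features and groups, and s_kj a feature x replicate
interaction.  Variance components are estimated by maximum likelihood; the
batch correction subtracts the BLUP of s_kj from each observation (group
effects and b_j are deliberately retained).

Estimation exploits the balanced design.  OLS cell means equal the GLS
fixed-effect estimates for any variance components here, and the profiled
likelihood decomposes over three mutually orthogonal eigenspaces of the
per-replicate covariance block (block mean; feature contrasts of replicate
means; within-(feature, replicate) contrasts), giving a closed-form ML
solution when it is interior and a bounded quasi-Newton solve otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import AdjustedMatrix, IntensityMatrix

logger = logging.getLogger("dapsel")

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class BatchModelFit:
    """ML variance components, fixed group means and random-effect BLUPs."""

    fixed_effects: pd.DataFrame   # features x groups cell means
    blup_b: pd.Series             # replicate -> predicted batch effect
    blup_s: pd.DataFrame          # features x replicates predicted interactions
    var_r: float
    var_s: float
    var_e: float
    loglik: float


@dataclass
class PCAResult:
    """Sample scores and per-component percent variance explained."""

    scores: pd.DataFrame          # samples x components
    var_explained: np.ndarray     # percent, over all components


# ---------------------------------------------------------------------------
# LMM fitting
# ---------------------------------------------------------------------------

def _design(data: IntensityMatrix):
    """Validate the balanced (group x replicate) layout and index it."""
    groups = data.groups()
    reps = sorted({s.replicate for s in data.samples})
    G, J = len(groups), len(reps)
    if G < 2:
        raise ValueError("need >= 2 groups to separate interaction from residual")
    if J < 2:
        raise ValueError("single-replicate design: replicate variance unidentifiable")
    if data.n_features < 2:
        raise ValueError("need >= 2 features")
    cell = {}
    for idx, s in enumerate(data.samples):
        key = (s.group, s.replicate)
        if key in cell:
            raise ValueError(f"duplicate (group, replicate) cell {key}")
        cell[key] = idx
    for g in groups:
        for j in reps:
            if (g, j) not in cell:
                raise ValueError(f"unbalanced design: missing cell (group={g}, replicate={j})")
    g_of = np.array([groups.index(s.group) for s in data.samples])
    j_of = np.array([reps.index(s.replicate) for s in data.samples])
    return groups, reps, g_of, j_of


def _neg2loglik(var: np.ndarray, stats: dict) -> float:
    var_r, var_s, var_e = np.maximum(var, 1e-12)
    p, G, J = stats["p"], stats["G"], stats["J"]
    lamA = var_e + G * var_s + p * G * var_r
    lamB = var_e + G * var_s
    lamC = var_e
    return (
        p * G * J * _LOG2PI
        + J * (np.log(lamA) + (p - 1) * np.log(lamB) + p * (G - 1) * np.log(lamC))
        + stats["SA"] / lamA
        + stats["SB"] / lamB
        + stats["SC"] / lamC
    )


def fit_lmm(data: IntensityMatrix) -> BatchModelFit:
    """Fit the crossed LMM by maximum likelihood and compute BLUPs."""
    groups, reps, g_of, j_of = _design(data)
    Y = data.values.to_numpy()
    p, G, J = data.n_features, len(groups), len(reps)

    # fixed effects: per-(feature, group) means (OLS = GLS in this design)
    cellmeans = np.empty((p, G))
    for gi in range(G):
        cellmeans[:, gi] = Y[:, g_of == gi].mean(axis=1)
    R = Y - cellmeans[:, g_of]

    # replicate-level summaries feeding the three orthogonal eigenspaces
    rbar_kj = np.empty((p, J))
    for ji in range(J):
        rbar_kj[:, ji] = R[:, j_of == ji].mean(axis=1)
    rbar_j = rbar_kj.mean(axis=0)

    SA = p * G * float(np.sum(rbar_j**2))
    SB = G * float(np.sum((rbar_kj - rbar_j[None, :]) ** 2))
    SC = float(np.sum((R - rbar_kj[:, j_of]) ** 2))
    stats = {"p": p, "G": G, "J": J, "SA": SA, "SB": SB, "SC": SC}

    # closed-form ML in the eigenvalue parameterization
    lamA = SA / J
    lamB = SB / (J * (p - 1))
    lamC = SC / (J * p * (G - 1))
    var_e = lamC
    var_s = (lamB - lamC) / G
    var_r = (lamA - lamB) / (p * G)

    if var_s < 0 or var_r < 0 or var_e <= 0:
        x0 = np.maximum([var_r, var_s, var_e], 1e-10)
        res = optimize.minimize(
            _neg2loglik,
            x0,
            args=(stats,),
            method="L-BFGS-B",
            bounds=[(0.0, None)] * 3,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if not res.success and res.status != 0:
            raise RuntimeError(f"LMM variance-component optimization failed: {res}")
        var_r, var_s, var_e = np.maximum(res.x, 0.0)

    loglik = -0.5 * _neg2loglik(np.array([var_r, var_s, var_e]), stats)

    # BLUPs at the ML estimates
    lamA = var_e + G * var_s + p * G * var_r
    lamB = var_e + G * var_s
    if lamA <= 0:
        blup_b = np.zeros(J)
        blup_s = np.zeros((p, J))
    else:
        blup_b = var_r * p * G * rbar_j / lamA
        if lamB <= 0:
            blup_s = np.zeros((p, J))
        else:
            blup_s = var_s * G * (
                (rbar_kj - rbar_j[None, :]) / lamB + rbar_j[None, :] / lamA
            )

    return BatchModelFit(
        fixed_effects=pd.DataFrame(cellmeans, index=data.feature_ids, columns=groups),
        blup_b=pd.Series(blup_b, index=reps),
        blup_s=pd.DataFrame(blup_s, index=data.feature_ids, columns=reps),
        var_r=float(var_r),
        var_s=float(var_s),
        var_e=float(var_e),
        loglik=float(loglik),
    )


def correct_batch(data: IntensityMatrix, fit: BatchModelFit) -> AdjustedMatrix:
    """Subtract the predicted feature x replicate effect from each entry.

    Only s_kj is removed; group means and the replicate main effect b_j are
    kept in the data.
    """
    if list(fit.blup_s.index) != data.feature_ids:
        raise ValueError("fit features do not match the matrix")
    reps = list(fit.blup_s.columns)
    for s in data.samples:
        if s.replicate not in reps:
            raise ValueError(f"sample {s.sample_id} has replicate {s.replicate} unseen by the fit")
    j_of = np.array([reps.index(s.replicate) for s in data.samples])
    adj = data.values.to_numpy() - fit.blup_s.to_numpy()[:, j_of]
    values = pd.DataFrame(adj, index=data.feature_ids, columns=data.sample_ids)
    return AdjustedMatrix(values, data.samples, provenance=fit)


# ---------------------------------------------------------------------------
# PCA quality control
# ---------------------------------------------------------------------------

def run_pca(data: IntensityMatrix, n_components: int = 2) -> PCAResult:
    """PCA of samples on feature-centered, unscaled intensities.

    Components are sorted by decreasing variance; each component's sign is
    fixed so its largest-magnitude feature loading is positive.
    """
    n, p = data.n_samples, data.n_features
    if n < 2:
        raise ValueError("need >= 2 samples for PCA")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= {min(n - 1, p)}")

    Y = data.values.to_numpy()
    M = (Y - Y.mean(axis=1, keepdims=True)).T  # samples x features, feature-centered
    U, S, Vt = np.linalg.svd(M, full_matrices=False)

    # deterministic signs from the loadings
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]

    variances = S**2
    total = variances.sum()
    var_explained = (
        100.0 * variances / total if total > 0 else np.zeros_like(variances)
    )
    scores = pd.DataFrame(
        (U * S[None, :])[:, :n_components],
        index=data.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PCAResult(scores=scores, var_explained=var_explained)
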