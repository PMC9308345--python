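"""Per-feature marginal regression with Bonferroni multiplicity control.

Each feature's adjusted intensity is regressed on the 0/1 group indicator:

    x_ik = beta_0 + y_i * beta_k + e_ik.

For a binary regressor the OLS slope is the difference of group means and
the t-test on beta_k is algebraically the pooled equal-variance two-sample
t-test with n - 2 degrees of freedom.  Raw two-sided p-values are adjusted
by p_adj = min(1, m * p_raw) with m the number of tested features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Comparison, IntensityMatrix

logger = logging.getLogger("dapsel")


@dataclass
class MarginalFit:
    feature_id: str
    beta0: float
    beta_k: float
    se: float
    t_stat: float
    df: int
    p_raw: float
    p_adj: float = np.nan
    residual_var: float = np.nan
    flagged: bool = False


@dataclass
class SelectionResult:
    """A selected feature set plus the control metadata that produced it."""

    method: str
    comparison: str
    selected_ids: list[str]
    control: dict = field(default_factory=dict)


def fit_marginal(data: IntensityMatrix, cmp: Comparison) -> list[MarginalFit]:
    """OLS of each feature on the binary group indicator of ``cmp``.

    Features with zero residual variance get p = NaN and are flagged; they
    can never be selected downstream.
    """
    X, y, feature_ids = cmp.subset(data)   # X: samples x features
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 < 2 or n0 < 2:
        raise ValueError(f"comparison {cmp.name} needs >= 2 samples per group")
    n = len(y)
    df = n - 2

    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    beta = m1 - m0
    beta0 = m0
    fitted = np.where(y[:, None] == 1.0, m1[None, :], m0[None, :])
    rss = ((X - fitted) ** 2).sum(axis=0)
    resid_var = rss / df
    se = np.sqrt(resid_var * (1.0 / n1 + 1.0 / n0))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    flagged = resid_var <= 0
    p = np.where(flagged, np.nan, p)
    if flagged.any():
        logger.info("flagged %d constant feature(s) in %s", int(flagged.sum()), cmp.name)

    return [
        MarginalFit(
            feature_id=fid,
            beta0=float(beta0[k]),
            beta_k=float(beta[k]),
            se=float(se[k]),
            t_stat=float(t[k]),
            df=df,
            p_raw=float(p[k]),
            residual_var=float(resid_var[k]),
            flagged=bool(flagged[k]),
        )
        for k, fid in enumerate(feature_ids)
    ]


def adjust_bonferroni(
    fits: list[MarginalFit], alpha: float = 0.05, comparison: str = ""
) -> SelectionResult:
    """Bonferroni-adjust the fits in place and return the selected set.

    m counts the features with a defined p-value; flagged (NaN) features are
    not tested and never selected.
    """
    if not fits:
        raise ValueError("no fits to adjust")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    m = sum(1 for f in fits if np.isfinite(f.p_raw))
    selected = []
    for f in fits:
        if np.isfinite(f.p_raw):
            f.p_adj = min(1.0, m * f.p_raw)
            if f.p_adj < alpha:
                selected.append(f.feature_id)
        else:
            f.p_adj = np.nan
    return SelectionResult(
        method="marginal",
        comparison=comparison,
        selected_ids=selected,
        control={"alpha": alpha, "m": m},
    )


def marginal_table(fits: list[MarginalFit], result: SelectionResult) -> pd.DataFrame:
    """Long-format per-feature output with a stable column order."""
    sel = set(result.selected_ids)
    return pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in fits],
            "beta": [f.beta_k for f in fits],
            "t": [f.t_stat for f in fits],
            "df": [f.df for f in fits],
            "p_raw": [f.p_raw for f in fits],
            "p_adj": [f.p_adj for f in fits],
            "selected": [f.feature_id in sel for f in fits],
            "direction": [
                ("up" if f.beta_k > 0 else "down") if f.feature_id in sel else ""
                for f in fits
            ],
        }
    )
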