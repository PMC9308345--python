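"""Feature selection from posterior inclusion probabilities and pooling of
results across methods and comparisons.

For the Bayesian method the local false discovery rate of feature j is
lfdr_j = 1 - PIP_j.  Sorting lfdrs in ascending order, the Bayesian FDR of
the top-T set is the mean of its T smallest lfdrs; the selection keeps the
largest T whose running mean is still strictly below the threshold alpha.
A PIP > cut heuristic is provided as the simpler alternative.

Selections from all methods and comparisons are pooled into a long DAP
(differentially abundant protein) table.  Per axis (genotype or treatment)
the distinct-feature union across methods and that axis's two comparisons is
reported together with per-method pairwise intersections; the overall total
is the sum of the two axis-level distinct counts (a feature significant on
both axes counts once per axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marginal import SelectionResult
from .ssvs import SSVSSummary


@dataclass
class DAPRecord:
    feature_id: str
    comparison: str
    axis: str
    method: str
    direction: str     # "up" | "down"
    stat: float        # method-native signed statistic (t, coefficient) or pip


@dataclass
class ComparisonSummary:
    axis_unions: dict[str, int]                       # axis -> distinct DAP count
    axis_union_ids: dict[str, list[str]]
    method_counts: dict[str, dict[str, int]]          # axis -> method -> count
    pairwise_intersections: dict[str, dict[str, int]]  # axis -> "m1&m2" -> count
    overall_total: int


# ---------------------------------------------------------------------------
# Bayesian FDR selection
# ---------------------------------------------------------------------------

def bfdr_select(
    summary: SSVSSummary, alpha: float = 0.05, comparison: str = ""
) -> SelectionResult:
    """Select the largest prefix of ascending lfdrs whose mean is < alpha.

    Ties in lfdr are broken lexicographically by feature id so the selection
    is deterministic.
    """
    if len(summary.pip) == 0:
        raise ValueError("empty summary")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    lfdr = (1.0 - summary.pip).sort_index()
    order = np.lexsort((np.array(lfdr.index, dtype=object), lfdr.to_numpy()))
    sorted_ids = [lfdr.index[i] for i in order]
    sorted_lfdr = lfdr.to_numpy()[order]
    cum_mean = np.cumsum(sorted_lfdr) / np.arange(1, len(sorted_lfdr) + 1)
    below = np.flatnonzero(cum_mean < alpha)
    t_star = int(below[-1] + 1) if below.size else 0
    return SelectionResult(
        method="ssvs",
        comparison=comparison,
        selected_ids=sorted_ids[:t_star],
        control={
            "alpha": alpha,
            "T": t_star,
            "bfdr_path": cum_mean,
            "sorted_ids": sorted_ids,
        },
    )


def pip_threshold_select(
    summary: SSVSSummary, cut: float = 0.5, comparison: str = ""
) -> SelectionResult:
    """Heuristic selection: features with PIP strictly above ``cut``."""
    if not 0.0 <= cut < 1.0:
        raise ValueError("cut must lie in [0, 1)")
    selected = [f for f in summary.pip.index if summary.pip[f] > cut]
    return SelectionResult(
        method="ssvs", comparison=comparison, selected_ids=selected,
        control={"cut": cut},
    )


# ---------------------------------------------------------------------------
# direction classification and pooling
# ---------------------------------------------------------------------------

def classify_direction(
    result: SelectionResult,
    stats: pd.Series,
    axis: str = "group",
) -> list[DAPRecord]:
    """Turn a selection into DAP records with up/down calls.

    ``stats`` maps feature id to the method's signed statistic (beta_k for
    the marginal fit, coefficient for the elastic net, conditional posterior
    mean for SSVS); positive means higher abundance in the y = 1
    (first-listed) group, i.e. "up".
    """
    records = []
    for fid in result.selected_ids:
        if fid not in stats.index or not np.isfinite(stats[fid]):
            raise ValueError(f"missing signed statistic for selected feature {fid}")
        s = float(stats[fid])
        if s == 0.0:
            raise ValueError(f"selected feature {fid} has zero effect")
        records.append(
            DAPRecord(
                feature_id=fid,
                comparison=result.comparison,
                axis=axis,
                method=result.method,
                direction="up" if s > 0 else "down",
                stat=s,
            )
        )
    return records


def pool_comparisons(records: list[DAPRecord]) -> ComparisonSummary:
    """Union/overlap bookkeeping across methods and comparisons, per axis."""
    if not records:
        raise ValueError("no records to pool")
    seen = set()
    for r in records:
        key = (r.feature_id, r.comparison, r.method)
        if key in seen:
            raise ValueError(f"duplicate DAP record {key}")
        seen.add(key)

    axes = sorted({r.axis for r in records})
    axis_unions: dict[str, int] = {}
    axis_union_ids: dict[str, list[str]] = {}
    method_counts: dict[str, dict[str, int]] = {}
    pairwise: dict[str, dict[str, int]] = {}
    for axis in axes:
        ax_records = [r for r in records if r.axis == axis]
        by_method: dict[str, set] = {}
        for r in ax_records:
            by_method.setdefault(r.method, set()).add(r.feature_id)
        union = set().union(*by_method.values())
        axis_unions[axis] = len(union)
        axis_union_ids[axis] = sorted(union)
        method_counts[axis] = {m: len(s) for m, s in sorted(by_method.items())}
        methods = sorted(by_method)
        pairwise[axis] = {
            f"{m1}&{m2}": len(by_method[m1] & by_method[m2])
            for i, m1 in enumerate(methods)
            for m2 in methods[i + 1:]
        }

    return ComparisonSummary(
        axis_unions=axis_unions,
        axis_union_ids=axis_union_ids,
        method_counts=method_counts,
        pairwise_intersections=pairwise,
        overall_total=sum(axis_unions.values()),
    )


def dap_table(records: list[DAPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "comparison": [r.comparison for r in records],
            "axis": [r.axis for r in records],
            "method": [r.method for r in records],
            "direction": [r.direction for r in records],
            "stat": [r.stat for r in records],
        }
    )
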