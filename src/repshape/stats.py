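"""Nonparametric group comparison for repertoire features.

The canonical analysis for repertoire feature panels across age groups:
Kruskal-Wallis per feature (tie-corrected, chi-square approximation),
Benjamini-Hochberg FDR across the feature family, and the post-hoc Dunn
test on joint mid-ranks for pairwise group contrasts (BH-adjusted within
the pair set).

Kruskal-Wallis is delegated to scipy; the Dunn test is implemented here
with the standard tie-corrected z statistic

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]

where T = sum(t^3 - t) over tie groups, with two-sided normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def _check_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("groups must be non-empty")
    if sum(len(a) for a in arrays) < 3:
        raise ValidationError("need at least 3 observations in total")
    return arrays


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    All-identical samples return (0, 1) rather than erroring: no rank
    information simply means no evidence against the null.
    """
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups, labels: list | None = None, adjust: str = "bh") -> pd.DataFrame:
    """Pairwise Dunn z tests on joint mid-ranks.

    Returns a table with columns group_i, group_j, z, p and (when
    ``adjust='bh'``) p_adj over the pair set.
    """
    arrays = _check_groups(groups)
    if labels is None:
        labels = list(range(len(arrays)))
    if adjust not in ("none", "bh"):
        raise ValidationError(f"unknown adjustment: {adjust!r}")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(arrays))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_core = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_i": labels[i], "group_j": labels[j],
                     "z": float(z), "p": min(float(p), 1.0)})
    df = pd.DataFrame(rows)
    if adjust == "bh":
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


@dataclass
class GroupComparison:
    feature: str
    kw_h: float
    kw_p: float
    kw_p_adj: float | None = None
    dunn: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_features(table: pd.DataFrame, group_col: str,
                     feature_cols: list[str] | None = None,
                     posthoc: bool = True) -> list[GroupComparison]:
    """Kruskal-Wallis per feature with BH adjustment across features,
    plus a Dunn pairwise table per feature (BH within the pair set)."""
    if group_col not in table.columns:
        raise ValidationError(f"missing group column: {group_col!r}")
    if feature_cols is None:
        feature_cols = [c for c in table.select_dtypes(include=[np.number]).columns
                        if c != group_col]
    group_labels = sorted(table[group_col].dropna().unique())
    grouped = {g: table[table[group_col] == g] for g in group_labels}
    out = []
    for feat in feature_cols:
        groups = [grouped[g][feat].dropna().to_numpy() for g in group_labels]
        h, p = kruskal_wallis(groups)
        comp = GroupComparison(feature=feat, kw_h=h, kw_p=p)
        if posthoc:
            comp.dunn = dunn_posthoc(groups, labels=group_labels, adjust="bh")
        out.append(comp)
    adj = bh_fdr([c.kw_p for c in out])
    for c, a in zip(out, adj):
        c.kw_p_adj = float(a)
    return out


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten a list of GroupComparison into one tidy frame."""
    rows = []
    for c in comparisons:
        rows.append({"feature": c.feature, "kw_H": c.kw_h, "kw_p": c.kw_p,
                     "kw_p_adj": c.kw_p_adj})
    return pd.DataFrame(rows)
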