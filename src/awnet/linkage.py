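"""Two-step linkage of network centrality to condition severity scores.

Step 1 correlates every facet (node) with every condition severity score
across participants — the zero-order node-condition associations.  Step 2
correlates, across the p nodes, the standardized expected influence with
each step-1 column: a positive step-2 coefficient means that facets central
to the behavioral network are also the facets most associated with that
condition.

The clinical-relevance rule then classifies node-condition cells: a cell
whose step-1 correlation reaches the relevance threshold (default: the mean
of all p x q step-1 correlations, signed, rounded to 4 decimals) is
"clinically relevant" if the node sits in the top third of expected
influence, and a "differential-diagnosis" marker otherwise — strongly tied
to the condition but not central to the network itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptives import CentralityProfile

__all__ = [
    "LinkageResult",
    "step1_zero_order",
    "step2_centrality_linkage",
    "clinical_relevance",
    "run_linkage",
]


def step1_zero_order(
    facets: pd.DataFrame,
    conditions: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """p x q zero-order correlations between raw facet scores and condition
    scores.

    Rows with a missing condition value are dropped listwise per condition
    (pairwise deletion across conditions); the number dropped is warned
    about.  A constant column yields NaN with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if len(facets) != len(conditions):
        raise ValueError(
            f"facets have {len(facets)} rows but conditions have {len(conditions)}"
        )
    out = pd.DataFrame(
        np.nan, index=facets.columns.copy(), columns=conditions.columns.copy()
    )
    out.index.name = "node"
    X = facets.to_numpy(dtype=float)
    for cond in conditions.columns:
        y = conditions[cond].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"condition {cond!r}: dropped {dropped} missing rows", stacklevel=2)
        if keep.sum() < 3 or np.ptp(y[keep]) == 0:
            warnings.warn(f"condition {cond!r}: correlation undefined", stacklevel=2)
            continue
        for i, node in enumerate(facets.columns):
            x = X[keep, i]
            if np.ptp(x) == 0:
                warnings.warn(f"node {node!r}: constant column, correlation undefined", stacklevel=2)
                continue
            if method == "spearman":
                out.loc[node, cond] = stats.spearmanr(x, y[keep]).statistic
            else:
                out.loc[node, cond] = stats.pearsonr(x, y[keep]).statistic
    return out


def step2_centrality_linkage(
    profile: CentralityProfile,
    step1: pd.DataFrame,
) -> pd.DataFrame:
    """Per condition: Spearman correlation (and two-sided p from the t
    approximation) across nodes between ei_z and the step-1 column."""
    p = len(profile.node_labels)
    if len(step1) != p:
        raise ValueError("step1 rows must match the centrality profile's nodes")
    if p < 4:
        raise ValueError("need at least 4 nodes for a node-level correlation")
    rows = {}
    for cond in step1.columns:
        col = step1[cond].to_numpy(dtype=float)
        res = stats.spearmanr(profile.ei_z, col, nan_policy="omit")
        rows[cond] = {"rho": float(res.statistic), "p_value": float(res.pvalue)}
    out = pd.DataFrame(rows).T
    out.index.name = "condition"
    return out


@dataclass
class LinkageResult:
    """Full two-step linkage output plus relevance/differential flags."""

    step1: pd.DataFrame           # p x q node-condition correlations
    step2: pd.DataFrame           # per condition: rho, p_value
    threshold: float
    threshold_mode: str
    relevant: pd.DataFrame        # p x q bool: top-third node, step1 >= threshold
    differential: pd.DataFrame    # p x q bool: non-top-third node, step1 >= threshold

    def relevant_nodes(self) -> dict[str, list[str]]:
        """Per condition, the clinically relevant node labels (machine analog
        of a per-condition relevance table)."""
        return {
            cond: self.relevant.index[self.relevant[cond]].tolist()
            for cond in self.relevant.columns
        }

    def heatmap_table(self) -> pd.DataFrame:
        """Step-1 correlations with cells below threshold masked to NaN —
        the tabular analog of a shaded relevance heatmap."""
        return self.step1.where(self.step1 >= self.threshold)

    def to_dict(self) -> dict:
        return {
            "step1": self.step1.to_dict(),
            "step2": self.step2.to_dict(),
            "threshold": self.threshold,
            "threshold_mode": self.threshold_mode,
            "relevant": self.relevant.to_dict(),
            "differential": self.differential.to_dict(),
            "relevant_nodes": self.relevant_nodes(),
        }


def clinical_relevance(
    profile: CentralityProfile,
    step1: pd.DataFrame,
    threshold_mode: str = "mean",
    threshold_value: float | None = None,
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Flag clinically relevant and differential-diagnosis cells.

    threshold = mean of all signed step-1 entries (mode "mean", rounded to 4
    decimals so the flags are exactly reproducible) or a fixed supplied value
    (mode "fixed").  relevant[i,j] = top_third[i] and step1[i,j] >= threshold;
    differential[i,j] = (not top_third[i]) and step1[i,j] >= threshold.
    """
    if step1.size == 0:
        raise ValueError("empty step-1 matrix")
    if threshold_mode == "mean":
        threshold = round(float(np.nanmean(step1.to_numpy(dtype=float))), 4)
    elif threshold_mode == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_mode='fixed' requires threshold_value")
        threshold = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    above = step1 >= threshold  # NaN compares False
    top = pd.Series(profile.top_third, index=profile.node_labels)
    top = top.reindex(step1.index)
    if top.isna().any():
        raise ValueError("step1 rows do not match the centrality profile's nodes")
    relevant = above.mul(top.astype(bool), axis=0)
    differential = above.mul(~top.astype(bool), axis=0)
    return threshold, relevant, differential


def run_linkage(
    facets: pd.DataFrame,
    conditions: pd.DataFrame,
    profile: CentralityProfile,
    method: str = "spearman",
    threshold_mode: str = "mean",
    threshold_value: float | None = None,
) -> LinkageResult:
    """Step 1 + step 2 + relevance flags in one call."""
    step1 = step1_zero_order(facets, conditions, method=method)
    step2 = step2_centrality_linkage(profile, step1)
    threshold, relevant, differential = clinical_relevance(
        profile, step1, threshold_mode=threshold_mode, threshold_value=threshold_value
    )
    return LinkageResult(
        step1=step1,
        step2=step2,
        threshold=threshold,
        threshold_mode=threshold_mode,
        relevant=relevant,
        differential=differential,
    )
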