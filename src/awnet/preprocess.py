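"""Preprocessing: nonparanormal transform, correlation estimation, redundancy screen.

Facet scores are bounded ordinal averages (at most ``4*items + 1`` distinct
levels), so ties are pervasive and marginals are skewed.  The nonparanormal
transform maps each column through its truncated empirical CDF and the
standard-normal quantile function, making the data suitable for Gaussian
graphical modeling while preserving within-column rank order exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "RedundancyReport",
    "npn_transform",
    "estimate_correlations",
    "nearest_psd_correlation",
    "goldbricker",
    "hittner_dependent_z",
]


def validate_facets(df: pd.DataFrame) -> None:
    """Schema checks shared by every entry point that accepts a facet table."""
    if df.shape[1] < 3:
        raise ValueError("facet matrix needs at least 3 columns")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate node labels: {dupes}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing cells in columns: {bad}")


def npn_transform(df: pd.DataFrame) -> pd.DataFrame:
    """Nonparanormal (truncated-ECDF / Gaussian quantile) transform, per column.

    For each column the empirical CDF is rank/n with average ranks for ties,
    truncated to [delta_n, 1 - delta_n] where
    ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))``, then passed through the
    standard-normal quantile function.  The map is a strictly increasing
    function of the ranks, so rank order is preserved and any strictly
    monotone pre-transform of a column leaves the output unchanged.
    """
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 rows")
    delta = 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            raise ValueError(f"column {col!r} is constant; nonparanormal transform undefined")
        u = stats.rankdata(x, method="average") / n
        out[col] = stats.norm.ppf(np.clip(u, delta, 1.0 - delta))
    return pd.DataFrame(out, index=df.index)


def nearest_psd_correlation(R: np.ndarray) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix to the nearest positive semidefinite
    correlation matrix by eigenvalue clipping plus diagonal re-normalization.

    Returns (matrix, repaired_flag); matrices already PSD pass through with
    only symmetrization and a unit diagonal.
    """
    R = np.asarray(R, dtype=float)
    R = (R + R.T) / 2.0
    repaired = False
    eigvals, eigvecs = np.linalg.eigh(R)
    if eigvals.min() < 0:
        eigvals = np.clip(eigvals, 0.0, None)
        R = eigvecs @ np.diag(eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(R))
        # a clipped-to-zero variance cannot be rescaled; leave that row as-is
        d[d == 0] = 1.0
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
        repaired = True
    np.fill_diagonal(R, 1.0)
    return R, repaired


@dataclass
class CorrelationMatrix:
    """p x p correlation matrix with provenance and a PSD-repair flag."""

    values: pd.DataFrame
    method: str
    psd_repaired: bool = False

    @property
    def node_labels(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()


def estimate_correlations(df: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise correlations of the (transformed) facet table.

    Default is Pearson, since the nonparanormal transform precedes it.  Any
    negative eigenvalue triggers projection to the nearest positive
    semidefinite matrix by eigenvalue clipping, followed by re-normalization
    of the diagonal to 1 (``psd_repaired`` set).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    n, p = df.shape
    if n < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: correlation matrix will be singular", stacklevel=2)
    R = df.corr(method=method).to_numpy()
    R, repaired = nearest_psd_correlation(R)
    values = pd.DataFrame(R, index=df.columns, columns=df.columns)
    return CorrelationMatrix(values=values, method=method, psd_repaired=repaired)


def hittner_dependent_z(r_ik: float, r_jk: float, r_ij: float, n: int) -> tuple[float, float]:
    """Test H0: rho(i,k) = rho(j,k) for correlations sharing variable k.

    Back-transformed average Fisher-z procedure (Hittner, May & Silver, 2003):
    the two correlations are averaged on the z scale, back-transformed, and
    that pooled value replaces the individual correlations in the covariance
    term of Steiger's statistic.  Returns (z, two-sided p).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    cap = 1.0 - 1e-12
    z1 = np.arctanh(np.clip(r_ik, -cap, cap))
    z2 = np.arctanh(np.clip(r_jk, -cap, cap))
    if z1 == z2:
        return 0.0, 1.0
    rbt = np.tanh((z1 + z2) / 2.0)
    r12 = np.clip(r_ij, -cap, cap)
    c = (r12 * (1.0 - 2.0 * rbt**2) - 0.5 * rbt**2 * (1.0 - 2.0 * rbt**2 - r12**2)) / (1.0 - rbt**2) ** 2
    c = min(c, cap)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class RedundancyReport:
    """Outcome of the node-redundancy screen.

    ``candidate_pairs`` rows: (node_i, node_j, r_ij, proportion of third
    variables with significantly different correlations, flagged).  A pair is
    flagged as redundant when its members correlate at least ``cor_min`` and
    fewer than ``prop_threshold`` of the dependent-correlation tests against
    third variables are significant at ``alpha``.
    """

    candidate_pairs: pd.DataFrame
    cor_min: float
    alpha: float
    prop_threshold: float
    suggested_reduced_node_set: list[str] = field(default_factory=list)

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.candidate_pairs[self.candidate_pairs["flagged"]]

    def to_dict(self) -> dict:
        return {
            "parameters": {
                "cor_min": self.cor_min,
                "alpha": self.alpha,
                "prop_threshold": self.prop_threshold,
            },
            "candidate_pairs": self.candidate_pairs.to_dict(orient="records"),
            "suggested_reduced_node_set": self.suggested_reduced_node_set,
        }


def goldbricker(
    df: pd.DataFrame,
    cor_min: float = 0.50,
    alpha: float = 0.05,
    prop_threshold: float = 0.25,
    method: str = "pearson",
) -> RedundancyReport:
    """Screen for statistically redundant node pairs.

    For each pair with ``|r_ij| >= cor_min``, every third node k supplies a
    dependent-overlapping-correlations test of rho(i,k) = rho(j,k) via
    :func:`hittner_dependent_z`; the pair is flagged when the proportion of
    significant tests falls below ``prop_threshold``.  The suggested reduced
    node set drops, from each flagged pair, the member with the lower
    variance (ties drop the lexicographically later label) — keeping the more
    informative indicator deterministically.
    """
    n, p = df.shape
    if p < 3:
        raise ValueError("need at least 3 nodes (no third variables to compare)")
    if n < 20:
        warnings.warn(f"n={n} < 20: redundancy tests will be unreliable", stacklevel=2)
    R = df.corr(method=method).to_numpy()
    labels = list(df.columns)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            r_ij = R[i, j]
            if abs(r_ij) < cor_min:
                continue
            others = [k for k in range(p) if k != i and k != j]
            n_sig = sum(
                1 for k in others if hittner_dependent_z(R[i, k], R[j, k], r_ij, n)[1] < alpha
            )
            prop = n_sig / len(others)
            rows.append(
                {
                    "node_i": labels[i],
                    "node_j": labels[j],
                    "r_ij": float(r_ij),
                    "prop_significant": prop,
                    "flagged": prop < prop_threshold,
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["node_i", "node_j", "r_ij", "prop_significant", "flagged"]
    )

    variances = df.var(ddof=1)
    dropped: set[str] = set()
    for _, row in pairs[pairs["flagged"]].iterrows():
        a, b = row["node_i"], row["node_j"]
        if a in dropped or b in dropped:
            continue
        va, vb = variances[a], variances[b]
        if va < vb:
            dropped.add(a)
        elif vb < va:
            dropped.add(b)
        else:
            dropped.add(max(a, b))
    reduced = [c for c in labels if c not in dropped]
    return RedundancyReport(
        candidate_pairs=pairs,
        cor_min=cor_min,
        alpha=alpha,
        prop_threshold=prop_threshold,
        suggested_reduced_node_set=reduced,
    )
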