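"""Case-dropping bootstrap and the correlation-stability (CS) coefficient.

Centrality orderings estimated from regularized networks can be fragile.
The case-dropping bootstrap refits the entire pipeline (nonparanormal
transform -> correlation -> graphical lasso path -> EBIC selection ->
expected influence) on subsamples with an increasing proportion of
participants removed, and correlates each subsample's centrality with the
full-sample centrality.  The CS coefficient is the largest drop proportion
at which at least ``coverage`` (default 95%) of replicates still correlate
at least ``r_threshold`` (default 0.7) with the full-sample values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .descriptives import expected_influence
from .ggm import fit_ggm
from .preprocess import estimate_correlations, npn_transform

__all__ = ["StabilityResult", "case_drop_bootstrap", "cs_coefficient", "DEFAULT_DROP_GRID"]

DEFAULT_DROP_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.75)


@dataclass
class StabilityResult:
    """Tidy table of (drop proportion, replicate, correlation) plus the CS."""

    correlations: pd.DataFrame  # columns: proportion, replicate, correlation
    cs: float
    B: int
    seed: int | None
    drop_proportions: tuple[float, ...]
    r_threshold: float = 0.7
    coverage: float = 0.95
    skipped_proportions: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cs_coefficient": self.cs,
            "B": self.B,
            "seed": self.seed,
            "drop_proportions": list(self.drop_proportions),
            "r_threshold": self.r_threshold,
            "coverage": self.coverage,
            "skipped_proportions": self.skipped_proportions,
            "correlations": self.correlations.to_dict(orient="list"),
        }


def cs_coefficient(
    correlations: pd.DataFrame,
    r_threshold: float = 0.7,
    coverage: float = 0.95,
) -> float:
    """Largest drop proportion whose replicate correlations reach
    ``r_threshold`` with probability at least ``coverage``; 0 if none does.

    Undefined (NaN) replicate correlations count as failures.
    """
    if len(correlations) == 0:
        raise ValueError("empty correlation table")
    qualifying = []
    for prop, grp in correlations.groupby("proportion"):
        vals = grp["correlation"].to_numpy()
        frac = np.mean(np.nan_to_num(vals, nan=-np.inf) >= r_threshold)
        if frac >= coverage:
            qualifying.append(float(prop))
    return max(qualifying) if qualifying else 0.0


def _fit_ei(df: pd.DataFrame, correlation_method: str, gamma: float,
            n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    transformed = npn_transform(df)
    S = estimate_correlations(transformed, method=correlation_method)
    net = fit_ggm(S, n=len(df), gamma=gamma, n_lambda=n_lambda,
                  lambda_min_ratio=lambda_min_ratio)
    return expected_influence(net).ei_raw


def case_drop_bootstrap(
    facets: pd.DataFrame,
    B: int = 1000,
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_GRID,
    seed: int | None = None,
    correlation_method: str = "pearson",
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    stat_correlation: str = "spearman",
    r_threshold: float = 0.7,
    coverage: float = 0.95,
) -> StabilityResult:
    """Case-dropping bootstrap of expected-influence centrality.

    Subsampling is without replacement.  A proportion whose retained sample
    size would fall below p+1 is skipped with a warning.  The per-replicate
    statistic is the Spearman (or Pearson, by ``stat_correlation``)
    correlation between subsample and full-sample raw expected influence;
    replicates where either profile is constant record NaN.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if stat_correlation not in ("spearman", "pearson"):
        raise ValueError(f"unknown stat_correlation {stat_correlation!r}")
    n, p = facets.shape
    rng = np.random.default_rng(seed)

    ei_full = _fit_ei(facets, correlation_method, gamma, n_lambda, lambda_min_ratio)

    usable, skipped = [], []
    for prop in drop_proportions:
        m = int(round(n * (1.0 - prop)))
        if m >= p + 1:
            usable.append((float(prop), m))
        else:
            skipped.append(float(prop))
            warnings.warn(
                f"drop proportion {prop} leaves {m} < p+1 = {p + 1} cases; skipped",
                stacklevel=2,
            )
    if not usable:
        raise ValueError("every drop proportion was skipped; nothing to bootstrap")

    rows = []
    for prop, m in usable:
        for b in range(B):
            idx = rng.choice(n, size=m, replace=False)
            if m == n:
                corr = 1.0
            else:
                try:
                    ei_sub = _fit_ei(facets.iloc[idx], correlation_method, gamma,
                                     n_lambda, lambda_min_ratio)
                except (ValueError, RuntimeError):
                    corr = np.nan
                else:
                    if np.ptp(ei_sub) == 0 or np.ptp(ei_full) == 0:
                        corr = np.nan
                    elif stat_correlation == "spearman":
                        corr = float(stats.spearmanr(ei_full, ei_sub).statistic)
                    else:
                        corr = float(stats.pearsonr(ei_full, ei_sub).statistic)
            rows.append({"proportion": prop, "replicate": b, "correlation": corr})

    table = pd.DataFrame(rows, columns=["proportion", "replicate", "correlation"])
    cs = cs_coefficient(table, r_threshold=r_threshold, coverage=coverage)
    return StabilityResult(
        correlations=table,
        cs=cs,
        B=B,
        seed=seed,
        drop_proportions=tuple(float(p_) for p_ in drop_proportions),
        r_threshold=r_threshold,
        coverage=coverage,
        skipped_proportions=skipped,
    )
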