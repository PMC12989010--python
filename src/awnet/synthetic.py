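"""Synthetic facet and condition data with a known sparse partial-correlation network.

The generator emulates the data structure the downstream pipeline assumes:
a latent multivariate-normal vector whose precision matrix encodes a sparse
signed partial-correlation network organized into communities; each observed
"facet" is the mean of a small number of 0-3 Likert items obtained by adding
item-level noise to the latent value and thresholding; condition severity
scores are noisy linear combinations of facet subsets, rescaled to a
T-score-like scale.  Because the true precision matrix, community labels and
loadings are retained, every downstream stage has a parameter-recovery test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "generate_true_network",
    "attach_condition_model",
    "sample_facet_data",
    "sample_condition_scores",
    "partials_from_precision",
    "noise_sd_for_r2",
]

#: default latent cut points mapping N(0,1)-scale values to {0,1,2,3};
#: placed off-center to induce the right skew typical of problem-behavior scales
DEFAULT_THRESHOLDS = (-0.5, 0.5, 1.5)


def partials_from_precision(precision: np.ndarray) -> np.ndarray:
    """Signed partial correlations -K_ij / sqrt(K_ii K_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    partials = -precision / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return partials


@dataclass
class SyntheticSpec:
    """Ground truth for one synthetic scenario.

    ``precision`` is the latent inverse-covariance matrix on the correlation
    scale (the implied covariance has unit diagonal); ``true_partials`` is its
    signed partial-correlation transform and is the support/weight reference
    for recovery tests.  ``communities`` holds the planted block label of each
    node.  ``loadings`` (p x q) and ``noise_sd`` define the condition-score
    model; they may be absent until :func:`attach_condition_model` is called.
    """

    precision: np.ndarray
    true_partials: np.ndarray
    communities: np.ndarray
    node_labels: list[str]
    seed: int | None = None
    likert_items: int = 4
    item_noise_sd: float = 0.3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    loadings: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    condition_labels: list[str] | None = None
    t_mean: float = 60.0
    t_sd: float = 12.0
    extras: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def true_expected_influence(self) -> np.ndarray:
        return self.true_partials.sum(axis=1)

    def validate(self) -> None:
        K = self.precision
        if K.shape[0] != K.shape[1] or not np.allclose(K, K.T):
            raise ValueError("precision must be square symmetric")
        eigvals = np.linalg.eigvalsh(K)
        if eigvals.min() <= 0:
            raise ValueError("precision must be positive definite")
        if not np.allclose(self.true_partials, partials_from_precision(K)):
            raise ValueError("true_partials inconsistent with precision")
        th = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def to_json(self, path) -> None:
        obj = {
            "precision": self.precision.tolist(),
            "true_partials": self.true_partials.tolist(),
            "communities": self.communities.tolist(),
            "node_labels": self.node_labels,
            "seed": self.seed,
            "likert_items": self.likert_items,
            "item_noise_sd": self.item_noise_sd,
            "thresholds": list(self.thresholds),
            "loadings": None if self.loadings is None else self.loadings.tolist(),
            "noise_sd": None if self.noise_sd is None else np.asarray(self.noise_sd).tolist(),
            "condition_labels": self.condition_labels,
            "t_mean": self.t_mean,
            "t_sd": self.t_sd,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            precision=np.asarray(obj["precision"], dtype=float),
            true_partials=np.asarray(obj["true_partials"], dtype=float),
            communities=np.asarray(obj["communities"], dtype=int),
            node_labels=list(obj["node_labels"]),
            seed=obj.get("seed"),
            likert_items=obj.get("likert_items", 4),
            item_noise_sd=obj.get("item_noise_sd", 0.3),
            thresholds=tuple(obj.get("thresholds", DEFAULT_THRESHOLDS)),
            loadings=None if obj.get("loadings") is None else np.asarray(obj["loadings"], dtype=float),
            noise_sd=None if obj.get("noise_sd") is None else np.asarray(obj["noise_sd"], dtype=float),
            condition_labels=obj.get("condition_labels"),
            t_mean=obj.get("t_mean", 60.0),
            t_sd=obj.get("t_sd", 12.0),
        )


def generate_true_network(
    p: int,
    n_communities: int = 4,
    within_prob: float = 0.4,
    between_prob: float = 0.05,
    weight_range: tuple[float, float] = (0.28, 0.45),
    positive_frac: float = 0.9,
    seed: int | None = None,
    **spec_kwargs,
) -> SyntheticSpec:
    """Draw a sparse community-structured precision matrix.

    Off-diagonal support is Bernoulli(``within_prob``) for node pairs inside
    the same community and Bernoulli(``between_prob``) across communities;
    nonzero partial correlations have magnitude uniform in ``weight_range``
    and positive sign with probability ``positive_frac``.  Positive
    definiteness is enforced by a diagonal-dominance repair (each diagonal
    entry is raised to the absolute off-diagonal row sum plus 0.1 whenever
    that exceeds 1), after which the precision is rescaled so the implied
    covariance is a correlation matrix, and ``true_partials`` are re-derived
    from the repaired matrix.  The repair shrinks the partials of heavy rows,
    so ``true_partials`` — not ``weight_range`` — is the recovery reference.
    """
    if not (0.0 <= between_prob <= within_prob <= 1.0):
        raise ValueError("require 0 <= between_prob <= within_prob <= 1")
    if p < n_communities:
        raise ValueError("p must be at least n_communities")
    lo, hi = weight_range
    if not (0.0 <= lo <= hi < 1.0):
        raise ValueError("weight_range must satisfy 0 <= lo <= hi < 1")

    rng = np.random.default_rng(seed)
    communities = np.concatenate(
        [np.full(len(block), c) for c, block in enumerate(np.array_split(np.arange(p), n_communities))]
    )

    K = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            prob = within_prob if communities[i] == communities[j] else between_prob
            if rng.random() < prob:
                w = rng.uniform(lo, hi)
                if rng.random() >= positive_frac:
                    w = -w
                K[i, j] = K[j, i] = -w  # precision off-diagonal has opposite sign

    # diagonal-dominance repair: strict dominance guarantees PD
    rowsum = np.abs(K).sum(axis=1) - np.diag(K)
    np.fill_diagonal(K, np.maximum(1.0, rowsum + 0.1))

    # rescale so the implied covariance has unit diagonal (D^-1 K D^-1 keeps
    # the support and the partial correlations exactly)
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    K = K * np.outer(d, d)
    K = (K + K.T) / 2.0

    if np.linalg.eigvalsh(K).min() <= 0:
        raise RuntimeError("precision not positive definite after dominance repair")

    labels = [f"F{i + 1:02d}" for i in range(p)]
    return SyntheticSpec(
        precision=K,
        true_partials=partials_from_precision(K),
        communities=communities,
        node_labels=labels,
        seed=seed,
        **spec_kwargs,
    )


def sample_facet_data(spec: SyntheticSpec, n: int, seed: int | None = None) -> pd.DataFrame:
    """Sample an n x p facet-score table.

    Each participant gets a latent MVN(0, precision^-1) vector; each facet is
    observed through ``likert_items`` conditionally independent replicates
    (latent value + N(0, item_noise_sd)), each thresholded into {0,1,2,3},
    and scored as the item mean — so values lie on [0, 3] in steps of
    1/likert_items.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    th = np.asarray(spec.thresholds, dtype=float)
    if np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = np.linalg.cholesky(spec.covariance)
    latent = rng.standard_normal((n, spec.p)) @ L.T
    items = latent[:, :, None] + rng.normal(0.0, spec.item_noise_sd, size=(n, spec.p, spec.likert_items))
    scores = np.digitize(items, th).mean(axis=2)
    return pd.DataFrame(
        scores,
        columns=spec.node_labels,
        index=[f"P{i + 1:04d}" for i in range(n)],
    )


def attach_condition_model(
    spec: SyntheticSpec,
    q: int = 10,
    facets_per_condition: int = 3,
    loading_value: float = 1.0,
    noise_sd: float | np.ndarray = 0.0,
    seed: int | None = None,
) -> SyntheticSpec:
    """Fill in a p x q loading matrix: each condition loads on a random subset
    of ``facets_per_condition`` facets with weight ``loading_value``."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    loadings = np.zeros((spec.p, q))
    for j in range(q):
        rows = rng.choice(spec.p, size=facets_per_condition, replace=False)
        loadings[rows, j] = loading_value
    spec.loadings = loadings
    spec.noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (q,)).copy()
    spec.condition_labels = [f"C{j + 1:02d}" for j in range(q)]
    return spec


def noise_sd_for_r2(facets: pd.DataFrame, loadings: np.ndarray, r2: float) -> np.ndarray:
    """Per-condition residual sd giving the target signal R-squared on this sample."""
    if not (0.0 < r2 <= 1.0):
        raise ValueError("r2 must be in (0, 1]")
    signal_var = (facets.to_numpy() @ loadings).var(axis=0, ddof=1)
    return np.sqrt(signal_var * (1.0 - r2) / r2)


def sample_condition_scores(
    facets: pd.DataFrame,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate n x q condition severity scores on a T-score-like scale.

    score = t_mean + t_sd * standardized(facets @ loadings + noise); a column
    whose signal and noise are both degenerate is held constant at t_mean.
    """
    if spec.loadings is None:
        raise ValueError("spec has no condition loadings; call attach_condition_model first")
    if spec.loadings.shape[0] != facets.shape[1]:
        raise ValueError(
            f"loadings have {spec.loadings.shape[0]} rows but facets have {facets.shape[1]} columns"
        )
    q = spec.loadings.shape[1]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    noise_sd = np.zeros(q) if spec.noise_sd is None else np.broadcast_to(spec.noise_sd, (q,))
    raw = facets.to_numpy() @ spec.loadings + rng.normal(0.0, 1.0, size=(len(facets), q)) * noise_sd
    sd = raw.std(axis=0, ddof=1)
    z = np.zeros_like(raw)
    nondeg = sd > 0
    z[:, nondeg] = (raw[:, nondeg] - raw[:, nondeg].mean(axis=0)) / sd[nondeg]
    labels = spec.condition_labels or [f"C{j + 1:02d}" for j in range(q)]
    return pd.DataFrame(spec.t_mean + spec.t_sd * z, columns=labels, index=facets.index)
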