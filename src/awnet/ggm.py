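"""Sparse Gaussian graphical model estimation with EBIC model selection.

The network is the matrix of L1-regularized partial correlations: the
graphical lasso is solved over a descending log-spaced penalty path and the
precision matrix minimizing the Extended Bayesian Information Criterion is
selected.  Edge weights are the signed partial correlations
``w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)``.

EBIC convention used throughout (constant terms common to the whole path are
dropped, so selection is unaffected):

    EBIC(Theta) = n * [tr(S Theta) - log det Theta] + E log n + 4 E gamma log p

with E the number of nonzero off-diagonal upper-triangle entries of Theta and
gamma in [0, 1] trading denser (gamma=0, ordinary BIC) against sparser
(gamma=1) networks.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .preprocess import CorrelationMatrix

__all__ = ["GGMNetwork", "glasso_path", "ebic", "select_network", "fit_ggm"]


def _as_matrix(S) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(S, CorrelationMatrix):
        return S.to_numpy(), S.node_labels
    return np.asarray(S, dtype=float), None


@dataclass
class GGMNetwork:
    """A selected regularized partial-correlation network."""

    weights: np.ndarray          # p x p signed partial correlations, zero diagonal
    precision: np.ndarray        # selected inverse covariance
    lambda_path: np.ndarray      # descending penalty values
    ebic_values: np.ndarray      # EBIC per path entry
    lambda_selected: float
    gamma: float
    n: int
    node_labels: list[str]

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> list[tuple[str, str, float]]:
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        return [
            (self.node_labels[i], self.node_labels[j], float(self.weights[i, j]))
            for i, j in zip(iu, ju)
        ]

    def to_igraph(self, absolute: bool = False):
        """Undirected weighted igraph view (optionally on absolute weights)."""
        import igraph

        g = igraph.Graph(n=self.p)
        g.vs["name"] = self.node_labels
        edges = self.edge_list()
        g.add_edges([(a, b) for a, b, _ in edges])
        g.es["weight"] = [abs(w) if absolute else w for _, _, w in edges]
        return g

    def write_graphml(self, path) -> None:
        self.to_igraph().write_graphml(str(path))

    def write_edge_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            writer.writerows(self.edge_list())

    def to_dict(self) -> dict:
        return {
            "node_labels": self.node_labels,
            "weights": self.weights.tolist(),
            "precision": self.precision.tolist(),
            "lambda_path": self.lambda_path.tolist(),
            "ebic_values": self.ebic_values.tolist(),
            "lambda_selected": self.lambda_selected,
            "gamma": self.gamma,
            "n": self.n,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, obj: dict) -> "GGMNetwork":
        return cls(
            weights=np.asarray(obj["weights"], dtype=float),
            precision=np.asarray(obj["precision"], dtype=float),
            lambda_path=np.asarray(obj["lambda_path"], dtype=float),
            ebic_values=np.asarray(obj["ebic_values"], dtype=float),
            lambda_selected=float(obj["lambda_selected"]),
            gamma=float(obj["gamma"]),
            n=int(obj["n"]),
            node_labels=list(obj["node_labels"]),
        )


def _solve_glasso(S: np.ndarray, lam: float, tol: float = 1e-4, max_iter: int = 200) -> np.ndarray:
    """One graphical-lasso solve: maximize log det T - tr(ST) - lam*||T||_1,offdiag."""
    if lam <= 0:
        return np.linalg.inv(S)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec = _sk_graphical_lasso(
                S, alpha=lam, tol=tol, enet_tol=tol, max_iter=max_iter
            )
    except FloatingPointError as exc:  # pragma: no cover - solver pathology
        raise RuntimeError(f"graphical lasso failed to converge at lambda={lam:.6g}") from exc
    return (prec + prec.T) / 2.0


def glasso_path(
    S,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Graphical-lasso solutions over a descending log-spaced penalty path.

    The path runs from ``lambda_max`` (the largest off-diagonal |S|, at which
    the solution has no edges) down to ``lambda_max * lambda_min_ratio``.
    Returns (lambda_path, list of precision matrices).
    """
    S_mat, _ = _as_matrix(S)
    if S_mat.shape[0] != S_mat.shape[1] or not np.allclose(S_mat, S_mat.T, atol=1e-10):
        raise ValueError("S must be square symmetric")
    if np.linalg.eigvalsh(S_mat).min() < -1e-8:
        raise ValueError("S must be positive semidefinite")
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    off = np.abs(S_mat - np.diag(np.diag(S_mat)))
    lam_max = off.max()
    if lam_max == 0:  # already diagonal: any penalty gives the same answer
        lambdas = np.array([1.0])
        return lambdas, [np.diag(1.0 / np.diag(S_mat))]
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    return lambdas, [_solve_glasso(S_mat, lam, tol=tol, max_iter=max_iter) for lam in lambdas]


def ebic(precision: np.ndarray, S, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a precision matrix against sample correlation S."""
    S_mat, _ = _as_matrix(S)
    theta = np.asarray(precision, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("precision must be positive definite")
    p = theta.shape[0]
    E = int(np.count_nonzero(np.triu(theta, k=1)))
    loglik_term = np.trace(S_mat @ theta) - logdet
    return float(n * loglik_term + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def select_network(
    path: tuple[np.ndarray, list[np.ndarray]],
    S,
    n: int,
    gamma: float = 0.5,
    node_labels: list[str] | None = None,
) -> GGMNetwork:
    """Pick the minimum-EBIC solution on the path (ties go to the larger
    penalty, i.e. the sparser network) and convert it to edge weights."""
    lambdas, precisions = path
    if len(precisions) == 0:
        raise ValueError("empty penalty path")
    S_mat, labels_from_S = _as_matrix(S)
    scores = np.array([ebic(theta, S_mat, n, gamma) for theta in precisions])
    # lambdas descend, so the first argmin is the sparser of any tied pair
    best = int(np.argmin(scores))
    theta = precisions[best]
    d = np.sqrt(np.diag(theta))
    weights = -theta / np.outer(d, d)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2.0
    p = theta.shape[0]
    labels = node_labels or labels_from_S or [f"V{i + 1:02d}" for i in range(p)]
    return GGMNetwork(
        weights=weights,
        precision=theta,
        lambda_path=np.asarray(lambdas, dtype=float),
        ebic_values=scores,
        lambda_selected=float(lambdas[best]),
        gamma=gamma,
        n=n,
        node_labels=list(labels),
    )


def fit_ggm(
    S,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_labels: list[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> GGMNetwork:
    """Convenience wrapper: penalty path plus EBIC selection in one call."""
    if n < np.shape(_as_matrix(S)[0])[0]:
        warnings.warn("n < p: estimates will be heavily regularized", stacklevel=2)
    path = glasso_path(S, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio, tol=tol, max_iter=max_iter)
    return select_network(path, S, n, gamma=gamma, node_labels=node_labels)
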