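"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the graphical-lasso
oracle is an ADMM solver (the package uses coordinate descent via
scikit-learn), the rank-correlation oracle builds ranks by hand, and the
CS-coefficient oracle is a direct enumeration of the definition.
"""

from __future__ import annotations

import numpy as np


def admm_glasso(S: np.ndarray, lam: float, rho: float = 1.0,
                max_iter: int = 20000, tol: float = 1e-10) -> np.ndarray:
    """ADMM maximization of log det T - tr(ST) - lam * ||T||_1,offdiag."""
    p = S.shape[0]
    Theta = np.eye(p)
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(max_iter):
        # Theta step: eigendecomposition of rho*(Z - U) - S
        vals, vecs = np.linalg.eigh(rho * (Z - U) - S)
        theta_vals = (vals + np.sqrt(vals**2 + 4.0 * rho)) / (2.0 * rho)
        Theta = vecs @ np.diag(theta_vals) @ vecs.T
        # Z step: off-diagonal soft threshold
        Z_old = Z
        A = Theta + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U = U + Theta - Z
        primal = np.linalg.norm(Theta - Z)
        dual = rho * np.linalg.norm(Z - Z_old)
        if primal < tol and dual < tol:
            break
    return (Z + Z.T) / 2.0


def spearman_by_hand(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks, built manually."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def hittner_z_reference(r1: float, r2: float, r12: float, n: int) -> float:
    """Back-transformed-average dependent-correlation z, written step by step."""
    fisher = lambda r: 0.5 * np.log((1 + r) / (1 - r))
    z1, z2 = fisher(r1), fisher(r2)
    zm = (z1 + z2) / 2.0
    rm = (np.exp(2 * zm) - 1) / (np.exp(2 * zm) + 1)  # tanh via exp
    num = r12 * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r12**2)
    c = num / (1 - rm**2) ** 2
    return float((z1 - z2) * np.sqrt((n - 3) / (2 - 2 * c)))


def cs_by_enumeration(table, r_threshold=0.7, coverage=0.95) -> float:
    """CS coefficient straight from its definition, looping over rows."""
    best = 0.0
    for prop in sorted(set(table["proportion"])):
        vals = [
            c for p_, c in zip(table["proportion"], table["correlation"]) if p_ == prop
        ]
        good = sum(1 for c in vals if not np.isnan(c) and c >= r_threshold)
        if good / len(vals) >= coverage:
            best = max(best, float(prop))
    return best


def modularity_by_hand(weights: np.ndarray, membership: np.ndarray) -> float:
    """Weighted Newman modularity on absolute weights, double loop."""
    W = np.abs(np.asarray(weights, dtype=float)).copy()
    np.fill_diagonal(W, 0.0)
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    q = 0.0
    p = len(membership)
    for i in range(p):
        for j in range(p):
            if membership[i] == membership[j]:
                q += W[i, j] - k[i] * k[j] / two_m
    return float(q / two_m)
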