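"""Node centrality and community structure of the selected network.

Centrality is one-step expected influence: the signed sum of a node's edge
weights.  Unlike strength it preserves edge sign, which matters for networks
that can contain negative partial correlations.  Communities come from the
walktrap algorithm — agglomerative merging driven by short-random-walk
distances, cut at maximum modularity — run on absolute edge weights, since
random-walk transition probabilities require non-negative weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ggm import GGMNetwork

__all__ = ["CentralityProfile", "CommunityPartition", "expected_influence", "top_third", "walktrap"]


@dataclass
class CentralityProfile:
    """Raw and z-scored expected influence plus rank and top-third membership.

    ``ei_z`` uses the sample (n-1) standard deviation; a constant ``ei_raw``
    (e.g. the empty network) gives ``ei_z = 0`` by convention.  ``rank`` is
    1..p by descending ``ei_raw``; ``top_third`` marks the round(p/3) highest
    nodes, boundary ties broken by node label order.
    """

    node_labels: list[str]
    ei_raw: np.ndarray
    ei_z: np.ndarray
    rank: np.ndarray
    top_third: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ei_raw": self.ei_raw,
                "ei_z": self.ei_z,
                "rank": self.rank,
                "top_third": self.top_third,
            },
            index=pd.Index(self.node_labels, name="node"),
        )

    @property
    def top_third_nodes(self) -> list[str]:
        return [lab for lab, t in zip(self.node_labels, self.top_third) if t]


def _descending_order(ei_raw: np.ndarray, labels: list[str]) -> np.ndarray:
    """Indices sorted by descending ei_raw; ties resolved by label order."""
    # np.lexsort: last key is primary
    return np.lexsort((np.array(labels), -np.asarray(ei_raw, dtype=float)))


def top_third(ei_raw: np.ndarray, labels: list[str]) -> np.ndarray:
    """Boolean mask of the round(p/3) nodes with highest expected influence."""
    p = len(labels)
    if p < 3:
        raise ValueError("need at least 3 nodes")
    k = round(p / 3)
    order = _descending_order(ei_raw, labels)
    mask = np.zeros(p, dtype=bool)
    mask[order[:k]] = True
    return mask


def expected_influence(net: GGMNetwork, two_step: bool = False) -> CentralityProfile:
    """One-step expected influence EI_i = sum_j w_ij (two-step adds the
    weight-propagated influence of neighbors, behind a flag)."""
    ei = net.weights.sum(axis=1)
    if two_step:
        ei = ei + net.weights @ ei
    sd = ei.std(ddof=1) if net.p > 1 else 0.0
    ei_z = (ei - ei.mean()) / sd if sd > 0 else np.zeros_like(ei)
    order = _descending_order(ei, net.node_labels)
    rank = np.empty(net.p, dtype=int)
    rank[order] = np.arange(1, net.p + 1)
    mask = top_third(ei, net.node_labels) if net.p >= 3 else np.zeros(net.p, dtype=bool)
    return CentralityProfile(
        node_labels=list(net.node_labels),
        ei_raw=ei,
        ei_z=ei_z,
        rank=rank,
        top_third=mask,
    )


@dataclass
class CommunityPartition:
    """Walktrap community assignment with the modularity of the chosen cut."""

    node_labels: list[str]
    membership: np.ndarray
    n_communities: int
    modularity: float
    walk_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"community": self.membership},
            index=pd.Index(self.node_labels, name="node"),
        )


def modularity_from_membership(weights: np.ndarray, membership: np.ndarray) -> float:
    """Newman weighted modularity of a partition, computed on |w| directly."""
    W = np.abs(np.asarray(weights, dtype=float))
    np.fill_diagonal(W, 0.0)
    total = W.sum() / 2.0
    if total == 0:
        return 0.0
    strength = W.sum(axis=1)
    same = membership[:, None] == membership[None, :]
    Q = (W[same].sum() - (np.outer(strength, strength)[same].sum()) / (2.0 * total)) / (2.0 * total)
    return float(Q)


def walktrap(net: GGMNetwork, walk_length: int = 4) -> CommunityPartition:
    """Walktrap communities on the absolute-weight graph.

    Isolated nodes are removed before the walk (a random walk cannot start
    there) and re-attached afterwards as singleton communities.  A fully
    empty network yields all singletons with a warning.  The cut maximizes
    modularity over the merge sequence.
    """
    import igraph

    p = net.p
    W = np.abs(net.weights.copy())
    np.fill_diagonal(W, 0.0)
    degree = W.sum(axis=1)
    connected = np.nonzero(degree > 0)[0]
    membership = np.full(p, -1, dtype=int)

    if len(connected) == 0:
        warnings.warn("network has no edges; every node is its own community", stacklevel=2)
        membership = np.arange(p)
        return CommunityPartition(
            node_labels=list(net.node_labels),
            membership=membership,
            n_communities=p,
            modularity=0.0,
            walk_length=walk_length,
        )

    sub = W[np.ix_(connected, connected)]
    iu, ju = np.nonzero(np.triu(sub, k=1))
    g = igraph.Graph(n=len(connected), edges=list(zip(iu.tolist(), ju.tolist())))
    w = sub[iu, ju].tolist()
    clustering = g.community_walktrap(weights=w, steps=walk_length).as_clustering()
    membership[connected] = clustering.membership
    next_id = max(clustering.membership) + 1
    for idx in np.nonzero(membership < 0)[0]:
        membership[idx] = next_id
        next_id += 1

    return CommunityPartition(
        node_labels=list(net.node_labels),
        membership=membership,
        n_communities=int(membership.max()) + 1,
        modularity=modularity_from_membership(net.weights, membership),
        walk_length=walk_length,
    )
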