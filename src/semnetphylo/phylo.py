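"""Trees, embeddings and clustering evaluation on semantic distance matrices.

Species are clustered with Ward's minimum-variance linkage on the
precomputed semantic distances (technically off-model for a
non-Euclidean distance, but applied as-is; average and complete linkage
remain available for sensitivity checks).  Trees export to Newick,
distance matrices embed into two dimensions by metric MDS, and
partitions are scored with the homogeneity score (HS, cluster purity
with respect to reference taxonomy) and the silhouette score (SS,
cohesion vs separation on the distance matrix itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.manifold import MDS
from sklearn.metrics import homogeneity_score, silhouette_score

from .semantic_compare import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "ClusterLabels",
    "ward_tree",
    "cut_clusters",
    "to_newick",
    "mds_embed",
    "evaluate_clustering",
    "correlate_distances",
]


@dataclass
class Dendrogram:
    """Agglomerative merge history (scipy linkage matrix) plus leaf ids."""

    linkage: np.ndarray
    leaves: tuple[str, ...]
    method: str = "ward"


@dataclass
class ClusterLabels:
    labels: dict[str, int]
    k: int

    def as_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])


def ward_tree(d: DistanceMatrix, method: str = "ward") -> Dendrogram:
    """Hierarchical clustering of species on the precomputed distances."""
    if not np.all(np.isfinite(d.matrix)):
        raise ValueError("distance matrix contains non-finite entries")
    condensed = squareform(d.matrix, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(linkage=Z, leaves=tuple(d.ids), method=method)


def cut_clusters(t: Dendrogram, k: int) -> ClusterLabels:
    """Cut the dendrogram into *k* flat clusters."""
    n = len(t.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    flat = hierarchy.fcluster(t.linkage, t=k, criterion="maxclust")
    return ClusterLabels(labels=dict(zip(t.leaves, map(int, flat))), k=len(set(flat)))


def to_newick(t: Dendrogram) -> str:
    """Serialize the dendrogram as a rooted Newick string with branch lengths."""
    root, nodes = hierarchy.to_tree(t.linkage, rd=True)

    def render(node) -> str:
        if node.is_leaf():
            return t.leaves[node.id]
        left = render(node.left)
        right = render(node.right)
        bl = node.dist - node.left.dist, node.dist - node.right.dist
        return f"({left}:{bl[0]:.6g},{right}:{bl[1]:.6g})"

    return render(root) + ";"


def mds_embed(
    d: DistanceMatrix, dims: int = 2, seed: int | None = None
) -> tuple[np.ndarray, float]:
    """Metric MDS of the species distances; returns coordinates and stress."""
    mds = MDS(
        n_components=dims,
        metric="precomputed",
        metric_mds=True,
        init="random",
        n_init=8,
        max_iter=3000,
        eps=1e-12,
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(d.matrix)
    return coords, float(mds.stress_)


def evaluate_clustering(
    labels: ClusterLabels,
    truth: Mapping[str, str | int],
    d: DistanceMatrix,
) -> tuple[float, float]:
    """(HS, SS) of a partition against reference classes.

    HS follows Rosenberg–Hirschberg homogeneity, with the degenerate
    single-class truth defined as 1.0.  SS is the mean silhouette over
    species on the precomputed distance matrix; a single-cluster
    partition has no silhouette and raises.
    """
    ids = d.ids
    if set(labels.labels) != set(ids) or set(truth) != set(ids):
        raise ValueError("labels, truth and distance matrix must cover the same species")
    y_pred = labels.as_array(ids)
    y_true = np.array([str(truth[i]) for i in ids])
    if len(set(y_true)) == 1:
        logger.info("single-class truth: homogeneity defined as 1.0")
        hs = 1.0
    else:
        hs = float(homogeneity_score(y_true, y_pred))
    if len(set(y_pred.tolist())) < 2:
        logger.info("single-cluster partition: silhouette undefined, returning nan")
        return hs, float("nan")
    ss = float(silhouette_score(d.matrix, y_pred, metric="precomputed"))
    return hs, ss


def correlate_distances(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    max_per_group: int | None = 80,
    groups: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> float:
    """Pearson correlation of two distance matrices over shared species.

    When *groups* maps species to taxonomic domains, at most
    *max_per_group* species per domain are randomly subsampled
    (deterministic under *seed*) before correlating the upper-triangle
    pairwise distances.
    """
    shared = sorted(set(d1.ids) & set(d2.ids))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared species, got {len(shared)}")
    if groups is not None and max_per_group is not None:
        rng = np.random.default_rng(seed)
        chosen: list[str] = []
        by_group: dict[str, list[str]] = {}
        for s in shared:
            by_group.setdefault(str(groups.get(s, "")), []).append(s)
        for g in sorted(by_group):
            members = by_group[g]
            if len(members) > max_per_group:
                members = list(rng.choice(members, size=max_per_group, replace=False))
            chosen.extend(members)
        shared = sorted(chosen)
    m1 = d1.submatrix(shared).matrix
    m2 = d2.submatrix(shared).matrix
    iu = np.triu_indices(len(shared), k=1)
    r, _ = pearsonr(m1[iu], m2[iu])
    return float(r)
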