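"""K-means clustering, elbow-based k selection, and medoid representatives.

Within one decomposition group, frames are featurized by backbone
dihedrals, reduced by PCA, clustered with k-means (k chosen by the
elbow criterion on the inertia curve), and each cluster is summarized
by its medoid: the member frame with the smallest mean superposed RMSD
to all other members. Unlike a coordinate average, a medoid is always a
physically valid conformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .descriptors import kabsch_superpose
from .ensemble import Ensemble
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "kmeans",
    "elbow_select",
    "medoid_representative",
    "cluster_group_pipeline",
]


@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    k: int
    seed: int

    def __post_init__(self) -> None:
        if self.inertia < 0:
            raise ParameterError("inertia must be non-negative")
        if set(np.unique(self.labels)) != set(range(self.k)):
            raise ParameterError("every cluster must be non-empty, labels in [0, k)")


def kmeans(points: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """K-means with k-means++ initialization, best of ``n_init`` restarts,
    deterministic for a given seed."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if not 1 <= k <= len(points):
        raise ParameterError(f"k must be in [1, {len(points)}], got {k}")
    est = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(points)
    return ClusterResult(
        labels=est.labels_,
        centroids=est.cluster_centers_,
        inertia=float(est.inertia_),
        k=k,
        seed=seed,
    )


def elbow_select(
    points: np.ndarray,
    k_range: range | list[int],
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, np.ndarray]:
    """Select k at the elbow of the inertia-vs-k curve.

    The elbow is the interior k maximizing the discrete curvature
    (second difference) of the inertia curve; on a flat curve the
    smallest interior k wins (argmax returns the first maximizer).
    Returns ``(k, inertia_curve)``.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ParameterError("k_range must contain at least 3 values for an elbow")
    points = np.asarray(points, dtype=float)
    n_distinct = len(np.unique(points, axis=0))
    ks = [k for k in ks if k <= n_distinct]
    if len(ks) < 3:
        # fewer distinct points than candidate ks: no elbow to find
        return ks[0] if ks else 1, np.array(
            [kmeans(points, k, seed=seed, n_init=n_init).inertia for k in ks]
        )
    inertias = np.array([kmeans(points, k, seed=seed, n_init=n_init).inertia for k in ks])
    if inertias[0] == 0.0:
        # already perfectly tight at the smallest k: no structure to split
        return ks[0], inertias
    curvature = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
    best = int(np.argmax(curvature))
    return ks[best + 1], inertias


def medoid_representative(
    ensemble: Ensemble,
    member_frames: np.ndarray,
    atom_subset: np.ndarray | None = None,
    max_exact: int = 2000,
    seed: int = 0,
) -> int:
    """Frame index of the cluster medoid.

    The medoid minimizes the mean pairwise superposed RMSD to the other
    members. Exact all-pairs evaluation up to ``max_exact`` members;
    larger sets are subsampled (seeded) to that size for the distance
    targets.
    """
    members = np.asarray(member_frames, dtype=int)
    if members.size == 0:
        raise ParameterError("empty member set")
    if members.size == 1:
        return int(members[0])
    targets = members
    if members.size > max_exact:
        rng = np.random.default_rng(seed)
        targets = rng.choice(members, size=max_exact, replace=False)
        logger.info("medoid search subsampled to %d targets", max_exact)
    best_frame, best_cost = int(members[0]), np.inf
    for f in members:
        cost = 0.0
        for g in targets:
            if f == g:
                continue
            _, _, rmsd = kabsch_superpose(
                ensemble.coords[f], ensemble.coords[g], atom_subset
            )
            cost += rmsd
        cost /= max(len(targets) - 1, 1)
        if cost < best_cost:
            best_frame, best_cost = int(f), cost
    return best_frame


def cluster_group_pipeline(
    ensemble: Ensemble,
    groups,
    group_label: int,
    k_range: range | list[int] = range(1, 9),
    seed: int = 0,
    n_components: int = 2,
) -> dict:
    """Full representative-extraction chain for one decomposition group.

    Dihedral features of the group's frames → PCA to ``n_components``
    → elbow k selection → k-means → medoid per cluster. Returns a dict
    with the selected k, the inertia curve, per-frame cluster labels,
    and the representative (medoid) frame index per cluster, all in
    original-ensemble frame numbering.
    """
    from .landscape import dihedral_features, pca_project

    if group_label not in groups.membership:
        raise ParameterError(f"group {group_label} not present in the decomposition")
    frames = np.asarray(groups.membership[group_label], dtype=int)
    sub = ensemble.subset_frames(frames)
    feats = dihedral_features(sub)
    proj, _, _ = pca_project(feats, n_components=min(n_components, feats.n_features))
    ks = [k for k in sorted(k_range) if k <= len(frames)]
    if len(ks) < len(sorted(k_range)):
        logger.warning("k_range clipped to group size %d", len(frames))
    if len(ks) >= 3:
        k, curve = elbow_select(proj, ks, seed=seed)
    else:
        k, curve = 1, np.array([kmeans(proj, 1, seed=seed).inertia])
    result = kmeans(proj, k, seed=seed)
    representatives = {}
    for c in range(k):
        members = frames[result.labels == c]
        representatives[c] = medoid_representative(ensemble, members, seed=seed)
    return {
        "group": group_label,
        "k": k,
        "inertia_curve": curve,
        "frame_labels": dict(zip(frames.tolist(), result.labels.tolist())),
        "representatives": representatives,
        "cluster_result": result,
    }
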