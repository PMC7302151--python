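"""Structure discovery on fold-change profiles.

Rows (entities) are clustered hierarchically on Spearman correlation
distance and cut into k clusters (k = 8 in the study design); columns
(timepoints) are clustered on Euclidean distance and cut into temporal
phases (3 in the study design). A sample-level PCA on the imputed log2
intensity matrix provides an orthogonal view of the phase structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .model import FoldChangeTable, IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSummary",
    "PCAResult",
    "spearman_distance_matrix",
    "hierarchical_cut",
    "cluster_means",
    "column_phase_grouping",
    "pca_samples",
]


@dataclass
class ClusterSummary:
    cluster_index: int
    size: int
    mean_profile: pd.Series  # indexed by timepoint


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample x component
    variance_fractions: np.ndarray


def spearman_distance_matrix(fc: FoldChangeTable) -> pd.DataFrame:
    """Pairwise 1 - Spearman rho between entity profiles (range [0, 2]).

    Ties in ranks are averaged. A constant profile has undefined rho; its
    distance to every other entity is set to 1 (and 0 to itself) with a
    warning.
    """
    values = fc.data.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2 or values.shape[1] < 3:
        raise ValueError("need >= 2 entities and >= 3 timepoints")
    constant = values.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "%d constant profiles; Spearman undefined, distance set to 1",
            int(constant.sum()),
        )

    # Spearman rho = Pearson correlation of average ranks
    ranks = np.apply_along_axis(rankdata, 1, values)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    dist = 1.0 - np.asarray(rho, dtype=float)
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(dist, index=fc.data.index.copy(), columns=fc.data.index.copy())


def hierarchical_cut(
    dist: pd.DataFrame, k: int = 8, linkage: str = "average"
) -> dict[str, int]:
    """Agglomerative clustering of a distance matrix cut into k clusters.

    Returns entity -> cluster index in [1, k]; cluster indices follow
    scipy's deterministic dendrogram ordering, so cuts at increasing k are
    nested partitions.
    """
    n = dist.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    return {entity: int(lbl) for entity, lbl in zip(dist.index, labels)}


def cluster_means(
    fc: FoldChangeTable, assignments: dict[str, int]
) -> list[ClusterSummary]:
    """Per-cluster, per-timepoint arithmetic mean of member fold changes."""
    missing = set(fc.entity_ids) - set(assignments)
    if missing:
        raise ValueError(f"{len(missing)} entities lack a cluster assignment")
    labels = pd.Series({e: assignments[e] for e in fc.entity_ids}, name="cluster")
    grouped = fc.data.groupby(labels).mean()
    sizes = labels.value_counts()
    return [
        ClusterSummary(int(idx), int(sizes[idx]), grouped.loc[idx])
        for idx in sorted(grouped.index)
    ]


def column_phase_grouping(
    fc: FoldChangeTable, n_phases: int = 3, linkage: str = "average"
) -> dict[float, int]:
    """Group timepoint columns into temporal phases by Euclidean clustering.

    Returns timepoint -> phase index in [1, n_phases]. The study design
    yields three phases over six timepoints with 12 h as the switch point
    and day 10 well separated from everything earlier.
    """
    cols = fc.data.to_numpy(dtype=float).T  # timepoint x entity
    if n_phases > cols.shape[0]:
        raise ValueError(f"n_phases {n_phases} exceeds {cols.shape[0]} timepoints")
    tree = hierarchy.linkage(cols, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(tree, t=n_phases, criterion="maxclust")
    return {tp: int(lbl) for tp, lbl in zip(fc.timepoints, labels)}


def pca_samples(matrix: IntensityMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of samples (observations) over entities (features), centered only.

    No unit-variance scaling: log2 LFQ magnitudes carry signal.
    """
    x = matrix.data.to_numpy(dtype=float).T  # sample x entity
    if x.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples")
    if np.isnan(x).any():
        raise ValueError("PCA expects an imputed (complete) matrix")
    n_components = n_components or min(x.shape)
    model = PCA(n_components=n_components)
    scores = model.fit_transform(x)
    frame = pd.DataFrame(
        scores,
        index=[s.label for s in matrix.samples],
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PCAResult(frame, model.explained_variance_ratio_)
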