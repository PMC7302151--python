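"""Functional-category summaries over clusters and omics layers.

``top_categories`` ranks the functional categories within each fold-change
cluster (the study labels each cluster's five most frequent categories its
"primary functional proteins"). ``category_delta`` builds the per-category
transcript-minus-protein fold-change matrix (LogetT - LogetP), the layer
comparison behind the study's category heatmap.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .model import AnnotationRecord, FoldChangeTable, UNKNOWN_CATEGORY

logger = logging.getLogger(__name__)

__all__ = ["CategoryFrequency", "CategoryDeltaMatrix", "top_categories", "category_delta"]


@dataclass
class CategoryFrequency:
    cluster_index: int
    category: str
    count: int
    rank: int
    is_top: bool


@dataclass
class CategoryDeltaMatrix:
    """Category x timepoint mean matrices per layer plus their difference."""

    mean_transcript: pd.DataFrame
    mean_protein: pd.DataFrame
    delta: pd.DataFrame  # meanT - meanP on shared timepoints


def top_categories(
    assignments: dict[str, int],
    annotations: list[AnnotationRecord],
    n_top: int = 5,
) -> list[CategoryFrequency]:
    """Rank category counts within each cluster, flagging the top ``n_top``.

    Unannotated entities count as UNKNOWN. Equal counts are broken
    alphabetically by category name.
    """
    category_of = {a.entity_id: a.functional_category for a in annotations}
    per_cluster: dict[int, Counter] = {}
    for entity, cluster in assignments.items():
        cat = category_of.get(entity, UNKNOWN_CATEGORY)
        per_cluster.setdefault(cluster, Counter())[cat] += 1

    out: list[CategoryFrequency] = []
    for cluster in sorted(per_cluster):
        ranked = sorted(per_cluster[cluster].items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (cat, count) in enumerate(ranked, start=1):
            out.append(CategoryFrequency(cluster, cat, count, rank, rank <= n_top))
    return out


def category_delta(
    fc_t: FoldChangeTable,
    fc_p: FoldChangeTable,
    annotations: list[AnnotationRecord],
    statistic: str = "mean",
    intersect_members: bool = False,
) -> CategoryDeltaMatrix:
    """Per-category layer means and their difference on shared timepoints.

    By default each layer aggregates over its own detected members of a
    category (the layers' detected gene sets differ); ``intersect_members``
    restricts both layers to genes detected in both. ``statistic`` is
    ``mean`` (default) or ``median``. Categories with no members in either
    layer are omitted with a warning.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    shared_tps = sorted(set(fc_t.timepoints) & set(fc_p.timepoints))
    if not shared_tps:
        raise ValueError("the two layers share no timepoints")

    category_of = {a.entity_id: a.functional_category for a in annotations}
    if intersect_members:
        common = set(fc_t.entity_ids) & set(fc_p.entity_ids)
    else:
        common = None

    def layer_means(fc: FoldChangeTable) -> pd.DataFrame:
        members = [
            e for e in fc.entity_ids if e in category_of and (common is None or e in common)
        ]
        sub = fc.data.loc[members]
        cats = pd.Series({e: category_of[e] for e in members}, name="category")
        agg = sub.groupby(cats)
        return agg.mean() if statistic == "mean" else agg.median()

    mean_t, mean_p = layer_means(fc_t), layer_means(fc_p)
    categories = sorted(set(mean_t.index) | set(mean_p.index))
    dropped = [c for c in categories if c not in mean_t.index and c not in mean_p.index]
    for cat in dropped:
        logger.warning("category %r has no members in either layer; omitted", cat)

    delta = mean_t.reindex(categories)[shared_tps] - mean_p.reindex(categories)[shared_tps]
    return CategoryDeltaMatrix(mean_t, mean_p, delta)


def frequencies_to_frame(freqs: list[CategoryFrequency]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.cluster_index, f.category, f.count, f.rank, f.is_top) for f in freqs],
        columns=["cluster", "category", "count", "rank", "is_top"],
    )
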