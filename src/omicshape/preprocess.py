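"""Label-free-quantification preprocessing.

Reproduces the Perseus-style workflow for paired N-/N+ time courses:
log2 transform, a "quantified in at least half" missingness filter,
imputation from a down-shifted normal distribution (width 0.3, down shift
1.8 column-SD units by default), replicate-mean log2(N-/N+) fold changes,
and per-timepoint Welch t-tests with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    Condition,
    ConfigurationError,
    FoldChangeTable,
    IntensityMatrix,
    OmicsLayer,
    Scale,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterMode",
    "FilterReport",
    "ImputationParams",
    "DifferentialResult",
    "log2_transform",
    "filter_min_quantified",
    "impute_downshifted_normal",
    "fold_change",
    "differential_test",
]


class FilterMode(str, Enum):
    #: count non-missing samples within each condition
    SAMPLE_LEVEL = "sample"
    #: count timepoints with >= 1 non-missing replicate within each condition
    TIMEPOINT_LEVEL = "timepoint"


@dataclass
class FilterReport:
    kept_ids: list[str]
    removed_ids: list[str]
    mode: FilterMode
    min_fraction: float


@dataclass
class ImputationParams:
    """Down-shifted normal imputation parameters, in column-SD units.

    Missing cells in column j are drawn from
    Normal(mean_j - down_shift * sd_j, (width * sd_j)^2) where mean_j / sd_j
    are computed over the column's present values.
    """

    width: float = 0.3
    down_shift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError(f"width must be > 0, got {self.width}")
        if self.down_shift < 0:
            raise ConfigurationError(f"down_shift must be >= 0, got {self.down_shift}")


@dataclass
class DifferentialResult:
    entity_id: str
    timepoint_hours: float
    t_statistic: float
    p_value: float
    q_value: float = math.nan
    significant: bool = False


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform a RAW matrix; MISSING cells stay missing."""
    if matrix.scale is not Scale.RAW:
        raise ValueError("matrix is already on the log2 scale")
    values = matrix.data.to_numpy(dtype=float)
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at entity {matrix.data.index[i]!r}, "
            f"sample {matrix.data.columns[j]!r}"
        )
    out = matrix.data.copy()
    out.iloc[:, :] = np.log2(values)
    return IntensityMatrix(out, list(matrix.samples), Scale.LOG2)


def filter_min_quantified(
    matrix: IntensityMatrix,
    min_fraction: float = 0.5,
    mode: FilterMode = FilterMode.SAMPLE_LEVEL,
) -> tuple[IntensityMatrix, FilterReport]:
    """Keep entities quantified in at least ``min_fraction`` of each condition.

    SAMPLE_LEVEL counts non-missing samples per condition; TIMEPOINT_LEVEL
    counts timepoints with at least one non-missing replicate. The threshold
    is ``ceil(min_fraction * count)`` within EACH condition.
    """
    if not 0 < min_fraction <= 1:
        raise ConfigurationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise ConfigurationError("both N- and N+ samples are required for filtering")

    present = ~matrix.data.isna().to_numpy()
    keep = np.ones(matrix.n_entities, dtype=bool)
    for cond in conditions:
        cols = matrix.columns_where(condition=cond)
        if not cols:
            raise ConfigurationError(f"no samples for condition {cond.value}")
        if mode is FilterMode.SAMPLE_LEVEL:
            need = math.ceil(min_fraction * len(cols))
            keep &= present[:, cols].sum(axis=1) >= need
        else:
            tps = sorted({matrix.samples[c].timepoint_hours for c in cols})
            need = math.ceil(min_fraction * len(tps))
            quantified = np.zeros(matrix.n_entities, dtype=int)
            for tp in tps:
                tp_cols = matrix.columns_where(condition=cond, timepoint_hours=tp)
                quantified += present[:, tp_cols].any(axis=1)
            keep &= quantified >= need

    ids = np.asarray(matrix.entity_ids)
    kept, removed = ids[keep].tolist(), ids[~keep].tolist()
    logger.info(
        "min-quantified filter (%s, %.2f): %d of %d entities remained",
        mode.value,
        min_fraction,
        len(kept),
        len(ids),
    )
    report = FilterReport(kept, removed, mode, min_fraction)
    return matrix.subset_entities(kept), report


def impute_downshifted_normal(
    matrix: IntensityMatrix, params: ImputationParams | None = None
) -> IntensityMatrix:
    """Replace MISSING log2 cells with down-shifted normal draws per column.

    One seeded stream is consumed column-by-column in sample order, so the
    output is bit-reproducible and independent of entity iteration order.
    Column statistics use the present values only (sample SD, ddof=1).
    """
    if matrix.scale is not Scale.LOG2:
        raise ValueError("imputation expects a log2-scale matrix")
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    values = matrix.data.to_numpy(dtype=float).copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        missing = np.isnan(col)
        present = col[~missing]
        if present.size < 2:
            raise ValueError(
                f"column {matrix.data.columns[j]!r} has < 2 present values; "
                "SD is undefined"
            )
        if not missing.any():
            continue
        mean, sd = present.mean(), present.std(ddof=1)
        col[missing] = rng.normal(
            mean - params.down_shift * sd, params.width * sd, size=int(missing.sum())
        )
    out = matrix.data.copy()
    out.iloc[:, :] = values
    return IntensityMatrix(out, list(matrix.samples), Scale.LOG2)


def fold_change(matrix: IntensityMatrix, layer: OmicsLayer) -> FoldChangeTable:
    """Replicate-mean log2(N-/N+) ratios per entity per timepoint.

    Means are taken on the log2 scale within each (condition, timepoint);
    the fold change is mean(N-) - mean(N+). Timepoints present in only one
    condition are excluded with a warning.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValueError("fold changes are computed on the log2 scale")
    tps_minus = {s.timepoint_hours for s in matrix.samples if s.condition is Condition.N_MINUS}
    tps_plus = {s.timepoint_hours for s in matrix.samples if s.condition is Condition.N_PLUS}
    shared = sorted(tps_minus & tps_plus)
    for tp in sorted(tps_minus ^ tps_plus):
        logger.warning("timepoint %g h present in only one condition; excluded", tp)
    if not shared:
        raise ConfigurationError("no timepoint is present in both conditions")

    values = np.empty((matrix.n_entities, len(shared)))
    for j, tp in enumerate(shared):
        minus = matrix.columns_where(Condition.N_MINUS, tp)
        plus = matrix.columns_where(Condition.N_PLUS, tp)
        grid = matrix.data.to_numpy(dtype=float)
        values[:, j] = grid[:, minus].mean(axis=1) - grid[:, plus].mean(axis=1)

    frame = pd.DataFrame(values, index=matrix.data.index.copy(), columns=shared)
    return FoldChangeTable(frame, layer)


def differential_test(
    matrix: IntensityMatrix,
    level: float = 0.05,
    equal_var: bool = False,
    pooled: bool = False,
) -> list[DifferentialResult]:
    """Per-entity N- vs N+ t-tests with BH FDR control.

    By default a Welch (unequal-variance) two-sample t-test is run per
    timepoint and Benjamini-Hochberg adjustment is applied across entities
    within each timepoint; ``pooled=True`` instead pools all samples of each
    condition into a single test per entity. Zero variance in both groups is
    resolved by convention: equal means -> p = 1, unequal means -> p = 0.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValueError("differential testing expects log2 intensities")
    grid = matrix.data.to_numpy(dtype=float)
    if np.isnan(grid).any():
        raise ValueError("differential testing expects an imputed (complete) matrix")

    timepoint_groups: list[tuple[float, list[int], list[int]]] = []
    if pooled:
        timepoint_groups.append(
            (
                math.nan,
                matrix.columns_where(Condition.N_MINUS),
                matrix.columns_where(Condition.N_PLUS),
            )
        )
    else:
        for tp in matrix.timepoints:
            minus = matrix.columns_where(Condition.N_MINUS, tp)
            plus = matrix.columns_where(Condition.N_PLUS, tp)
            if len(minus) < 2 or len(plus) < 2:
                raise ConfigurationError(
                    f">= 2 replicates per condition required at {tp} h"
                )
            timepoint_groups.append((tp, minus, plus))

    results: list[DifferentialResult] = []
    for tp, minus, plus in timepoint_groups:
        a, b = grid[:, minus], grid[:, plus]
        t_stat, p_val = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        t_stat, p_val = np.asarray(t_stat, float), np.asarray(p_val, float)
        degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
        if degenerate.any():
            same = np.isclose(a.mean(axis=1), b.mean(axis=1))
            p_val[degenerate & same] = 1.0
            t_stat[degenerate & same] = 0.0
            p_val[degenerate & ~same] = 0.0
            t_stat[degenerate & ~same] = math.inf
            logger.info(
                "%d zero-variance entities at %s h resolved by convention",
                int(degenerate.sum()),
                tp,
            )
        _, q_val, _, _ = multipletests(p_val, alpha=level, method="fdr_bh")
        for i, entity in enumerate(matrix.entity_ids):
            results.append(
                DifferentialResult(
                    entity_id=entity,
                    timepoint_hours=tp,
                    t_statistic=float(t_stat[i]),
                    p_value=float(p_val[i]),
                    q_value=float(q_val[i]),
                    significant=bool(q_val[i] <= level),
                )
            )
    return results
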