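"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators:

* :func:`generate_paired_series` emits paired transcript/protein log2-ratio
  trajectories. A "delayed" pair shares a base shape — the protein is the
  transcript shifted by a whole number of timepoints (edge-padded),
  rescaled, and perturbed with Gaussian noise — emulating a proteome that
  follows its transcriptome with a lag. An "independent" pair draws a fresh
  base shape for the protein. Ground-truth labels travel with the fixture,
  so SBD-based concordance calls can be scored against truth.

* :func:`generate_lfq_matrix` emits a label-free-quantification intensity
  matrix with intensity-dependent (MNAR) missingness: the probability that
  a cell is unquantified is logistic in its negative log2 intensity, so
  dim measurements vanish preferentially — the structure that motivates
  down-shifted normal imputation.

Base trajectories are random walks (cumulative Gaussian steps): irregular
monotone/zigzag shapes like observed fold-change cluster profiles, without
committing to a parametric family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    Condition,
    ConfigurationError,
    FoldChangeTable,
    IntensityMatrix,
    OmicsLayer,
    SampleKey,
    Scale,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PairTruth",
    "LfqEffectModel",
    "MatrixTruth",
    "STUDY_TIMEPOINTS_SHARED",
    "STUDY_TIMEPOINTS_PROTEOME",
    "generate_paired_series",
    "generate_lfq_matrix",
]

#: timepoints (h) shared by both omics layers in the study design
STUDY_TIMEPOINTS_SHARED = (3.0, 6.0, 12.0, 24.0, 48.0)
#: proteome design adds the 10th-day sample
STUDY_TIMEPOINTS_PROTEOME = (3.0, 6.0, 12.0, 24.0, 48.0, 240.0)


@dataclass
class PairTruth:
    entity_id: str
    is_delayed_copy: bool
    delay: int = 0
    scale: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class LfqEffectModel:
    """Log2-scale generative parameters for one LFQ matrix.

    ``baseline_mean``/``baseline_sd`` place per-entity abundances on the
    log2-LFQ scale; ``effect_step_sd`` drives a per-entity random-walk
    treatment effect over timepoints under N-; ``replicate_sd`` is i.i.d.
    measurement noise.
    """

    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    effect_step_sd: float = 0.5
    replicate_sd: float = 0.4


@dataclass
class MatrixTruth:
    true_log2_means: pd.DataFrame  # entity x (condition, timepoint) mean log2 intensity
    missing_intercept: float
    missing_slope: float
    seed: int


def _random_walk(rng: np.random.Generator, m: int) -> np.ndarray:
    return np.cumsum(rng.normal(size=m))


def generate_paired_series(
    n_pairs: int,
    frac_delayed: float = 0.5,
    m: int = 5,
    delay_choices: tuple[int, ...] = (0, 1, 2),
    noise_sd: float = 0.2,
    scale_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> tuple[FoldChangeTable, FoldChangeTable, list[PairTruth]]:
    """Paired transcript/protein fold-change tables with truth labels.

    The first ``round(frac_delayed * n_pairs)`` entities are delayed copies,
    the rest independent; all randomness flows from ``seed``. Timepoints are
    the study's shared grid when ``m == 5``, otherwise a doubling grid.
    """
    if not 0 <= frac_delayed <= 1:
        raise ConfigurationError(f"frac_delayed must be in [0, 1], got {frac_delayed}")
    if m < 3:
        raise ConfigurationError(f"m must be >= 3, got {m}")
    if max(delay_choices) >= m:
        raise ConfigurationError(f"delays {delay_choices} must be < m = {m}")

    rng = np.random.default_rng(seed)
    timepoints = (
        list(STUDY_TIMEPOINTS_SHARED) if m == 5 else [3.0 * 2**i for i in range(m)]
    )
    n_delayed = round(frac_delayed * n_pairs)

    t_rows, p_rows, truths = [], [], []
    for i in range(n_pairs):
        entity = f"SYN_{i + 1:05d}"
        base = _random_walk(rng, m)
        delayed = i < n_delayed
        if delayed:
            delay = int(rng.choice(delay_choices))
            scale = float(np.exp(rng.uniform(np.log(scale_range[0]), np.log(scale_range[1]))))
            shifted = np.concatenate([np.full(delay, base[0]), base[: m - delay]])
            protein = scale * shifted + rng.normal(0.0, noise_sd, size=m)
            truths.append(PairTruth(entity, True, delay, scale, noise_sd, seed))
        else:
            protein = _random_walk(rng, m) + rng.normal(0.0, noise_sd, size=m)
            truths.append(PairTruth(entity, False, 0, 1.0, noise_sd, seed))
        t_rows.append(base)
        p_rows.append(protein)

    index = pd.Index([t.entity_id for t in truths], name="entity_id")
    fc_t = FoldChangeTable(pd.DataFrame(t_rows, index=index, columns=timepoints), OmicsLayer.TRANSCRIPT)
    fc_p = FoldChangeTable(pd.DataFrame(p_rows, index=index.copy(), columns=timepoints), OmicsLayer.PROTEIN)
    return fc_t, fc_p, truths


def generate_lfq_matrix(
    n_entities: int,
    timepoints: tuple[float, ...] = STUDY_TIMEPOINTS_PROTEOME,
    n_reps: int = 3,
    effect_model: LfqEffectModel | None = None,
    missing_intercept: float = -2.0,
    missing_slope: float = 0.8,
    seed: int = 0,
) -> tuple[IntensityMatrix, MatrixTruth]:
    """RAW LFQ intensity matrix with MNAR missingness plus its truth.

    Cell intensities are log-normal around per-entity condition/timepoint
    means; each cell is masked MISSING with probability
    ``expit(intercept + slope * (baseline_mean - log2 intensity))``
    (``slope >= 0`` makes dim cells vanish more often; ``slope = 0`` gives a
    flat rate ``expit(intercept)``, and ``intercept = -inf`` disables
    missingness entirely). Columns left with fewer than two present values
    raise, since downstream imputation would be undefined.
    """
    if missing_slope < 0:
        raise ConfigurationError(f"missing_slope must be >= 0, got {missing_slope}")
    model = effect_model or LfqEffectModel()
    rng = np.random.default_rng(seed)

    samples = [
        SampleKey(cond, tp, rep)
        for cond in (Condition.N_MINUS, Condition.N_PLUS)
        for tp in timepoints
        for rep in range(1, n_reps + 1)
    ]
    entities = [f"GEN_{i + 1:05d}" for i in range(n_entities)]

    baseline = rng.normal(model.baseline_mean, model.baseline_sd, size=n_entities)
    effect = np.cumsum(
        rng.normal(0.0, model.effect_step_sd, size=(n_entities, len(timepoints))), axis=1
    )
    tp_index = {tp: j for j, tp in enumerate(timepoints)}

    means = np.empty((n_entities, len(samples)))
    for c, key in enumerate(samples):
        mu = baseline.copy()
        if key.condition is Condition.N_MINUS:
            mu = mu + effect[:, tp_index[key.timepoint_hours]]
        means[:, c] = mu

    log2_vals = means + rng.normal(0.0, model.replicate_sd, size=means.shape)
    p_missing = expit(missing_intercept + missing_slope * (model.baseline_mean - log2_vals))
    mask = rng.uniform(size=log2_vals.shape) < p_missing

    raw = np.power(2.0, log2_vals)
    raw[mask] = np.nan
    low = (~np.isnan(raw)).sum(axis=0) < 2
    if low.any():
        raise ConfigurationError(
            "missingness parameters left a column with < 2 quantified values"
        )

    data = pd.DataFrame(
        raw, index=pd.Index(entities, name="entity_id"), columns=[s.label for s in samples]
    )
    truth_means = pd.DataFrame(
        means, index=data.index.copy(), columns=[s.label for s in samples]
    )
    logger.info(
        "generated %d x %d LFQ matrix, %.1f%% missing",
        n_entities,
        len(samples),
        100.0 * mask.mean(),
    )
    matrix = IntensityMatrix(data, samples, Scale.RAW)
    return matrix, MatrixTruth(truth_means, missing_intercept, missing_slope, seed)
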