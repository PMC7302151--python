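"""Shape-based distance (SBD) and k-shape clustering.

The shape-based distance between two equal-length series is

    SBD(x, y) = 1 - max_w NCCc(x, y)[w]

where NCCc is the coefficient-normalized cross-correlation of the
z-normalized series, bounded in [-1, 1] over shifts w in [-(m-1), m-1].
SBD lies in [0, 2]; 0 means identical shape up to a shift and a positive
affine rescaling. Because a protein trajectory often reproduces its
transcript's trajectory with a temporal delay and amplitude change, SBD
captures transcript/protein concordance that a point-by-point comparison
misses.

Shift sign convention: a positive ``best_shift`` means the SECOND series
lags (is a delayed copy of) the first.

The k-shape clusterer alternates SBD-based assignment with eigenvector-based
shape extraction until assignments stabilise.

The time axis is treated as equally spaced ranks: the study's 3/6/12/24/48 h
design is uneven in hours, but 5-6 point series cannot support
continuous-time alignment, and cross-correlation shifts are index shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import linalg, signal

from .model import ConfigurationError, FoldChangeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityClass",
    "TimeProfile",
    "SBDRecord",
    "QuartileThresholds",
    "KShapeModel",
    "znormalize",
    "is_degenerate",
    "ncc_c",
    "sbd",
    "pair_profiles",
    "classify_similarity",
    "kshape_extract_shape",
    "kshape_cluster",
]


class SimilarityClass(str, Enum):
    HIGHLY_SIMILAR = "highly_similar"
    INDISTINCT = "indistinct"
    HIGHLY_UNSIMILAR = "highly_unsimilar"


@dataclass
class TimeProfile:
    """One entity's trajectory over >= 3 ordered timepoints (no missing)."""

    entity_id: str
    timepoints_hours: np.ndarray
    values: np.ndarray
    layer: str = ""

    def __post_init__(self) -> None:
        self.timepoints_hours = np.asarray(self.timepoints_hours, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 3:
            raise ValueError("a time profile needs >= 3 points")
        if np.any(np.diff(self.timepoints_hours) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile {self.entity_id!r} contains non-finite values")


@dataclass
class SBDRecord:
    entity_id: str
    sbd: float
    best_shift: int
    ncc_max: float
    similarity_class: SimilarityClass | None = None


@dataclass
class QuartileThresholds:
    q1: float
    q3: float
    n: int
    method: str = "linear"


@dataclass
class KShapeModel:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray  # k x m, z-normalized rows
    n_iterations: int
    converged: bool
    seed: int
    objective_trace: list[float] = field(default_factory=list)


def znormalize(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to unit population SD.

    A zero-variance (degenerate) input maps to the all-zero vector; callers
    can detect this with :func:`is_degenerate`. Idempotent.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("z-normalization needs >= 2 points")
    sd = x.std()  # population (1/m) convention
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def is_degenerate(x: np.ndarray) -> bool:
    """True for zero-variance series (which z-normalize to all zeros)."""
    return bool(np.asarray(x, dtype=float).std() == 0)


def ncc_c(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficient-normalized cross-correlation over all 2m-1 shifts.

    Inputs are z-normalized internally. Entry ``i`` holds the coefficient at
    shift ``w = i - (m - 1)``; coefficients lie in [-1, 1]. Positive ``w``
    means ``y`` lags ``x``. Degenerate inputs yield all-zero coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be equal-length 1-D, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    xz, yz = znormalize(x), znormalize(y)
    den = np.linalg.norm(xz) * np.linalg.norm(yz)
    if den == 0:
        return np.zeros(2 * x.size - 1)
    # cc[w] = sum_t x[t] * y[t + w], zero-padded; FFT-accelerated
    cc = signal.correlate(yz, xz, mode="full", method="fft")
    return np.clip(cc / den, -1.0, 1.0)


def sbd(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Shape-based distance, best shift and max cross-correlation.

    Returns ``(1 - ncc_max, best_shift, ncc_max)``. Ties on the maximum are
    broken toward the smallest absolute shift, then negative before positive.
    Degenerate inputs: both flat -> distance 0 (identical shapes); exactly
    one flat -> distance 1 (the uninformative midpoint).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_flat, y_flat = is_degenerate(x), is_degenerate(y)
    if x_flat and y_flat:
        return 0.0, 0, 1.0
    if x_flat or y_flat:
        logger.debug("SBD against a zero-variance series defined as 1")
        return 1.0, 0, 0.0

    coeffs = ncc_c(x, y)
    m = x.size
    shifts = np.arange(-(m - 1), m)
    best = coeffs.max()
    tied = shifts[np.isclose(coeffs, best, rtol=0.0, atol=0.0) | (coeffs == best)]
    # smallest |shift| first, negative before positive
    best_shift = int(min(tied, key=lambda w: (abs(w), w > 0)))
    return float(1.0 - best), best_shift, float(best)


def _sbd_oracle_align(y: np.ndarray, shift: int) -> np.ndarray:
    """Shift ``y`` by ``-shift`` with zero padding (align a lagging copy back)."""
    m = y.size
    out = np.zeros(m)
    if shift >= 0:
        out[: m - shift] = y[shift:]
    else:
        out[-shift:] = y[: m + shift]
    return out


def pair_profiles(
    fc_t: FoldChangeTable, fc_p: FoldChangeTable
) -> tuple[list[tuple[TimeProfile, TimeProfile]], list[str]]:
    """Pair transcript/protein trajectories over their shared timepoints.

    Returns ``(pairs, unpaired_ids)``; each pair is restricted to the
    ascending intersection of timepoints (>= 3 required).
    """
    shared_tps = sorted(set(fc_t.timepoints) & set(fc_p.timepoints))
    if len(shared_tps) < 3:
        raise ConfigurationError(
            f"only {len(shared_tps)} shared timepoints; >= 3 required"
        )
    t_ids, p_ids = set(fc_t.entity_ids), set(fc_p.entity_ids)
    shared_ids = [e for e in fc_t.entity_ids if e in p_ids]
    unpaired = sorted((t_ids | p_ids) - (t_ids & p_ids))

    tps = np.asarray(shared_tps)
    pairs = []
    for entity in shared_ids:
        t_vals = fc_t.data.loc[entity, shared_tps].to_numpy(dtype=float)
        p_vals = fc_p.data.loc[entity, shared_tps].to_numpy(dtype=float)
        pairs.append(
            (
                TimeProfile(entity, tps, t_vals, layer=fc_t.layer.value),
                TimeProfile(entity, tps, p_vals, layer=fc_p.layer.value),
            )
        )
    logger.info(
        "paired %d entities over %d shared timepoints (%d unpaired)",
        len(pairs),
        len(shared_tps),
        len(unpaired),
    )
    return pairs, unpaired


def classify_similarity(
    records: list[SBDRecord],
    reference: list[float] | None = None,
    method: str = "linear",
) -> tuple[list[SBDRecord], QuartileThresholds]:
    """Three-way concordance classes from the quartiles of the SBD pool.

    SBD strictly below the lower quartile -> HIGHLY_SIMILAR; strictly above
    the upper quartile -> HIGHLY_UNSIMILAR; otherwise INDISTINCT. The
    reference pool defaults to the records themselves (all paired genes).
    """
    ref = np.asarray(
        reference if reference is not None else [r.sbd for r in records], dtype=float
    )
    if ref.size < 4:
        raise ConfigurationError(f"reference set of {ref.size} SBDs; >= 4 required")
    q1, q3 = np.percentile(ref, [25, 75], method=method)
    out = []
    for rec in records:
        if rec.sbd < q1:
            cls = SimilarityClass.HIGHLY_SIMILAR
        elif rec.sbd > q3:
            cls = SimilarityClass.HIGHLY_UNSIMILAR
        else:
            cls = SimilarityClass.INDISTINCT
        out.append(SBDRecord(rec.entity_id, rec.sbd, rec.best_shift, rec.ncc_max, cls))
    return out, QuartileThresholds(float(q1), float(q3), int(ref.size), method)


def kshape_extract_shape(
    members: np.ndarray, current_centroid: np.ndarray
) -> np.ndarray:
    """Update one cluster's shape centroid from its members.

    Members are aligned to the current centroid at their optimal SBD shift
    (zero-padded), then the centroid is the principal eigenvector of
    ``Q^T S Q`` with ``S = sum_i y_i y_i^T`` over aligned members and
    ``Q = I - (1/m) 1 1^T`` (the centering projector), with the sign chosen
    to correlate non-negatively with the aligned-member mean; the result is
    z-normalized. An empty member set returns the centroid unchanged.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    m = current_centroid.size
    if members.size == 0:
        logger.debug("shape extraction on an empty cluster; centroid kept")
        return current_centroid.copy()

    aligned = np.empty((members.shape[0], m))
    for i, y in enumerate(members):
        if is_degenerate(current_centroid):
            aligned[i] = znormalize(y)
        else:
            _, shift, _ = sbd(current_centroid, y)
            aligned[i] = _sbd_oracle_align(znormalize(y), shift)

    s_mat = aligned.T @ aligned
    q = np.eye(m) - np.ones((m, m)) / m
    mmat = q @ s_mat @ q
    _, vecs = linalg.eigh(mmat, subset_by_index=[m - 1, m - 1])
    centroid = vecs[:, 0]
    if centroid @ aligned.mean(axis=0) < 0:
        centroid = -centroid
    if is_degenerate(centroid):
        return np.zeros(m)
    return znormalize(centroid)


def kshape_cluster(
    profiles: list[TimeProfile],
    k: int,
    seed: int = 0,
    max_iter: int = 100,
) -> KShapeModel:
    """Iterative-refinement (k-shape) clustering of trajectories.

    Starts from a random assignment and alternates per-cluster shape
    extraction with SBD-minimizing reassignment until assignments stop
    changing or ``max_iter`` is reached. An emptied cluster is reseeded with
    the profile farthest from its own centroid.
    """
    n = len(profiles)
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    series = np.stack([znormalize(p.values) for p in profiles])
    m = series.shape[1]

    labels = rng.integers(0, k, size=n)
    centroids = np.zeros((k, m))
    converged = False
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for j in range(k):
            mask = labels == j
            if mask.any():
                centroids[j] = kshape_extract_shape(series[mask], centroids[j])

        dist = np.empty((n, k))
        for i in range(n):
            for j in range(k):
                dist[i, j] = sbd(centroids[j], series[i])[0]
        new_labels = dist.argmin(axis=1)

        # reseed emptied clusters with the worst-fitting profile
        for j in range(k):
            if not (new_labels == j).any():
                farthest = int(dist[np.arange(n), new_labels].argmax())
                new_labels[farthest] = j

        trace.append(float(dist[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels) and n_iter > 1:
            converged = True
            break
        labels = new_labels

    assignments = {p.entity_id: int(lbl) + 1 for p, lbl in zip(profiles, labels)}
    logger.info(
        "k-shape: k=%d, %d profiles, %d iterations, converged=%s",
        k, n, n_iter, converged,
    )
    return KShapeModel(k, assignments, centroids, n_iter, converged, seed, trace)
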