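"""Shared data model for the time-course omics pipeline.

Quantification tables are held as pandas DataFrames (entities on rows); a
``NaN`` cell always means "not quantified" (MISSING), never zero. Sample
identity (condition, timepoint, replicate) travels alongside the frame as a
list of :class:`SampleKey` parallel to the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Scale",
    "OmicsLayer",
    "SampleKey",
    "IntensityMatrix",
    "FoldChangeTable",
    "AnnotationRecord",
    "UNKNOWN_CATEGORY",
    "FormatError",
    "ConfigurationError",
]

UNKNOWN_CATEGORY = "unknown"


class FormatError(ValueError):
    """An input file does not follow its declared tabular dialect."""


class ConfigurationError(ValueError):
    """Parameters or sample maps are inconsistent with the data."""


class Condition(str, Enum):
    """Nitrogen availability of a culture: deplete (N-) or replete (N+)."""

    N_MINUS = "N-"
    N_PLUS = "N+"


class Scale(str, Enum):
    RAW = "raw"
    LOG2 = "log2"


class OmicsLayer(str, Enum):
    PROTEIN = "protein"
    TRANSCRIPT = "transcript"


@dataclass(frozen=True, order=True)
class SampleKey:
    """One measured sample: condition x timepoint (hours) x replicate."""

    condition: Condition
    timepoint_hours: float
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint_hours <= 0:
            raise ConfigurationError(
                f"timepoint must be positive, got {self.timepoint_hours}"
            )
        if self.replicate < 1:
            raise ConfigurationError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def label(self) -> str:
        tp = self.timepoint_hours
        tp_str = f"{tp:g}"
        return f"{self.condition.value}_{tp_str}h_r{self.replicate}"


@dataclass
class IntensityMatrix:
    """Entity x sample quantification grid with sample metadata.

    ``data`` holds non-negative intensities (RAW) or log2 intensities (LOG2);
    NaN marks MISSING. Column order of ``data`` matches ``samples``.
    """

    data: pd.DataFrame
    samples: list[SampleKey]
    scale: Scale = Scale.RAW

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.samples):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.samples)} sample keys"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated entity ids: {dupes[:5]}")
        if self.scale is Scale.RAW:
            present = self.data.to_numpy(dtype=float)
            if np.nanmin(present, initial=np.inf) < 0:
                raise ValueError("RAW intensities must be non-negative")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_entities(self) -> int:
        return self.data.shape[0]

    @property
    def conditions(self) -> list[Condition]:
        seen: list[Condition] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    @property
    def timepoints(self) -> list[float]:
        return sorted({s.timepoint_hours for s in self.samples})

    def columns_where(
        self,
        condition: Condition | None = None,
        timepoint_hours: float | None = None,
    ) -> list[int]:
        """Positional indices of samples matching the given condition/timepoint."""
        idx = []
        for i, s in enumerate(self.samples):
            if condition is not None and s.condition is not condition:
                continue
            if timepoint_hours is not None and s.timepoint_hours != timepoint_hours:
                continue
            idx.append(i)
        return idx

    def subset_entities(self, ids: Iterable[str]) -> "IntensityMatrix":
        ids = list(ids)
        return IntensityMatrix(self.data.loc[ids].copy(), list(self.samples), self.scale)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.data.copy(), list(self.samples), self.scale)


@dataclass
class FoldChangeTable:
    """Entity x timepoint log2(N-/N+) ratios for one omics layer.

    LogetP (protein layer) is log2 LFQ(N-/N+); LogetT (transcript layer) is
    log2 FPKM(N-/N+), both as replicate means on the log2 scale.
    """

    data: pd.DataFrame  # columns: timepoint hours (float), ascending
    layer: OmicsLayer

    def __post_init__(self) -> None:
        cols = [float(c) for c in self.data.columns]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError(f"timepoints must be strictly increasing, got {cols}")
        self.data.columns = cols

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> list[float]:
        return [float(c) for c in self.data.columns]

    def profile(self, entity_id: str) -> np.ndarray:
        return self.data.loc[entity_id].to_numpy(dtype=float)


@dataclass
class AnnotationRecord:
    """Functional category and (optional) localization calls for one entity."""

    entity_id: str
    functional_category: str = UNKNOWN_CATEGORY
    localization_calls: dict[str, str] = field(default_factory=dict)
    consensus_localization: str | None = None


def sample_map_from_design(
    conditions: Sequence[Condition],
    timepoints: Sequence[float],
    n_replicates: int,
    column_template: str = "{cond}_{tp:g}h_r{rep}",
) -> dict[str, SampleKey]:
    """Build a column-name -> SampleKey map for a full factorial design."""
    out: dict[str, SampleKey] = {}
    for cond in conditions:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                key = SampleKey(cond, float(tp), rep)
                out[column_template.format(cond=cond.value, tp=tp, rep=rep)] = key
    return out
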