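"""Readers and writers for the pipeline's tabular dialects.

Three input dialects are supported:

* MaxQuant ``proteinGroups.txt``-style tables ("LFQ intensity <sample>"
  columns, optional ``Reverse`` / ``Potential contaminant`` flags);
* plain gene x sample FPKM matrices, including the GEO series-matrix layout
  where metadata lines start with ``!``;
* annotation tables mapping entities to functional categories and optional
  per-tool subcellular localization calls.

All outputs are UTF-8 tab-separated text with ``NA`` for missing cells so
that write -> read round-trips are bit-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotationRecord,
    ConfigurationError,
    FoldChangeTable,
    FormatError,
    IntensityMatrix,
    OmicsLayer,
    SampleKey,
    Scale,
    UNKNOWN_CATEGORY,
)

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: tools whose per-protein calls may appear as annotation columns
LOCALIZATION_TOOLS = ("SignalP", "ChloroP", "TargetP")


def _read_tsv(path: str | Path, skip_bang: bool = False) -> pd.DataFrame:
    kwargs: dict = {"sep": "\t", "dtype": str, "keep_default_na": False}
    if skip_bang:
        kwargs["comment"] = "!"
    return pd.read_csv(path, **kwargs)


def read_protein_groups(
    path: str | Path,
    sample_map: Mapping[str, SampleKey],
    id_column: str = "Protein IDs",
    lfq_prefix: str = "LFQ intensity ",
) -> IntensityMatrix:
    """Read a MaxQuant proteinGroups-style table into a RAW IntensityMatrix.

    ``sample_map`` maps the sample token of each "LFQ intensity <token>"
    column (or a full column name) to its :class:`SampleKey`; the returned
    sample order follows the map's insertion order regardless of column
    order on disk. Rows flagged ``+`` under ``Reverse`` or ``Potential
    contaminant`` are dropped before anything is counted; LFQ zeros become
    MISSING (MaxLFQ reports 0 for "not quantified").
    """
    df = _read_tsv(path)
    if id_column not in df.columns:
        raise FormatError(f"identifier column {id_column!r} not found in {path}")

    for flag_col in ("Reverse", "Potential contaminant"):
        if flag_col in df.columns:
            flagged = df[flag_col].str.strip() == "+"
            n = int(flagged.sum())
            if n:
                logger.info("dropping %d rows flagged %r", n, flag_col)
            df = df.loc[~flagged]

    ids = df[id_column].str.strip()
    if ids.duplicated().any():
        raise FormatError(
            f"duplicated entity ids in {path}: "
            f"{ids[ids.duplicated()].unique()[:5].tolist()}"
        )

    columns: list[str] = []
    keys: list[SampleKey] = []
    for token, key in sample_map.items():
        for candidate in (f"{lfq_prefix}{token}", token):
            if candidate in df.columns:
                columns.append(candidate)
                keys.append(key)
                break
        else:
            raise ConfigurationError(
                f"sample_map entry {token!r} matches no column in {path}"
            )

    values = np.empty((len(df), len(columns)), dtype=float)
    for j, col in enumerate(columns):
        values[:, j] = _parse_numeric_column(df[col], col)
    values[values == 0.0] = np.nan  # MaxLFQ convention: 0 == unquantified

    data = pd.DataFrame(values, index=pd.Index(ids, name="entity_id"), columns=[k.label for k in keys])
    logger.info("read %d protein groups from %s", len(data), path)
    return IntensityMatrix(data, keys, Scale.RAW)


def _parse_numeric_column(col: pd.Series, name: str) -> np.ndarray:
    out = np.empty(len(col), dtype=float)
    for i, raw in enumerate(col.to_numpy()):
        token = str(raw).strip()
        if token in ("", NA_TOKEN, "nan", "NaN"):
            out[i] = np.nan
            continue
        try:
            out[i] = float(token)
        except ValueError as exc:
            raise FormatError(
                f"non-numeric cell {token!r} at row {i}, column {name!r}"
            ) from exc
    return out


def read_fpkm_matrix(
    path: str | Path,
    sample_map: Mapping[str, SampleKey],
    id_column: str | None = None,
) -> IntensityMatrix:
    """Read a gene x sample FPKM table into a RAW IntensityMatrix.

    GEO series-matrix-style metadata lines (starting ``!``) are skipped.
    ``id_column`` defaults to the first column. ``NA`` cells become MISSING.
    """
    df = _read_tsv(path, skip_bang=True)
    if id_column is None:
        id_column = df.columns[0]
    elif id_column not in df.columns:
        raise FormatError(f"identifier column {id_column!r} not found in {path}")

    ids = df[id_column].str.strip()
    if ids.duplicated().any():
        raise FormatError(f"duplicated gene ids in {path}")

    columns, keys = [], []
    for token, key in sample_map.items():
        if token not in df.columns:
            raise ConfigurationError(
                f"sample_map entry {token!r} matches no column in {path}"
            )
        columns.append(token)
        keys.append(key)

    values = np.empty((len(df), len(columns)), dtype=float)
    for j, col in enumerate(columns):
        values[:, j] = _parse_numeric_column(df[col], col)

    data = pd.DataFrame(values, index=pd.Index(ids, name="entity_id"), columns=[k.label for k in keys])
    logger.info("read %d gene rows from %s", len(data), path)
    return IntensityMatrix(data, keys, Scale.RAW)


def read_annotations(
    path: str | Path,
    category_vocabulary: Sequence[str],
    id_column: str = "entity_id",
    category_column: str = "category",
) -> list[AnnotationRecord]:
    """Read an entity -> functional-category table (plus optional tool calls).

    Categories outside ``category_vocabulary`` map to UNKNOWN with a warning;
    on duplicate entity ids the last record wins.
    """
    df = _read_tsv(path)
    if df.empty:
        logger.warning("annotation file %s is empty", path)
        return []
    if id_column not in df.columns or category_column not in df.columns:
        raise FormatError(
            f"annotation file {path} needs columns {id_column!r} and {category_column!r}"
        )

    vocab = {c.lower(): c for c in category_vocabulary}
    tool_cols = [t for t in LOCALIZATION_TOOLS if t in df.columns]

    records: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        entity = str(row[id_column]).strip()
        raw_cat = str(row[category_column]).strip()
        category = vocab.get(raw_cat.lower())
        if category is None:
            if raw_cat and raw_cat.lower() != UNKNOWN_CATEGORY:
                logger.warning(
                    "category %r for %s not in vocabulary; mapped to UNKNOWN",
                    raw_cat,
                    entity,
                )
            category = UNKNOWN_CATEGORY
        calls = {
            tool: str(row[tool]).strip()
            for tool in tool_cols
            if str(row[tool]).strip() not in ("", NA_TOKEN)
        }
        if entity in records:
            logger.warning("duplicate annotation for %s; last record wins", entity)
        records[entity] = AnnotationRecord(entity, category, calls)
    return list(records.values())


def matrix_to_frame(matrix: IntensityMatrix) -> pd.DataFrame:
    """Flat entity x sample-label frame of an IntensityMatrix (NaN = MISSING)."""
    return matrix.data.copy()


def write_matrix(matrix: IntensityMatrix, path: str | Path, precision: int = 6) -> None:
    """Write an IntensityMatrix as TSV; MISSING rendered as ``NA``."""
    write_table(matrix.data, path, precision=precision)


def write_table(
    frame: pd.DataFrame, path: str | Path, precision: int = 6, index: bool = True
) -> None:
    """Write any result frame as UTF-8 TSV with ``NA`` for missing cells."""
    frame.to_csv(
        path,
        sep="\t",
        na_rep=NA_TOKEN,
        float_format=f"%.{precision}g",
        index=index,
        encoding="utf-8",
    )


def read_matrix(
    path: str | Path, samples: Sequence[SampleKey], scale: Scale = Scale.RAW
) -> IntensityMatrix:
    """Read back a matrix written by :func:`write_matrix` (round-trip)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    expected = [k.label for k in samples]
    if list(df.columns) != expected:
        raise FormatError(f"columns of {path} do not match the declared samples")
    return IntensityMatrix(df, list(samples), scale)


def write_fold_changes(table: FoldChangeTable, path: str | Path, precision: int = 6) -> None:
    frame = table.data.copy()
    frame.columns = [f"{c:g}" for c in frame.columns]
    write_table(frame, path, precision=precision)


def read_fold_changes(path: str | Path, layer: OmicsLayer) -> FoldChangeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN]).astype(float)
    df.columns = [float(c) for c in df.columns]
    return FoldChangeTable(df, layer)
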