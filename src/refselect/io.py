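"""Delimited-text readers and writers.

Matrix layout: first column gene (or probe) identifiers, header row
sample identifiers, numeric body.  Tab is the preferred delimiter,
comma is accepted; the delimiter is sniffed from the header line.
Lines starting with ``#`` are provenance headers written by the CLI and
are skipped on read.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    CqTable,
    ExpressionMatrix,
    GeneGroupStats,
    ProbeMap,
    SampleMetadata,
    records_to_frame,
)
from .errors import DataFormatError, MetadataError

__all__ = [
    "read_expression_matrix",
    "read_cq_table",
    "read_sample_metadata",
    "read_probe_map",
    "write_stats_table",
    "write_records_table",
    "write_matrix",
]

PathLike = Union[str, Path]
_NA_TOKENS = ("", "NA", "N/A", "NaN", "nan", "Undetermined")


def _sniff_delimiter(path: PathLike) -> str:
    with open(path, "r", newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise DataFormatError(f"{path}: file is empty")


def _read_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path,
        sep=sep,
        comment="#",
        dtype=str,
        keep_default_na=False,
        quoting=csv.QUOTE_MINIMAL,
    )
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected an id column plus data columns")
    return df


def _numeric_body(df: pd.DataFrame, path: PathLike) -> tuple[pd.DataFrame, bool]:
    """Parse the numeric body; also report whether every present cell was
    written as a plain non-negative integer token (count-like data)."""
    ids = df.iloc[:, 0].astype(str)
    body = df.iloc[:, 1:]
    out = np.full(body.shape, np.nan)
    count_like = True
    any_present = False
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            token = cell.strip()
            if token in _NA_TOKENS:
                continue
            try:
                out[i, j] = float(token)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric cell {cell!r} at row {ids.iloc[i]!r}, "
                    f"column {col!r}"
                ) from None
            any_present = True
            count_like = count_like and token.isdigit()
    frame = pd.DataFrame(out, index=ids.tolist(), columns=body.columns.tolist())
    return frame, count_like and any_present


def read_expression_matrix(
    path: PathLike, scale_hint: Optional[str] = None
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    The scale is detected automatically: a body written entirely as
    plain non-negative integer tokens is tagged ``raw_counts``,
    anything else (any sign, decimal point or exponent) ``log2``.
    Pass ``scale_hint`` to override detection.
    """
    values, count_like = _numeric_body(_read_table(path), path)
    tag = scale_hint if scale_hint is not None else (
        "raw_counts" if count_like else "log2"
    )
    return ExpressionMatrix(values=values, scale_tag=tag)


def read_sample_metadata(path: PathLike) -> SampleMetadata:
    """Read per-sample metadata (columns sample_id, group, sex, batch, pair_id)."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        # headerless convenience: first column is the sample id
        df = df.rename(columns={df.columns[0]: "sample_id"})
    return SampleMetadata(df)


def read_cq_table(path: PathLike, metadata_path: PathLike) -> CqTable:
    """Read a Cq matrix together with its sample metadata.

    Empty cells, "NA" and "Undetermined" are stored as missing wells.
    Every sample column must have a metadata row; Cq values must be
    positive cycle numbers.
    """
    values, _ = _numeric_body(_read_table(path), path)
    metadata = read_sample_metadata(metadata_path)
    return CqTable(values=values, metadata=metadata)


def read_probe_map(path: PathLike) -> ProbeMap:
    """Read a two-column probe -> gene symbol mapping."""
    df = _read_table(path)
    return ProbeMap(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


_STATS_COLUMNS = ["gene", "group", "n", "max", "min", "sd", "mean", "cv_percent"]


def write_stats_table(
    records: Sequence[GeneGroupStats],
    path: PathLike,
    decimals: Optional[int] = None,
    sep: str = "\t",
    header_lines: Sequence[str] = (),
) -> None:
    """Write per-gene per-group descriptive statistics.

    Values are written at full precision unless ``decimals`` is given
    (2 reproduces the look of published summary tables; downstream
    computation should always reread full-precision files).
    """
    if not records:
        raise DataFormatError("no statistics records to write")
    df = records_to_frame(records).rename(columns={"gene_id": "gene"})
    df = df.loc[:, _STATS_COLUMNS]
    if decimals is not None:
        for col in ("max", "min", "sd", "mean", "cv_percent"):
            df[col] = df[col].round(decimals)
    _write_frame(df, path, sep=sep, header_lines=header_lines)


def write_records_table(
    records: Sequence,
    path: PathLike,
    sep: str = "\t",
    header_lines: Sequence[str] = (),
) -> None:
    """Write any record list (effect sizes, normalizations, criteria) as TSV."""
    _write_frame(records_to_frame(records), path, sep=sep, header_lines=header_lines)


def write_matrix(
    matrix: Union[ExpressionMatrix, CqTable],
    path: PathLike,
    sep: str = "\t",
    header_lines: Sequence[str] = (),
    id_label: str = "gene_id",
) -> None:
    """Write a matrix container back to delimited text."""
    df = matrix.values.copy()
    df.index.name = id_label
    _write_frame(df.reset_index(), path, sep=sep, header_lines=header_lines)


def write_metadata(
    metadata: SampleMetadata,
    path: PathLike,
    sep: str = "\t",
    header_lines: Sequence[str] = (),
) -> None:
    _write_frame(metadata.table, path, sep=sep, header_lines=header_lines)


def _write_frame(
    df: pd.DataFrame, path: PathLike, sep: str, header_lines: Sequence[str]
) -> None:
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep=sep, index=False, na_rep="NA")
    except OSError as exc:
        raise DataFormatError(f"cannot write {path}: {exc}") from exc
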