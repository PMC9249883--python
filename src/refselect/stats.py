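"""Per-gene, per-group descriptive statistics.

The central stability measure is CqCV%, the coefficient of variation of
quantification-cycle values: 100 * SD / mean.  Because the mean enters
the denominator, CV% compares dispersion across genes with very
different absolute expression, which a bare SD cannot do.  Lower CV% =
more stable expression = a better reference-gene candidate.

Standard deviations use the sample (n-1) denominator.  Published
summary tables round to two decimals for display, but everything
downstream works on full-precision values: CV% cells recomputed from
rounded SD/mean columns do not always reproduce, so never chain rounded
intermediates.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import CqTable, ExpressionMatrix, GeneGroupStats, SampleMetadata
from .errors import DataFormatError, MetadataError

__all__ = ["cv_percent", "gene_group_stats", "log2_cpm", "stats_lookup"]


def cv_percent(sd: float, mean: float) -> float:
    """Coefficient of variation as a percentage: 100 * sd / mean.

    Requires mean > 0 (Cq and log2-expression means are positive in
    this domain; a non-positive mean makes CV undefined or unstable).
    """
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if mean <= 0:
        raise ValueError(f"cv_percent requires mean > 0, got {mean}")
    return 100.0 * sd / mean


def log2_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount.

    log2((count + pseudocount) / (library_size + 2*pseudocount) * 1e6),
    the usual moderated-CPM transform for putting RNA-seq counts on an
    approximately log2-expression scale before ordinary linear models.
    """
    lib = counts.sum(axis=0)
    return np.log2((counts + pseudocount) / (lib + 2.0 * pseudocount) * 1.0e6)


def to_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a log2-scale view of a matrix, transforming raw counts."""
    if matrix.scale_tag == "log2":
        return matrix
    return ExpressionMatrix(
        values=log2_cpm(matrix.values),
        scale_tag="log2",
        metadata=matrix.metadata,
    )


MatrixLike = Union[CqTable, ExpressionMatrix]


def _resolve_metadata(
    matrix: MatrixLike, metadata: Optional[SampleMetadata]
) -> Optional[SampleMetadata]:
    if metadata is not None:
        return metadata.subset(matrix.values.columns)
    return getattr(matrix, "metadata", None)


def gene_group_stats(
    matrix: MatrixLike,
    metadata: Optional[SampleMetadata] = None,
    group_by: Optional[str] = "group",
    groups: Optional[Sequence[str]] = None,
) -> list[GeneGroupStats]:
    """Descriptive statistics of every gene within every sample group.

    One record per gene per group with n, max, min, mean, sample SD and
    CV%.  Missing values are excluded per gene; a gene/group with fewer
    than two present values gets NaN sd and cv (undefined, not an
    error).  ``group_by=None`` treats the whole table as one group
    labelled "all".  Raw-count matrices are transformed to log2 CPM
    first.
    """
    if isinstance(matrix, ExpressionMatrix):
        matrix = to_log2(matrix)
    values = matrix.values
    meta = _resolve_metadata(matrix, metadata)

    if group_by is None:
        grouping = {"all": list(values.columns)}
    else:
        if meta is None:
            raise MetadataError("grouping requested but no metadata supplied")
        col = meta.column(group_by) if group_by in meta.table.columns else None
        if col is None:
            raise MetadataError(f"unknown grouping key {group_by!r}")
        grouping = {
            str(g): idx.tolist() for g, idx in col.groupby(col).groups.items()
        }
    if groups is not None:
        unknown = set(groups) - set(grouping)
        if unknown:
            raise MetadataError(f"unknown groups requested: {sorted(unknown)}")
        grouping = {g: grouping[g] for g in groups}
    if not grouping or any(len(s) == 0 for s in grouping.values()):
        raise MetadataError("every requested group needs at least one sample")

    records: list[GeneGroupStats] = []
    for group, samples in grouping.items():
        sub = values.loc[:, samples]
        arr = sub.to_numpy(dtype=float)
        n = np.sum(~np.isnan(arr), axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(n[:, None] > 0, arr, np.nan), axis=1)
            gmax = np.nanmax(np.where(n[:, None] > 0, arr, np.nan), axis=1)
            gmin = np.nanmin(np.where(n[:, None] > 0, arr, np.nan), axis=1)
        sd = np.full(arr.shape[0], np.nan)
        ok = n >= 2
        if np.any(ok):
            sd[ok] = np.nanstd(arr[ok], axis=1, ddof=1)
        cv = np.where((mean > 0) & ~np.isnan(sd), 100.0 * sd / np.where(mean > 0, mean, np.nan), np.nan)
        for i, gene in enumerate(values.index):
            records.append(
                GeneGroupStats(
                    gene_id=str(gene),
                    group=group,
                    n=int(n[i]),
                    max=float(gmax[i]),
                    min=float(gmin[i]),
                    mean=float(mean[i]),
                    sd=float(sd[i]),
                    cv_percent=float(cv[i]),
                )
            )
    return records


def stats_lookup(
    records: Iterable[GeneGroupStats],
) -> dict[tuple[str, str], GeneGroupStats]:
    """Index stats records by case-folded (gene, group) for criterion checks."""
    out: dict[tuple[str, str], GeneGroupStats] = {}
    for rec in records:
        key = (rec.gene_id.casefold(), rec.group)
        if key in out:
            raise DataFormatError(
                f"duplicate statistics for gene {rec.gene_id!r} in group {rec.group!r}"
            )
        out[key] = rec
    return out
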