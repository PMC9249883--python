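"""Pooled-data preprocessing and effect-size screening.

Pipeline for multi-dataset (pooled) expression matrices: collapse
platform probes to genes, remove additive dataset/batch offsets with a
group-protected linear fit, flag low-correlation outlier samples, then
screen genes with per-gene linear models.

The effect size (ES) is the unstandardized difference of group means
on the log2 scale — the fitted coefficient of the per-gene model
``expression ~ group`` — not a standardized quantity like Cohen's d.
Raw p-values come from ordinary pooled-variance t statistics (no
empirical-Bayes variance moderation, a deliberate simplification), and
the family-wise error rate is controlled by Bonferroni across all
genes tested in the matrix, per contrast.

For reference-gene screening the interesting genes are the ones that
do *not* move: the best candidates have |ES| near zero and a
non-significant FWER.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    CqTable,
    EffectSizeRecord,
    ExpressionMatrix,
    ProbeMap,
    SampleMetadata,
)
from .errors import DataFormatError, DesignError, MetadataError
from .stats import to_log2

__all__ = [
    "collapse_probes",
    "remove_batch_effect",
    "flag_outliers",
    "two_group_effect_size",
    "interaction_effect_size",
    "bonferroni_fwer",
    "relabel_subtypes",
]

log = logging.getLogger(__name__)


def collapse_probes(matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Average probe rows into one row per gene.

    Each gene's row is the arithmetic mean of its probes' rows (log2
    scale).  Probes without a mapping are dropped; the count is logged.
    """
    if matrix.scale_tag != "log2":
        raise DataFormatError("collapse_probes expects a log2-scale matrix")
    probes = matrix.values.index
    mapped = [p for p in probes if p in probe_map]
    dropped = len(probes) - len(mapped)
    if not mapped:
        raise DataFormatError("no probes in the matrix are present in the probe map")
    if dropped:
        log.info("collapse_probes: dropped %d unmapped probes", dropped)
    genes = pd.Series({p: probe_map[p] for p in mapped})
    collapsed = matrix.values.loc[mapped].groupby(genes, sort=False).mean()
    collapsed.index = collapsed.index.astype(str)
    return ExpressionMatrix(
        values=collapsed, scale_tag="log2", metadata=matrix.metadata
    )


def _batch_design(
    samples: Sequence[str], meta: SampleMetadata
) -> tuple[np.ndarray, np.ndarray]:
    """Design columns: [intercept + group dummies | sum-to-zero batch contrasts]."""
    batch = meta.column("batch").loc[list(samples)]
    group = meta.column("group").loc[list(samples)]
    if (batch == "").any():
        missing = [s for s, b in batch.items() if b == ""]
        raise MetadataError(f"samples without a batch label: {missing}")
    batches = sorted(set(batch))
    if len(batches) < 2:
        raise DesignError("batch-effect removal requires at least 2 batches")
    for b in batches:
        in_b = set(batch.index[batch == b])
        for g in sorted(set(group)):
            if in_b == set(group.index[group == g]):
                raise DesignError(
                    f"batch {b!r} is perfectly confounded with group {g!r}"
                )
    n = len(samples)
    groups = sorted(set(group))
    protect = [np.ones(n)]
    for g in groups[1:]:
        protect.append((group == g).to_numpy(dtype=float))
    # sum-to-zero batch contrasts: last batch = -(sum of others)
    contrasts = []
    last = batches[-1]
    for b in batches[:-1]:
        col = np.where(batch == b, 1.0, 0.0) - np.where(batch == last, 1.0, 0.0)
        contrasts.append(col)
    return np.column_stack(protect), np.column_stack(contrasts)


def remove_batch_effect(
    matrix: ExpressionMatrix, metadata: Optional[SampleMetadata] = None
) -> ExpressionMatrix:
    """Subtract additive per-batch offsets while protecting group effects.

    Per gene, expression is regressed jointly on group indicators and
    sum-to-zero batch contrasts; only the fitted batch component is
    subtracted, so group-mean structure is preserved and the operation
    is idempotent.  A batch whose sample set coincides exactly with a
    group's cannot be separated from it and raises an error naming the
    pair.
    """
    matrix = to_log2(matrix)
    meta = metadata if metadata is not None else matrix.metadata
    if meta is None:
        raise MetadataError("batch-effect removal needs sample metadata")
    meta = meta.subset(matrix.values.columns)
    protect, batch_cols = _batch_design(matrix.sample_ids, meta)
    X = np.hstack([protect, batch_cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("batch/group design is rank-deficient (confounded)")
    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_part = batch_cols @ beta[protect.shape[1]:, :]
    corrected = pd.DataFrame(
        (Y - batch_part).T, index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(values=corrected, scale_tag="log2", metadata=meta)


def flag_outliers(
    matrix: ExpressionMatrix,
    threshold_rule: Union[str, float] = "mad",
) -> list[str]:
    """Flag samples poorly correlated with the rest of the pool.

    Each sample's mean Pearson correlation to all other samples is
    computed; under the default rule a sample is flagged when its mean
    correlation falls below median - 3*MAD of the per-sample means
    (MAD = median absolute deviation).  Pass a float to use a fixed
    correlation cutoff instead.  The caller decides whether to drop the
    flagged samples.
    """
    values = to_log2(matrix).values
    n = values.shape[1]
    if n < 3:
        raise DesignError("outlier flagging requires at least 3 samples")
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    mean_corr = (corr.sum(axis=1) - 1.0) / (n - 1)
    if isinstance(threshold_rule, (int, float)) and not isinstance(threshold_rule, bool):
        cutoff = float(threshold_rule)
    elif threshold_rule == "mad":
        med = np.median(mean_corr)
        mad = np.median(np.abs(mean_corr - med))
        cutoff = med - 3.0 * mad
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    flagged = [s for s, m in zip(values.columns, mean_corr) if m < cutoff]
    if flagged:
        log.info("flag_outliers: flagged %d of %d samples", len(flagged), n)
    return flagged


def bonferroni_fwer(p_values: Sequence[float], g: int) -> list[float]:
    """Bonferroni family-wise adjustment: p -> min(1, p*g)."""
    if g < 1:
        raise ValueError("g must be a positive count")
    out = []
    for p in p_values:
        if np.isnan(p):
            out.append(float("nan"))
            continue
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, float(p) * g))
    return out


def _group_samples(
    meta: SampleMetadata, samples: Sequence[str], **criteria: str
) -> list[str]:
    keep = []
    for s in samples:
        row = meta.table.set_index("sample_id").loc[s]
        if all(row[k] == v for k, v in criteria.items()):
            keep.append(s)
    return keep


def two_group_effect_size(
    matrix: Union[ExpressionMatrix, CqTable],
    metadata: Optional[SampleMetadata] = None,
    group_a: str = "",
    group_b: str = "",
    sex: Optional[str] = None,
) -> list[EffectSizeRecord]:
    """Per-gene two-group screen: ES = mean(a) - mean(b), pooled t-test.

    ES is the coefficient of the per-gene linear model with a binary
    group indicator; the raw p is a two-sided pooled-variance t-test on
    that coefficient, and fwer = min(1, p*G) with G = genes tested.
    ``sex`` restricts both groups to one sex (intra-sex screens).
    A gene with zero residual variance gets p = 0 if its ES is nonzero
    else 1, with a logged warning.
    """
    if isinstance(matrix, ExpressionMatrix):
        matrix = to_log2(matrix)
    meta = metadata if metadata is not None else getattr(matrix, "metadata", None)
    if meta is None:
        raise MetadataError("two_group_effect_size needs sample metadata")
    meta = meta.subset(matrix.values.columns)
    crit_a = {"group": group_a} | ({"sex": sex} if sex else {})
    crit_b = {"group": group_b} | ({"sex": sex} if sex else {})
    a_samples = _group_samples(meta, matrix.sample_ids, **crit_a)
    b_samples = _group_samples(meta, matrix.sample_ids, **crit_b)
    for label, samp in ((group_a, a_samples), (group_b, b_samples)):
        if len(samp) < 2:
            raise DesignError(
                f"group {label!r} has {len(samp)} samples; need at least 2"
            )
    A = matrix.values.loc[:, a_samples].to_numpy(dtype=float)
    B = matrix.values.loc[:, b_samples].to_numpy(dtype=float)
    es = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=1, equal_var=True)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        log.warning(
            "two_group_effect_size: %d genes with zero residual variance",
            int(degenerate.sum()),
        )
        p = np.where(degenerate & (es != 0), 0.0, np.where(degenerate, 1.0, p))
    g = matrix.values.shape[0]
    fwer = bonferroni_fwer(p.tolist(), g)
    contrast = f"{group_a}-vs-{group_b}" + (f" ({sex})" if sex else "")
    return [
        EffectSizeRecord(
            gene_id=str(gene), contrast=contrast, es=float(es[i]),
            p=float(p[i]), fwer=float(fwer[i]),
        )
        for i, gene in enumerate(matrix.values.index)
    ]


def interaction_effect_size(
    matrix: Union[ExpressionMatrix, CqTable],
    metadata: Optional[SampleMetadata] = None,
    subtype: str = "",
    normal_label: str = "Normal",
) -> list[EffectSizeRecord]:
    """Sex-by-disease interaction contrast for one tumor subtype.

    ES_int = (mean F.tumor - mean F.normal) - (mean M.tumor - mean
    M.normal), i.e. the difference between the female and male
    disease effects.  The p-value is the corresponding contrast in a
    single-factor four-level (cell-means) linear model, Bonferroni
    adjusted across genes.  Samples with unknown sex are excluded; an
    empty cell raises an error naming it (the contrast is then not
    estimable).
    """
    if isinstance(matrix, ExpressionMatrix):
        matrix = to_log2(matrix)
    meta = metadata if metadata is not None else getattr(matrix, "metadata", None)
    if meta is None:
        raise MetadataError("interaction_effect_size needs sample metadata")
    meta = meta.subset(matrix.values.columns)
    cells = {
        "female.tumor": ("female", subtype),
        "female.normal": ("female", normal_label),
        "male.tumor": ("male", subtype),
        "male.normal": ("male", normal_label),
    }
    cell_samples = {}
    for name, (sex, group) in cells.items():
        samp = _group_samples(meta, matrix.sample_ids, sex=sex, group=group)
        if not samp:
            raise DesignError(
                f"interaction contrast not estimable: cell {name!r} "
                f"(sex={sex}, group={group}) is empty"
            )
        cell_samples[name] = samp

    order = ["female.tumor", "female.normal", "male.tumor", "male.normal"]
    contrast = np.array([1.0, -1.0, -1.0, 1.0])
    ns = np.array([len(cell_samples[c]) for c in order], dtype=float)
    arrs = [matrix.values.loc[:, cell_samples[c]].to_numpy(dtype=float) for c in order]
    means = np.column_stack([a.mean(axis=1) for a in arrs])  # genes x 4
    es = means @ contrast
    N = int(ns.sum())
    df = N - 4
    if df >= 1:
        sse = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrs)
        mse = sse / df
        se2 = mse * float(np.sum(contrast**2 / ns))
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = es / np.sqrt(se2)
            p = 2.0 * sps.t.sf(np.abs(tstat), df)
        degenerate = ~np.isfinite(p)
        if np.any(degenerate):
            log.warning(
                "interaction_effect_size: %d genes with zero residual variance",
                int(degenerate.sum()),
            )
            p = np.where(degenerate & (es != 0), 0.0, np.where(degenerate, 1.0, p))
    else:
        log.warning("interaction_effect_size: no residual degrees of freedom")
        p = np.full(es.shape, np.nan)
    g = matrix.values.shape[0]
    fwer = np.array(bonferroni_fwer(p.tolist(), g))
    label = f"({subtype}.female-{normal_label}.female)-({subtype}.male-{normal_label}.male)"
    return [
        EffectSizeRecord(
            gene_id=str(gene), contrast=label, es=float(es[i]),
            p=float(p[i]), fwer=float(fwer[i]),
        )
        for i, gene in enumerate(matrix.values.index)
    ]


def relabel_subtypes(
    metadata: SampleMetadata, aliases: dict[str, str]
) -> SampleMetadata:
    """Merge subtype labels on ingest (e.g. {"FVPTC": "PTC"})."""
    df = metadata.table.copy()
    df["group"] = df["group"].replace(aliases)
    return SampleMetadata(df)
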