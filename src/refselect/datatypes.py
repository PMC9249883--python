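"""Domain containers shared by every stage of the pipeline.

Matrices are stored as pandas DataFrames (genes in rows, samples in
columns).  Gene identifiers are case-preserving but looked up
case-insensitively, because symbol tables mixed from qPCR sheets,
microarray annotation and RNA-seq pipelines rarely agree on case.

Quantities carry the units of their source scale throughout: Cq values
are PCR cycles (typically 15-40, higher Cq = lower expression) and
pooled expression values are dimensionless log2 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, MetadataError

__all__ = [
    "SampleMetadata",
    "CqTable",
    "ExpressionMatrix",
    "ProbeMap",
    "GeneGroupStats",
    "EffectSizeRecord",
    "NormalizationRecord",
    "DiscordanceReport",
    "CriterionRecord",
    "ddcq_sign",
    "records_to_frame",
]

_METADATA_COLUMNS = ("sample_id", "group", "sex", "batch", "pair_id")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        key = str(i).casefold()
        if key in seen:
            raise DataFormatError(f"duplicate {what} id: {i!r}")
        seen.add(key)


def resolve_id(index: pd.Index, name: str, what: str = "gene") -> str:
    """Return the stored identifier matching ``name`` case-insensitively."""
    if name in index:
        return name
    lowered = {str(i).casefold(): i for i in index}
    try:
        return lowered[str(name).casefold()]
    except KeyError:
        raise KeyError(f"{what} {name!r} not found") from None


@dataclass
class SampleMetadata:
    """Per-sample phenotype annotations.

    ``table`` has one row per sample with columns sample_id, group, sex,
    batch and pair_id.  ``group`` is a pathology label (Normal, PTC,
    FTA, FTC, MTC, PDTC, ATC, ...); ``pair_id`` links a tumor sample to
    its adjacent normal from the same patient and may be empty.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in _METADATA_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col != "sex" else "unknown"
        df = df.loc[:, list(_METADATA_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        for col in ("group", "sex", "batch", "pair_id"):
            df[col] = df[col].fillna("").astype(str)
        df.loc[df["sex"] == "", "sex"] = "unknown"
        df["sex"] = df["sex"].str.lower()
        bad_sex = set(df["sex"]) - {"female", "male", "unknown"}
        if bad_sex:
            raise MetadataError(f"unrecognized sex labels: {sorted(bad_sex)}")
        _check_unique(df["sample_id"].tolist(), "sample")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        wanted = [str(s) for s in sample_ids]
        missing = set(wanted) - set(self.sample_ids)
        if missing:
            raise MetadataError(f"samples absent from metadata: {sorted(missing)}")
        df = self.table.set_index("sample_id").loc[wanted].reset_index()
        return SampleMetadata(df)

    def column(self, name: str) -> pd.Series:
        return self.table.set_index("sample_id")[name]

    def groups(self) -> list[str]:
        return sorted(set(self.table["group"]))


def _validate_matrix(values: pd.DataFrame) -> pd.DataFrame:
    values = values.copy()
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    _check_unique(values.index.tolist(), "gene")
    _check_unique(values.columns.tolist(), "sample")
    return values


@dataclass
class CqTable:
    """Genes x samples of quantification-cycle values with metadata.

    Missing wells (undetermined reactions) are stored as NaN and
    excluded pairwise from downstream statistics.  All present values
    must be finite and strictly positive cycle numbers.
    """

    values: pd.DataFrame
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        values = _validate_matrix(self.values).astype(float)
        arr = values.to_numpy()
        present = ~np.isnan(arr)
        if np.any(~np.isfinite(arr[present])):
            raise DataFormatError("Cq table contains non-finite values")
        if np.any(arr[present] <= 0):
            raise DataFormatError("Cq values must be > 0 cycles")
        missing = set(values.columns) - set(self.metadata.sample_ids)
        if missing:
            raise MetadataError(
                f"samples in Cq table absent from metadata: {sorted(missing)}"
            )
        self.values = values
        self.metadata = self.metadata.subset(values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def gene(self, name: str) -> pd.Series:
        return self.values.loc[resolve_id(self.values.index, name)]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    ``scale_tag`` records whether values are log2 units ("log2") or raw
    RNA-seq counts ("raw_counts"); raw counts are non-negative integers
    and are transformed to log2 counts-per-million before any
    statistics.
    """

    values: pd.DataFrame
    scale_tag: str = "log2"
    metadata: Optional[SampleMetadata] = None

    def __post_init__(self) -> None:
        if self.scale_tag not in ("log2", "raw_counts"):
            raise DataFormatError(f"unknown scale_tag {self.scale_tag!r}")
        values = _validate_matrix(self.values).astype(float)
        arr = values.to_numpy()
        if self.scale_tag == "raw_counts":
            present = arr[~np.isnan(arr)]
            if np.any(present < 0) or np.any(present != np.floor(present)):
                raise DataFormatError(
                    "raw_counts matrices must hold non-negative integers"
                )
        else:
            if np.any(~np.isfinite(arr[~np.isnan(arr)])):
                raise DataFormatError("log2 matrix contains non-finite values")
        if self.metadata is not None:
            missing = set(values.columns) - set(self.metadata.sample_ids)
            if missing:
                raise MetadataError(
                    f"samples in matrix absent from metadata: {sorted(missing)}"
                )
            self.metadata = self.metadata.subset(values.columns)
        self.values = values

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def gene(self, name: str) -> pd.Series:
        return self.values.loc[resolve_id(self.values.index, name)]


@dataclass
class ProbeMap:
    """Many-to-one mapping from platform probe ids to gene symbols."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for probe, gene in dict(self.mapping).items():
            probe = str(probe)
            gene = str(gene)
            if not gene:
                raise DataFormatError(f"probe {probe!r} maps to an empty gene symbol")
            if probe in clean and clean[probe] != gene:
                raise DataFormatError(f"probe {probe!r} maps to multiple genes")
            clean[probe] = gene
        self.mapping = clean

    def __contains__(self, probe: str) -> bool:
        return str(probe) in self.mapping

    def __getitem__(self, probe: str) -> str:
        return self.mapping[str(probe)]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneGroupStats:
    """Descriptive statistics of one gene within one sample group.

    All quantities are on the input scale (Cq cycles or log2 units).
    ``sd`` uses the n-1 denominator and is NaN when fewer than two
    values are present; ``cv_percent`` is 100*sd/mean and is NaN
    whenever sd is undefined or the mean is not positive.
    """

    gene_id: str
    group: str
    n: int
    max: float
    min: float
    mean: float
    sd: float
    cv_percent: float


@dataclass
class EffectSizeRecord:
    """Per-gene effect size for one contrast.

    ``es`` is the unstandardized difference of group means (the fitted
    coefficient of the per-gene linear model), ``p`` the raw two-sided
    p-value and ``fwer`` its Bonferroni adjustment.
    """

    gene_id: str
    contrast: str
    es: float
    p: float
    fwer: float


def ddcq_sign(ddcq: float) -> Optional[str]:
    """Sign category of a delta-delta Cq value.

    Exact zero is its own category so that discordance counting is
    deterministic; a missing (NaN) input yields ``None``.
    """
    if ddcq is None or (isinstance(ddcq, float) and math.isnan(ddcq)):
        return None
    if ddcq > 0:
        return "positive"
    if ddcq < 0:
        return "negative"
    return "zero"


@dataclass
class NormalizationRecord:
    """Livak-method quantities for one tumor sample.

    Positive ddcq means the target is down-regulated in the tumor
    sample relative to the calibrator; negative means over-expressed.
    ``fold_change`` = 2**(-ddcq).
    """

    sample_id: str
    target: str
    reference: str
    dcq: float
    ddcq: float
    fold_change: float
    sign: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sign is None:
            self.sign = ddcq_sign(self.ddcq)


@dataclass
class DiscordanceReport:
    """Cross-reference sign agreement for one target gene.

    A tumor sample is discordant when its ddCq sign under reference A
    differs from its sign under reference B (zero counts as its own
    category, discordant with both signs).
    """

    target: str
    reference_a: str
    reference_b: str
    n_samples: int
    n_discordant: int
    discordance_percent: float
    sign_pairs: list[tuple[str, Optional[str], Optional[str]]] = field(
        default_factory=list
    )


@dataclass
class CriterionRecord:
    """One evaluation of the overlap criterion |muT - muR| >= 3*sdT + 2*sdR."""

    target: str
    reference: str
    group: str
    mu_t: float
    mu_r: float
    sd_t: float
    sd_r: float
    gap: float
    required_gap: float
    passes: bool

    @property
    def margin(self) -> float:
        """gap - required_gap; positive when the criterion is met."""
        return self.gap - self.required_gap


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Flatten a list of record dataclasses into a DataFrame."""
    if not records:
        raise DataFormatError("no records to tabulate")
    rows = []
    for rec in records:
        row = dict(vars(rec))
        row.pop("sign_pairs", None)
        rows.append(row)
    return pd.DataFrame(rows)
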