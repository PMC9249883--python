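"""Livak relative quantification and the cross-reference discordance audit.

The Livak (delta-delta Cq) method quantifies a target gene relative to
a reference gene and a calibrator condition:

    dCq(sample)  = Cq_target(sample) - Cq_reference(sample)
    ddCq(sample) = dCq(sample) - dCq(calibrator)
    fold change  = 2 ** (-ddCq)

Because Cq counts cycles on a log2 scale, a positive ddCq means the
target is *down-regulated* in the sample relative to the calibrator and
a negative ddCq means it is over-expressed.

The discordance audit re-normalizes the same target against two
different reference genes and counts tumor samples whose ddCq sign
flips between the two: with a well-separated, stable reference the
flip rate approaches zero, while a reference whose Cq distribution
overlaps the target's produces samples whose positive and negative
ddCq mutually cancel, inverting apparent expression patterns.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    CqTable,
    DiscordanceReport,
    NormalizationRecord,
    ddcq_sign,
    resolve_id,
)
from .errors import DataFormatError, DesignError, MetadataError

__all__ = [
    "delta_cq",
    "delta_delta_cq",
    "fold_change",
    "normalize_experiment",
    "discordance_percent",
    "discordance_report",
]

CALIBRATOR_MODES = ("mean_of_normals", "paired_adjacent")


def delta_cq(cq_target: float, cq_reference: float) -> float:
    """Cq_target - Cq_reference for one sample; NaN propagates."""
    return float(cq_target) - float(cq_reference)


def delta_delta_cq(dcq_sample: float, calibrator_dcq: float) -> float:
    """dCq(sample) - dCq(calibrator); NaN propagates.

    Positive = down-regulated relative to the calibrator, negative =
    over-expressed.
    """
    return float(dcq_sample) - float(calibrator_dcq)


def fold_change(ddcq: float) -> float:
    """Relative expression 2**(-ddcq)."""
    return float(2.0 ** (-float(ddcq)))


def normalize_experiment(
    cq: CqTable,
    target: str,
    reference: str,
    calibrator_mode: str = "mean_of_normals",
    normal_group: str = "Normal",
    tumor_group: Optional[str] = None,
) -> list[NormalizationRecord]:
    """Livak-normalize one target against one reference gene.

    Returns one record per tumor sample.  ``calibrator_mode``:

    * ``mean_of_normals`` (default): the calibrator dCq is the average
      dCq over all normal samples.
    * ``paired_adjacent``: each tumor sample is calibrated against the
      dCq of its own adjacent normal tissue (linked by ``pair_id``).

    Missing Cq wells propagate to missing dCq/ddCq (sign ``None``),
    never to an exception.
    """
    if calibrator_mode not in CALIBRATOR_MODES:
        raise ValueError(
            f"calibrator_mode must be one of {CALIBRATOR_MODES}, got {calibrator_mode!r}"
        )
    target = resolve_id(cq.values.index, target)
    reference = resolve_id(cq.values.index, reference)
    if target == reference:
        raise DataFormatError(
            f"target and reference are the same gene ({target!r})"
        )

    groups = cq.metadata.column("group")
    is_normal = groups == normal_group
    if tumor_group is not None:
        is_tumor = groups == tumor_group
    else:
        is_tumor = ~is_normal
    tumor_samples = [s for s in cq.sample_ids if is_tumor.get(s, False)]
    normal_samples = [s for s in cq.sample_ids if is_normal.get(s, False)]
    if not tumor_samples:
        raise DesignError("no tumor samples identified from metadata")

    dcq_all = cq.values.loc[target] - cq.values.loc[reference]

    if calibrator_mode == "mean_of_normals":
        if not normal_samples:
            raise DesignError(
                "mean_of_normals calibrator requires at least one normal sample"
            )
        normal_dcq = dcq_all.loc[normal_samples].to_numpy(dtype=float)
        if np.all(np.isnan(normal_dcq)):
            raise DesignError("all normal-sample dCq values are missing")
        calibrator = float(np.nanmean(normal_dcq))
        calibrator_for = {s: calibrator for s in tumor_samples}
    else:
        pair_ids = cq.metadata.column("pair_id")
        normal_by_pair: dict[str, str] = {}
        for s in normal_samples:
            pid = pair_ids.get(s, "")
            if pid:
                if pid in normal_by_pair:
                    raise MetadataError(f"pair_id {pid!r} links multiple normal samples")
                normal_by_pair[pid] = s
        calibrator_for = {}
        for s in tumor_samples:
            pid = pair_ids.get(s, "")
            if not pid or pid not in normal_by_pair:
                raise MetadataError(
                    f"tumor sample {s!r} has no paired adjacent normal (pair_id {pid!r})"
                )
            calibrator_for[s] = float(dcq_all.loc[normal_by_pair[pid]])

    records = []
    for s in tumor_samples:
        dcq = float(dcq_all.loc[s])
        ddcq = delta_delta_cq(dcq, calibrator_for[s])
        fc = fold_change(ddcq) if not math.isnan(ddcq) else float("nan")
        records.append(
            NormalizationRecord(
                sample_id=s,
                target=target,
                reference=reference,
                dcq=dcq,
                ddcq=ddcq,
                fold_change=fc,
            )
        )
    return records


def discordance_percent(n_discordant: int, n_samples: int) -> float:
    """100 * n_discordant / n_samples (display convention: one decimal)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0 <= n_discordant <= n_samples:
        raise ValueError(
            f"n_discordant must lie in [0, {n_samples}], got {n_discordant}"
        )
    return 100.0 * n_discordant / n_samples


def discordance_report(
    records_a: Sequence[NormalizationRecord],
    records_b: Sequence[NormalizationRecord],
) -> DiscordanceReport:
    """Compare per-sample ddCq signs of one target under two references.

    Both record lists must cover the same target gene and the same
    tumor samples, differing only in reference gene.  A sample is
    discordant iff its two signs differ (zero is its own category, so a
    zero against either sign counts as discordant).  Samples with a
    missing sign under either reference are excluded from the counts.
    """
    by_a = {r.sample_id: r for r in records_a}
    by_b = {r.sample_id: r for r in records_b}
    if set(by_a) != set(by_b):
        raise DataFormatError(
            "the two normalizations cover different sample sets: "
            f"{sorted(set(by_a) ^ set(by_b))}"
        )
    targets = {r.target for r in records_a} | {r.target for r in records_b}
    if len(targets) != 1:
        raise DataFormatError(f"records mix target genes: {sorted(targets)}")

    sign_pairs = []
    n_samples = 0
    n_discordant = 0
    for s in by_a:
        sa, sb = by_a[s].sign, by_b[s].sign
        sign_pairs.append((s, sa, sb))
        if sa is None or sb is None:
            continue
        n_samples += 1
        if sa != sb:
            n_discordant += 1
    if n_samples == 0:
        raise DataFormatError("no samples with ddCq signs under both references")
    return DiscordanceReport(
        target=targets.pop(),
        reference_a=next(iter(records_a)).reference if records_a else "",
        reference_b=next(iter(records_b)).reference if records_b else "",
        n_samples=n_samples,
        n_discordant=n_discordant,
        discordance_percent=discordance_percent(n_discordant, n_samples),
        sign_pairs=sorted(sign_pairs),
    )
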