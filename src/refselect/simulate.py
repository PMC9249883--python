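"""Synthetic Cq experiments and pooled expression matrices.

Every stage of the toolkit is testable without downloads: this module
generates (a) paired tumor/normal RT-qPCR Cq experiments with per-gene
true means and SDs and Gaussian Cq noise, and (b) pooled multi-batch
log2 expression matrices with additive batch offsets, spiked group
effects and Gaussian residuals.

Cq noise is modelled as homoscedastic Gaussian within gene and
condition: Cq is already a log2-scale quantity and within-condition Cq
replicates are approximately normal, which is also the regime in which
the mean/SD overlap criterion is formulated.  Every generator takes an
explicit seed; there is no hidden global random state.

The default Cq specification (`thyroid_cq_spec`) emulates a 17-pair
papillary thyroid carcinoma (PTC) / adjacent-normal design with two
candidate reference genes — one high-variance, well separated from the
targets (GAPDH-like) and one low-variance, overlapping them
(SYMPK-like) — plus three target genes in the same Cq range, i.e. the
regime where reference choice flips expression calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CqTable, ExpressionMatrix, SampleMetadata
from .errors import SpecError

__all__ = [
    "CqGeneSpec",
    "CqSimSpec",
    "PoolSimSpec",
    "simulate_cq_experiment",
    "simulate_expression_pool",
    "thyroid_cq_spec",
    "thyroid_pool_spec",
]


@dataclass(frozen=True)
class CqGeneSpec:
    """True per-gene Cq parameters: group means (cycles) and noise SD."""

    mu_normal: float
    mu_tumor: float
    sd: float


@dataclass
class CqSimSpec:
    """Specification of a paired tumor/normal Cq experiment.

    ``genes`` maps gene id to its true (mu_normal, mu_tumor, sd); Cq
    means must be plausible cycle numbers in (10, 40) and SDs
    non-negative.  ``n_pairs`` is the patient count (each contributes
    one tumor and one adjacent-normal sample).
    """

    genes: Mapping[str, CqGeneSpec]
    n_pairs: int = 17
    seed: int = 0
    tumor_group: str = "PTC"
    normal_group: str = "Normal"

    def __post_init__(self) -> None:
        if not self.genes:
            raise SpecError("CqSimSpec needs at least one gene")
        if self.n_pairs < 1:
            raise SpecError(f"n_pairs must be >= 1, got {self.n_pairs}")
        for gene, gs in self.genes.items():
            if not isinstance(gs, CqGeneSpec):
                raise SpecError(f"gene {gene!r}: expected a CqGeneSpec")
            for mu in (gs.mu_normal, gs.mu_tumor):
                if not 10.0 < mu < 40.0:
                    raise SpecError(
                        f"gene {gene!r}: Cq mean {mu} outside the plausible (10, 40) range"
                    )
            if gs.sd < 0:
                raise SpecError(f"gene {gene!r}: sd must be non-negative, got {gs.sd}")


def simulate_cq_experiment(spec: CqSimSpec) -> CqTable:
    """Draw a paired tumor/normal Cq experiment.

    Each well is drawn independently from Normal(mu_group, sd) for its
    gene; pair P<i> contributes samples ``P<i>_N`` and ``P<i>_T``.
    Reproducible given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    width = max(2, len(str(spec.n_pairs)))
    sample_ids, groups, pair_ids = [], [], []
    for i in range(1, spec.n_pairs + 1):
        pid = f"P{i:0{width}d}"
        for suffix, group in (("N", spec.normal_group), ("T", spec.tumor_group)):
            sample_ids.append(f"{pid}_{suffix}")
            groups.append(group)
            pair_ids.append(pid)
    values = np.empty((len(genes), len(sample_ids)))
    for gi, gene in enumerate(genes):
        gs = spec.genes[gene]
        mus = np.array(
            [gs.mu_normal if g == spec.normal_group else gs.mu_tumor for g in groups]
        )
        values[gi] = rng.normal(mus, gs.sd)
    # Cq values are cycle numbers; keep them positive even under extreme draws
    np.clip(values, 1.0, None, out=values)
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "sex": "unknown",
                "batch": "lab",
                "pair_id": pair_ids,
            }
        )
    )
    return CqTable(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        metadata=metadata,
    )


@dataclass
class PoolSimSpec:
    """Specification of a pooled multi-batch expression matrix.

    ``group_sizes`` maps (subtype, sex) to sample counts.  ``batches``
    maps batch label to its additive offset (log2 units); samples are
    assigned to batches round-robin so batches stay balanced across
    groups.  ``spikes`` maps gene id to {subtype: true ES} shifts added
    on top of the gene baseline; all other genes are null.  Residual
    noise is Normal(0, residual_sd).
    """

    n_genes: int
    group_sizes: Mapping[tuple[str, str], int]
    batches: Mapping[str, float] = field(default_factory=lambda: {"b1": 0.0})
    spikes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    residual_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SpecError("n_genes must be >= 1")
        if not self.group_sizes:
            raise SpecError("at least one (subtype, sex) group is required")
        for key, n in self.group_sizes.items():
            if n < 0:
                raise SpecError(f"group {key}: negative sample count")
        if sum(self.group_sizes.values()) < 1:
            raise SpecError("no samples requested")
        if self.residual_sd <= 0:
            raise SpecError("residual_sd must be positive")
        if not self.batches:
            raise SpecError("at least one batch is required")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        named = list(self.spikes)
        auto = [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]
        # spiked genes take the first rows under their own names
        return named + auto[: self.n_genes - len(named)]


def simulate_expression_pool(
    spec: PoolSimSpec,
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Draw a pooled log2 expression matrix with known ground truth.

    value = gene baseline + spiked subtype effect + batch offset +
    Normal(0, residual_sd).  Reproducible given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    sample_ids, subtypes, sexes = [], [], []
    for (subtype, sex), n in spec.group_sizes.items():
        for _ in range(n):
            sample_ids.append(f"S{len(sample_ids) + 1:04d}")
            subtypes.append(subtype)
            sexes.append(sex)
    batch_labels = list(spec.batches)
    assigned = [batch_labels[i % len(batch_labels)] for i in range(len(sample_ids))]

    lo, hi = spec.baseline_range
    baseline = rng.uniform(lo, hi, size=len(genes))
    values = np.tile(baseline[:, None], (1, len(sample_ids)))
    for gi, gene in enumerate(genes):
        shifts = spec.spikes.get(gene)
        if shifts:
            for si, subtype in enumerate(subtypes):
                values[gi, si] += shifts.get(subtype, 0.0)
    offsets = np.array([spec.batches[b] for b in assigned])
    values += offsets[None, :]
    values += rng.normal(0.0, spec.residual_sd, size=values.shape)

    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": subtypes,
                "sex": sexes,
                "batch": assigned,
                "pair_id": "",
            }
        )
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        scale_tag="log2",
        metadata=metadata,
    )
    return matrix, metadata


def thyroid_cq_spec(
    n_pairs: int = 17,
    seed: int = 0,
    extra_genes: Optional[Mapping[str, CqGeneSpec]] = None,
) -> CqSimSpec:
    """Default paired PTC/normal Cq experiment.

    Gene parameters follow the magnitudes seen in lab RT-qPCR summary
    tables for this design: a high-variance reference well below the
    targets (GAPDH-like, mean ~26 cycles, SD ~4), a low-variance
    reference inside the target Cq range (SYMPK-like, mean ~30, SD
    ~1.7), and three targets around 26-29 cycles with SDs near 3.
    """
    genes: dict[str, CqGeneSpec] = {
        "GAPDH": CqGeneSpec(mu_normal=26.5, mu_tumor=25.7, sd=4.0),
        "SYMPK": CqGeneSpec(mu_normal=30.0, mu_tumor=29.6, sd=1.7),
        "TGT_A": CqGeneSpec(mu_normal=29.0, mu_tumor=28.4, sd=3.0),
        "TGT_B": CqGeneSpec(mu_normal=28.7, mu_tumor=29.3, sd=3.2),
        "TGT_C": CqGeneSpec(mu_normal=26.2, mu_tumor=25.8, sd=3.2),
    }
    if extra_genes:
        genes.update(extra_genes)
    return CqSimSpec(genes=genes, n_pairs=n_pairs, seed=seed)


def thyroid_pool_spec(
    n_genes: int = 500,
    seed: int = 0,
    spikes: Optional[Mapping[str, Mapping[str, float]]] = None,
    residual_sd: float = 0.5,
) -> PoolSimSpec:
    """Default pooled thyroid-subtype design with sexed group sizes.

    Group sizes follow a sexed multi-dataset thyroid compilation
    (253 samples: Normal 30F/14M, PTC 76F/43M, FTA 15F/0M, FTC 15F/9M,
    PDTC 19F/8M, ATC 16F/8M) split over three batches with additive
    log2 offsets (0, +1.5, -1.0).
    """
    sizes = {
        ("Normal", "female"): 30,
        ("Normal", "male"): 14,
        ("PTC", "female"): 76,
        ("PTC", "male"): 43,
        ("FTA", "female"): 15,
        ("FTC", "female"): 15,
        ("FTC", "male"): 9,
        ("PDTC", "female"): 19,
        ("PDTC", "male"): 8,
        ("ATC", "female"): 16,
        ("ATC", "male"): 8,
    }
    return PoolSimSpec(
        n_genes=n_genes,
        group_sizes=sizes,
        batches={"b1": 0.0, "b2": 1.5, "b3": -1.0},
        spikes=dict(spikes or {}),
        residual_sd=residual_sd,
        seed=seed,
    )
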