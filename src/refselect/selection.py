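"""Target-aware reference-gene selection.

A reference gene is only usable for a given target if their expression
distributions do not overlap; otherwise individual samples land on
either side of the reference and their positive and negative ddCq
mutually cancel, inverting apparent expression patterns.  The overlap
criterion formalizes this with the group means and SDs of the two
genes:

    |muT - muR| >= 3*sdT + 2*sdR

where T is the target and R the candidate reference, evaluated on one
consistent scale (Cq cycles or log2 expression) within each sample
group.  The asymmetric multipliers (3 for the target, 2 for the
reference) are fixed constants of the criterion; an override is
provided for sensitivity analyses but is not the default.

Candidates that clear the criterion for a target in every requested
group are then ordered by stability: non-significant FWER first,
smallest |ES| wins, ties broken by CV% then gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import math

from .datatypes import CriterionRecord, EffectSizeRecord, GeneGroupStats
from .errors import DataFormatError
from .stats import stats_lookup

__all__ = [
    "required_gap",
    "criterion_passes",
    "rank_candidates",
    "select_references",
    "RankedCandidate",
    "TargetReport",
    "SelectionReport",
]

TARGET_SD_MULTIPLIER = 3.0
REFERENCE_SD_MULTIPLIER = 2.0


def required_gap(
    sd_t: float,
    sd_r: float,
    target_multiplier: float = TARGET_SD_MULTIPLIER,
    reference_multiplier: float = REFERENCE_SD_MULTIPLIER,
) -> float:
    """Minimum |muT - muR| separating target and reference: 3*sdT + 2*sdR.

    Units follow the expression scale of the inputs (Cq cycles or log2
    units).  With a noiseless reference (sdR = 0) the rule reduces to
    three target SDs; every unit of reference SD adds two more.
    """
    for name, sd in (("sd_t", sd_t), ("sd_r", sd_r)):
        if not math.isfinite(sd):
            raise ValueError(f"{name} must be finite, got {sd}")
        if sd < 0:
            raise ValueError(f"{name} must be non-negative, got {sd}")
    return target_multiplier * sd_t + reference_multiplier * sd_r


def criterion_passes(
    mu_t: float,
    mu_r: float,
    sd_t: float,
    sd_r: float,
    target: str = "target",
    reference: str = "reference",
    group: str = "all",
    target_multiplier: float = TARGET_SD_MULTIPLIER,
    reference_multiplier: float = REFERENCE_SD_MULTIPLIER,
) -> CriterionRecord:
    """Evaluate the overlap criterion for one target/reference/group.

    Boundary equality passes (the criterion is ">=").
    """
    for name, v in (("mu_t", mu_t), ("mu_r", mu_r)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    gap = abs(mu_t - mu_r)
    req = required_gap(sd_t, sd_r, target_multiplier, reference_multiplier)
    return CriterionRecord(
        target=target,
        reference=reference,
        group=group,
        mu_t=mu_t,
        mu_r=mu_r,
        sd_t=sd_t,
        sd_r=sd_r,
        gap=gap,
        required_gap=req,
        passes=bool(gap >= req),
    )


@dataclass
class RankedCandidate:
    """A candidate reference gene with its stability ordering inputs."""

    gene_id: str
    es: float
    fwer: float
    suitable: bool
    cv_percent: float = float("nan")


def rank_candidates(
    records: Sequence[EffectSizeRecord],
    alpha: float = 0.05,
    cv_by_gene: Optional[Mapping[str, float]] = None,
) -> list[RankedCandidate]:
    """Order candidate references by stability for one contrast.

    Candidates with a non-significant effect (fwer >= alpha) come
    first, ordered by |ES| ascending; significant candidates follow,
    flagged unsuitable, in the same order.  Ties break by CV%
    ascending (when supplied) then gene id.
    """
    if not records:
        raise DataFormatError("empty candidate set")
    cv_by_gene = {k.casefold(): v for k, v in (cv_by_gene or {}).items()}
    ranked = [
        RankedCandidate(
            gene_id=r.gene_id,
            es=r.es,
            fwer=r.fwer,
            suitable=bool(r.fwer >= alpha),
            cv_percent=float(cv_by_gene.get(r.gene_id.casefold(), float("nan"))),
        )
        for r in records
    ]

    def key(c: RankedCandidate):
        cv = c.cv_percent if math.isfinite(c.cv_percent) else math.inf
        return (not c.suitable, abs(c.es), cv, c.gene_id.casefold())

    return sorted(ranked, key=key)


@dataclass
class TargetReport:
    """Selection outcome for one target gene."""

    target: str
    criteria: list[CriterionRecord]
    eligible: list[RankedCandidate]
    best_available: Optional[str] = None  # set only when nothing passes
    best_available_margin: float = float("nan")

    @property
    def criterion_met(self) -> bool:
        return bool(self.eligible)


@dataclass
class SelectionReport:
    """Full target-aware selection report."""

    targets: list[TargetReport]
    ranking: list[RankedCandidate]
    groups: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = []
        lines.append(
            "Candidate stability ranking: "
            + ", ".join(
                f"{c.gene_id} (ES={c.es:+.3f}{'' if c.suitable else ', unsuitable'})"
                for c in self.ranking
            )
        )
        for t in self.targets:
            if t.criterion_met:
                refs = ", ".join(c.gene_id for c in t.eligible)
                lines.append(f"{t.target}: eligible references -> {refs}")
            else:
                lines.append(
                    f"{t.target}: no candidate passes the overlap criterion; "
                    f"best-available {t.best_available} "
                    f"(margin {t.best_available_margin:.2f}, criterion unmet)"
                )
        return "\n".join(lines)


def select_references(
    candidates: Sequence[str],
    targets: Sequence[str],
    stats: Iterable[GeneGroupStats],
    es_records: Sequence[EffectSizeRecord],
    groups: Sequence[str],
    alpha: float = 0.05,
    target_multiplier: float = TARGET_SD_MULTIPLIER,
    reference_multiplier: float = REFERENCE_SD_MULTIPLIER,
) -> SelectionReport:
    """Target-aware composite selection.

    For every (target, candidate, group) the overlap criterion is
    evaluated from the supplied group statistics; a candidate is
    eligible for a target only if it passes in *every* requested group.
    Eligible candidates are ordered by `rank_candidates` on the
    supplied effect-size records (CV% of the first requested group
    breaks ties).  When no candidate passes for a target, the report
    flags the candidate with the largest minimum margin
    (gap - required_gap) as "best-available, criterion unmet".

    An empty target list degenerates to the candidate stability
    ranking alone.  Output is deterministic and invariant to the order
    of the candidate list.
    """
    if not candidates:
        raise DataFormatError("empty candidate set")
    if not groups:
        raise DataFormatError("at least one group is required")
    lookup = stats_lookup(stats)

    def stat_for(gene: str, group: str) -> GeneGroupStats:
        try:
            return lookup[(gene.casefold(), group)]
        except KeyError:
            raise DataFormatError(
                f"missing statistics for gene {gene!r} in group {group!r}"
            ) from None

    es_by_gene = {r.gene_id.casefold(): r for r in es_records}
    cand_records = []
    for c in sorted(candidates, key=str.casefold):
        rec = es_by_gene.get(c.casefold())
        if rec is None:
            raise DataFormatError(f"missing effect-size record for candidate {c!r}")
        cand_records.append(rec)
    cv_by_gene = {
        c: stat_for(c, groups[0]).cv_percent for c in candidates
    }
    ranking = rank_candidates(cand_records, alpha=alpha, cv_by_gene=cv_by_gene)

    target_reports = []
    for t in targets:
        criteria: list[CriterionRecord] = []
        min_margin: dict[str, float] = {}
        passes_all: dict[str, bool] = {}
        for c in sorted(candidates, key=str.casefold):
            margins = []
            ok = True
            for g in groups:
                st = stat_for(t, g)
                sr = stat_for(c, g)
                rec = criterion_passes(
                    st.mean, sr.mean, st.sd, sr.sd,
                    target=st.gene_id, reference=sr.gene_id, group=g,
                    target_multiplier=target_multiplier,
                    reference_multiplier=reference_multiplier,
                )
                criteria.append(rec)
                margins.append(rec.margin)
                ok = ok and rec.passes
            min_margin[c] = min(margins)
            passes_all[c.casefold()] = ok
        eligible = [r for r in ranking if passes_all.get(r.gene_id.casefold(), False)]
        if not eligible:
            # deterministic arg-max: largest minimum margin, gene id tie-break
            best = max(
                sorted(min_margin, key=str.casefold), key=lambda c: min_margin[c]
            )
            target_reports.append(
                TargetReport(
                    target=t,
                    criteria=criteria,
                    eligible=[],
                    best_available=stat_for(best, groups[0]).gene_id,
                    best_available_margin=min_margin[best],
                )
            )
        else:
            target_reports.append(
                TargetReport(target=t, criteria=criteria, eligible=eligible)
            )
    return SelectionReport(
        targets=target_reports, ranking=ranking, groups=list(groups)
    )
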