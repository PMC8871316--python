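"""Cohort-level pipeline: PN-based and screenee-based MV-vs-EV comparison.

Every eligible baseline nodule carries two volumes — the software-measured
volume (MV) and the sphere estimate from the maximal diameter (EV) — and
therefore two triage categories.  Nodules re-measured at first recall
additionally carry two volume-doubling-time categories, where the EV-based
VDT uses the sphere estimate at *both* timepoints, simulating a program
that never segments.  This module cross-classifies the two categorisations
per nodule (PN-based) and per screenee via a dominant nodule
(screenee-based), and quantifies the downstream recall burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .agreement import ContingencyTable, build_table
from .volumetry import (
    NoduleObservation,
    OutcomeCategory,
    ScreeningThresholds,
    VdtCategory,
    classify_outcome,
    classify_vdt,
    compute_vdt,
    eligibility_filter,
)

__all__ = [
    "ScreeneeRecord",
    "CohortAnalysisResult",
    "build_screenee_records",
    "select_dominant",
    "pn_based_analysis",
    "screenee_based_analysis",
    "severity_shift_fraction",
    "recall_burden",
    "compare_recall_burden",
]

DominanceRule = Literal["by_MV", "by_EV", "worst_category"]

OUTCOME_LABELS = tuple(c.label for c in OutcomeCategory)
VDT_LABELS = tuple(c.label for c in VdtCategory)


@dataclass
class ScreeneeRecord:
    """All of one screenee's eligible baseline nodules plus any follow-ups.

    ``followups`` maps nodule_id to the timepoint-1 observation when the
    nodule was re-measured.
    """

    screenee_id: str
    nodules: list[NoduleObservation]
    followups: dict[str, NoduleObservation]

    def __post_init__(self) -> None:
        if not self.nodules:
            raise ValueError(f"screenee {self.screenee_id}: no eligible baseline nodule")


@dataclass(frozen=True)
class CohortAnalysisResult:
    """Cross-classification of MV vs EV categories for one unit × metric.

    ``upward_shift_fraction`` is, among discordant items, the fraction whose
    EV category requests a *shorter* follow-up than the MV category (more
    severe triage outcome, or faster VDT category).  ``None`` when there is
    no discordance.
    """

    unit: str  # "PN" | "screenee"
    metric: str  # "ldct_outcome" | "vdt_category"
    table: ContingencyTable
    n_items: int
    n_discordant: int
    discordant_fraction: float
    upward_shift_fraction: Optional[float]

    @classmethod
    def from_table(
        cls, unit: str, metric: str, table: ContingencyTable
    ) -> "CohortAnalysisResult":
        n = table.grand_total
        disc = table.off_diagonal_sum
        # severity increases with column index for the LDCT outcome but
        # decreases for VDT (probably_malignant is listed first)
        ascending = metric == "ldct_outcome"
        shift = (
            severity_shift_fraction(table, ascending_severity=ascending)
            if disc > 0
            else None
        )
        return cls(unit, metric, table, n, disc, disc / n if n else 0.0, shift)


def build_screenee_records(
    observations: Iterable[NoduleObservation],
    thresholds: ScreeningThresholds | None = None,
) -> list[ScreeneeRecord]:
    """Group a flat observation list into per-screenee records.

    Applies the eligibility filter to baseline rows; follow-up rows are kept
    only when their baseline nodule is eligible and they carry a re-measured
    volume.  Screenees left with no eligible nodule are dropped.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    observations = list(observations)
    seen: set[tuple[str, str, int]] = set()
    for obs in observations:
        if obs.key in seen:
            raise ValueError(f"duplicate observation key {obs.key}")
        seen.add(obs.key)
    baseline = eligibility_filter(observations, thresholds)
    eligible_keys = {(o.screenee_id, o.nodule_id) for o in baseline}
    by_screenee: dict[str, ScreeneeRecord] = {}
    for obs in baseline:
        rec = by_screenee.get(obs.screenee_id)
        if rec is None:
            by_screenee[obs.screenee_id] = ScreeneeRecord(obs.screenee_id, [obs], {})
        else:
            rec.nodules.append(obs)
    for obs in observations:
        if obs.timepoint == 0:
            continue
        if (obs.screenee_id, obs.nodule_id) not in eligible_keys:
            continue
        if obs.measured_volume_mm3 is None:
            continue
        by_screenee[obs.screenee_id].followups[obs.nodule_id] = obs
    return [by_screenee[sid] for sid in sorted(by_screenee)]


def select_dominant(record: ScreeneeRecord, rule: DominanceRule = "by_MV") -> str:
    """Nodule id of the screenee's dominant nodule.

    ``by_MV`` (default) picks the largest measured volume, ``by_EV`` the
    largest sphere-estimated volume; ties break by larger maximal diameter,
    then lexicographically smallest nodule id.  ``worst_category`` has no
    single dominant nodule (the per-measure worst category may come from
    different nodules) and is handled inside the screenee-based analysis.
    """
    if rule == "worst_category":
        raise ValueError("worst_category defines no single dominant nodule")
    if rule not in ("by_MV", "by_EV"):
        raise ValueError(f"unknown dominance rule {rule!r}")

    def sort_key(obs: NoduleObservation):
        size = (
            obs.measured_volume_mm3 if rule == "by_MV" else obs.estimated_volume_mm3
        )
        if size is None:
            raise ValueError(
                f"nodule {obs.nodule_id} lacks a baseline measured volume"
            )
        return (-size, -obs.max_diameter_mm, obs.nodule_id)

    return min(record.nodules, key=sort_key).nodule_id


def _nodule_category_pair(
    obs: NoduleObservation, thresholds: ScreeningThresholds
) -> tuple[OutcomeCategory, OutcomeCategory]:
    if obs.measured_volume_mm3 is None:
        raise ValueError(f"nodule {obs.key} lacks a baseline measured volume")
    mv_cat = classify_outcome(obs.measured_volume_mm3, thresholds)
    ev_cat = classify_outcome(obs.estimated_volume_mm3, thresholds)
    return mv_cat, ev_cat


def _vdt_category_pair(
    base: NoduleObservation,
    follow: NoduleObservation,
    thresholds: ScreeningThresholds,
) -> tuple[VdtCategory, VdtCategory]:
    dt = follow.days_from_baseline - base.days_from_baseline
    mv_vdt = compute_vdt(base.measured_volume_mm3, follow.measured_volume_mm3, dt)
    ev_vdt = compute_vdt(base.estimated_volume_mm3, follow.estimated_volume_mm3, dt)
    return classify_vdt(mv_vdt, thresholds), classify_vdt(ev_vdt, thresholds)


def pn_based_analysis(
    cohort: Sequence[ScreeneeRecord],
    thresholds: ScreeningThresholds | None = None,
) -> dict[str, CohortAnalysisResult]:
    """Cross-classify MV vs EV categories with each nodule as one item.

    Returns results keyed ``"ldct_outcome"`` and ``"vdt_category"``.  The
    VDT table only counts nodules with a re-measured follow-up volume.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    if not cohort:
        raise ValueError("empty cohort")
    outcome_pairs = []
    vdt_pairs = []
    for rec in cohort:
        for obs in rec.nodules:
            outcome_pairs.append(_nodule_category_pair(obs, thresholds))
            follow = rec.followups.get(obs.nodule_id)
            if follow is not None:
                vdt_pairs.append(_vdt_category_pair(obs, follow, thresholds))
    return {
        "ldct_outcome": CohortAnalysisResult.from_table(
            "PN", "ldct_outcome", build_table(outcome_pairs, list(OutcomeCategory))
        ),
        "vdt_category": CohortAnalysisResult.from_table(
            "PN", "vdt_category", build_table(vdt_pairs, list(VdtCategory))
        ),
    }


def screenee_based_analysis(
    cohort: Sequence[ScreeneeRecord],
    thresholds: ScreeningThresholds | None = None,
    rule: DominanceRule = "by_MV",
) -> dict[str, CohortAnalysisResult]:
    """Cross-classify MV vs EV categories with one item per screenee.

    Under ``by_MV``/``by_EV`` the dominant nodule supplies both categories;
    under ``worst_category`` each measure contributes its most severe
    category over all of the screenee's nodules.  The VDT analysis keeps
    only screenees whose dominant nodule (or, for ``worst_category``, any
    nodule) has a follow-up measurement.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    if not cohort:
        raise ValueError("empty cohort")
    outcome_pairs = []
    vdt_pairs = []
    for rec in cohort:
        if rule == "worst_category":
            pairs = [_nodule_category_pair(o, thresholds) for o in rec.nodules]
            outcome_pairs.append(
                (max(p[0] for p in pairs), max(p[1] for p in pairs))
            )
            vps = [
                _vdt_category_pair(o, rec.followups[o.nodule_id], thresholds)
                for o in rec.nodules
                if o.nodule_id in rec.followups
            ]
            if vps:
                # most severe = shortest VDT category = smallest enum value
                vdt_pairs.append((min(p[0] for p in vps), min(p[1] for p in vps)))
        else:
            dom_id = select_dominant(rec, rule)
            dom = next(o for o in rec.nodules if o.nodule_id == dom_id)
            outcome_pairs.append(_nodule_category_pair(dom, thresholds))
            follow = rec.followups.get(dom_id)
            if follow is not None:
                vdt_pairs.append(_vdt_category_pair(dom, follow, thresholds))
    return {
        "ldct_outcome": CohortAnalysisResult.from_table(
            "screenee", "ldct_outcome", build_table(outcome_pairs, list(OutcomeCategory))
        ),
        "vdt_category": CohortAnalysisResult.from_table(
            "screenee", "vdt_category", build_table(vdt_pairs, list(VdtCategory))
        ),
    }


def severity_shift_fraction(
    table: ContingencyTable, ascending_severity: bool = True
) -> float:
    """Fraction of discordant items shifted toward a more severe EV category.

    ``ascending_severity`` says whether severity increases with label index
    (true for the LDCT outcome ordering negative < indeterminate < positive;
    false for VDT categories, where the most severe — probably malignant —
    is listed first).  Raises when the table has no discordant items.
    """
    disc = table.off_diagonal_sum
    if disc == 0:
        raise ValueError("no discordant items: severity shift undefined")
    shifted = table.above_diagonal_sum if ascending_severity else table.below_diagonal_sum
    return shifted / disc


def recall_burden(
    categories: Iterable[OutcomeCategory],
    thresholds: ScreeningThresholds | None = None,
    horizon_months: float = 36.0,
) -> int:
    """Total follow-up LDCTs scheduled across screenees within a horizon.

    Each screenee repeats LDCT at the interval their category dictates, at
    interval, 2·interval, ... up to and including the horizon; the baseline
    scan itself is not counted.  With the default mapping a negative
    screenee contributes one scan per 36-month horizon, an indeterminate
    screenee three, a positive twelve.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    total = 0
    for cat in categories:
        interval = thresholds.interval_by_category[OutcomeCategory(cat)]
        total += int((horizon_months + 1e-9) // interval)
    return total


def compare_recall_burden(
    mv_categories: Sequence[OutcomeCategory],
    ev_categories: Sequence[OutcomeCategory],
    thresholds: ScreeningThresholds | None = None,
    horizon_months: float = 36.0,
) -> dict[str, int]:
    """MV-based vs EV-based scheduled-scan totals over the same screenees."""
    if len(mv_categories) != len(ev_categories):
        raise ValueError("category sequences must align one-to-one")
    mv_total = recall_burden(mv_categories, thresholds, horizon_months)
    ev_total = recall_burden(ev_categories, thresholds, horizon_months)
    return {"mv_scans": mv_total, "ev_scans": ev_total, "difference": ev_total - mv_total}
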