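"""Nodule-level volumetry: estimated volume, triage categories, doubling time.

Lung cancer screening programs that manage solid pulmonary nodules by volume
assign each nodule a triage category from its volume in mm³ and, at recall,
from its volume doubling time (VDT) in days.  Two volume readings are
compared throughout this package: the *measured volume* (MV) reported by
semi-automated segmentation software, and the *estimated volume* (EV)
obtained by treating the nodule as a sphere of its maximal diameter,
``EV = (π/6)·D³``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "OutcomeCategory",
    "VdtCategory",
    "NoduleObservation",
    "ScreeningThresholds",
    "DAYS_PER_MONTH",
    "estimated_volume",
    "diameter_from_volume",
    "classify_outcome",
    "compute_vdt",
    "classify_vdt",
    "eligibility_filter",
]

#: Mean Gregorian month length, used when a follow-up interval quoted in
#: months must be placed on the day axis.
DAYS_PER_MONTH = 30.44


class OutcomeCategory(enum.IntEnum):
    """LDCT triage outcome, ordered by increasing severity.

    Severity drives the interval to the next scan: a negative outcome means
    routine rescreening, indeterminate an early repeat LDCT, positive an
    immediate diagnostic work-up.
    """

    NEGATIVE = 0
    INDETERMINATE = 1
    POSITIVE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


class VdtCategory(enum.IntEnum):
    """Growth category from volume doubling time, ordered by increasing VDT.

    Shorter doubling times suggest malignancy, so — unlike
    :class:`OutcomeCategory` — severity *decreases* along this order.
    """

    PROBABLY_MALIGNANT = 0
    INDETERMINATE = 1
    PROBABLY_BENIGN = 2

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class NoduleObservation:
    """One solid pulmonary nodule observed at one screening timepoint.

    Parameters
    ----------
    screenee_id, nodule_id
        Opaque identifiers; ``nodule_id`` is unique within a screenee.
    timepoint
        Ordinal scan index: 0 = baseline, 1 = first recall.
    days_from_baseline
        Days elapsed since the baseline scan (0 at baseline).
    max_diameter_mm
        Software-reported maximal diameter, mm.
    measured_volume_mm3
        Segmentation volume, mm³.  ``None`` when the nodule was not
        re-measured at follow-up.
    """

    screenee_id: str
    nodule_id: str
    timepoint: int
    days_from_baseline: float
    max_diameter_mm: float
    measured_volume_mm3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_diameter_mm <= 0:
            raise ValueError(
                f"max_diameter_mm must be positive, got {self.max_diameter_mm}"
            )
        if self.measured_volume_mm3 is not None and self.measured_volume_mm3 <= 0:
            raise ValueError(
                f"measured_volume_mm3 must be positive, got {self.measured_volume_mm3}"
            )
        if self.days_from_baseline < 0:
            raise ValueError("days_from_baseline must be non-negative")
        if self.timepoint == 0 and self.days_from_baseline != 0:
            raise ValueError("baseline records must have days_from_baseline = 0")

    @property
    def estimated_volume_mm3(self) -> float:
        """Sphere volume from the maximal diameter."""
        return estimated_volume(self.max_diameter_mm)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.screenee_id, self.nodule_id, self.timepoint)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Trial thresholds for triage and growth categorisation.

    Defaults follow a volumetric screening protocol: negative below 113 mm³,
    positive above 260 mm³, indeterminate in the closed band between;
    probably-malignant growth below 400 days VDT, probably-benign above 600,
    with the closed band [400, 600] indeterminate.  Nodules enter the study
    at a maximal diameter of at least 3 mm (inclusive).

    ``shrinking_vdt_rule`` controls how non-positive or undefined VDTs
    (stable or shrinking nodules) are categorised:

    - ``"benign"`` (default): shrinkage is not growth, hence probably benign.
    - ``"literal"``: apply the printed band edges literally, so a negative
      VDT satisfies "< 400 days" and is called probably malignant; an
      undefined VDT (no volume change) is probably benign.
    """

    neg_max_mm3: float = 113.0
    pos_min_mm3: float = 260.0
    vdt_malignant_max_days: float = 400.0
    vdt_benign_min_days: float = 600.0
    min_diameter_mm: float = 3.0
    shrinking_vdt_rule: str = "benign"
    interval_by_category: dict = field(
        default_factory=lambda: {
            OutcomeCategory.NEGATIVE: 36.0,
            OutcomeCategory.INDETERMINATE: 12.0,
            OutcomeCategory.POSITIVE: 3.0,
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.neg_max_mm3 < self.pos_min_mm3:
            raise ValueError("require 0 < neg_max_mm3 < pos_min_mm3")
        if not 0 < self.vdt_malignant_max_days < self.vdt_benign_min_days:
            raise ValueError("require 0 < vdt_malignant_max_days < vdt_benign_min_days")
        if self.min_diameter_mm < 0:
            raise ValueError("min_diameter_mm must be non-negative")
        if self.shrinking_vdt_rule not in ("benign", "literal"):
            raise ValueError("shrinking_vdt_rule must be 'benign' or 'literal'")
        ivals = [self.interval_by_category[c] for c in sorted(OutcomeCategory)]
        if not all(a > b for a, b in zip(ivals, ivals[1:])):
            raise ValueError("follow-up interval must strictly decrease with severity")


def estimated_volume(max_diameter_mm: float) -> float:
    """Volume of a sphere of diameter ``max_diameter_mm``, in mm³.

    ``V = (π/6)·D³`` — the standard geometric conversion used when only a
    diameter is available.
    """
    if max_diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi / 6.0 * max_diameter_mm**3


def diameter_from_volume(volume_mm3: float) -> float:
    """Diameter of a sphere of volume ``volume_mm3``, in mm.

    Exact inverse of :func:`estimated_volume`: ``D = (6V/π)^(1/3)``.
    """
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


def classify_outcome(
    volume_mm3: float, thresholds: ScreeningThresholds | None = None
) -> OutcomeCategory:
    """Assign the LDCT triage outcome for a nodule volume.

    The indeterminate band is closed on both ends: volumes exactly at either
    cut-off are indeterminate, matching strict inequalities on the outer
    categories (< 113, > 260 by default).
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    if volume_mm3 < thresholds.neg_max_mm3:
        return OutcomeCategory.NEGATIVE
    if volume_mm3 > thresholds.pos_min_mm3:
        return OutcomeCategory.POSITIVE
    return OutcomeCategory.INDETERMINATE


def compute_vdt(
    v1_mm3: float, v2_mm3: float, delta_days: float
) -> Optional[float]:
    """Volume doubling time in days: ``VDT = ln2·ΔT / ln(V2/V1)``.

    Negative when the nodule shrank; ``None`` (undefined) when the two
    volumes are exactly equal, since no finite doubling time describes a
    volume that did not change.
    """
    if v1_mm3 <= 0 or v2_mm3 <= 0:
        raise ValueError("volumes must be positive")
    if delta_days <= 0:
        raise ValueError("delta_days must be positive")
    if v2_mm3 == v1_mm3:
        return None
    return math.log(2.0) * delta_days / math.log(v2_mm3 / v1_mm3)


def classify_vdt(
    vdt_days: Optional[float], thresholds: ScreeningThresholds | None = None
) -> VdtCategory:
    """Assign the growth category for a volume doubling time.

    Growing nodules follow the band edges (< 400 probably malignant,
    [400, 600] indeterminate, > 600 probably benign by default).  Stable or
    shrinking nodules (``vdt_days`` undefined or non-positive) follow
    ``thresholds.shrinking_vdt_rule``; see :class:`ScreeningThresholds`.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    if vdt_days is None:
        return VdtCategory.PROBABLY_BENIGN
    if vdt_days <= 0:
        if thresholds.shrinking_vdt_rule == "literal":
            return VdtCategory.PROBABLY_MALIGNANT
        return VdtCategory.PROBABLY_BENIGN
    if vdt_days < thresholds.vdt_malignant_max_days:
        return VdtCategory.PROBABLY_MALIGNANT
    if vdt_days > thresholds.vdt_benign_min_days:
        return VdtCategory.PROBABLY_BENIGN
    return VdtCategory.INDETERMINATE


def eligibility_filter(
    observations: Iterable[NoduleObservation],
    thresholds: ScreeningThresholds | None = None,
) -> list[NoduleObservation]:
    """Baseline records eligible for analysis: diameter at or above the floor.

    Only timepoint-0 records are returned; follow-up rows attach to their
    baseline nodule downstream and are not filtered here.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    return [
        obs
        for obs in observations
        if obs.timepoint == 0 and obs.max_diameter_mm >= thresholds.min_diameter_mm
    ]
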