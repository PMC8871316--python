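"""Cohort file readers/writers and the packaged reference tables.

A cohort file is delimited text (comma or tab, auto-detected) with one row
per (screenee, nodule, timepoint) and columns::

    screenee_id, nodule_id, timepoint, days_from_baseline,
    max_diameter_mm, measured_volume_mm3

An empty ``measured_volume_mm3`` field marks a follow-up scan where the
nodule was not re-measured.

The four published 3×3 cross-classifications (PN-based and screenee-based,
LDCT outcome and VDT category) ship as packaged CSV fixtures and load via
:func:`load_fixture`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .agreement import ContingencyTable
from .volumetry import NoduleObservation

__all__ = [
    "COHORT_COLUMNS",
    "FIXTURE_NAMES",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "cohort_to_dataframe",
    "load_fixture",
    "load_all_fixtures",
]

COHORT_COLUMNS = (
    "screenee_id",
    "nodule_id",
    "timepoint",
    "days_from_baseline",
    "max_diameter_mm",
    "measured_volume_mm3",
)

#: Packaged cross-classification tables: unit (PN/screenee) × metric.
FIXTURE_NAMES = ("pn_ldct", "pn_vdt", "screenee_ldct", "screenee_vdt")

_FIXTURE_TOTALS = {
    "pn_ldct": 2715,
    "pn_vdt": 2311,
    "screenee_ldct": 1583,
    "screenee_vdt": 1347,
}


class CohortParseError(ValueError):
    """A cohort file failed validation; the message names the offending lines."""


def _fail(path, problems: list[str]) -> None:
    raise CohortParseError(f"{path}: " + "; ".join(problems))


def read_cohort(path: str | Path) -> list[NoduleObservation]:
    """Read and validate a cohort file into observation records.

    Malformed rows (non-numeric fields, missing baseline volume, duplicate
    keys) are reported with their line numbers in a single
    :class:`CohortParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        _fail(path, ["file is empty"])
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        _fail(path, [f"missing columns: {sorted(missing)}"])

    problems: list[str] = []
    records: list[NoduleObservation] = []
    seen: dict[tuple, int] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after the header
        try:
            timepoint = int(getattr(row, "timepoint"))
            days = float(getattr(row, "days_from_baseline"))
            diam = float(getattr(row, "max_diameter_mm"))
            vol_raw = getattr(row, "measured_volume_mm3")
            vol = None if pd.isna(vol_raw) or str(vol_raw).strip() == "" else float(vol_raw)
            obs = NoduleObservation(
                screenee_id=str(getattr(row, "screenee_id")),
                nodule_id=str(getattr(row, "nodule_id")),
                timepoint=timepoint,
                days_from_baseline=days,
                max_diameter_mm=diam,
                measured_volume_mm3=vol,
            )
            if obs.timepoint == 0 and obs.measured_volume_mm3 is None:
                raise ValueError("baseline record lacks measured_volume_mm3")
        except (TypeError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
            continue
        if obs.key in seen:
            problems.append(
                f"line {line}: duplicate key {obs.key} (first seen on line {seen[obs.key]})"
            )
            continue
        seen[obs.key] = line
        records.append(obs)
    if problems:
        _fail(path, problems)
    return records


def cohort_to_dataframe(observations: Iterable[NoduleObservation]) -> pd.DataFrame:
    rows = [
        {
            "screenee_id": o.screenee_id,
            "nodule_id": o.nodule_id,
            "timepoint": o.timepoint,
            "days_from_baseline": o.days_from_baseline,
            "max_diameter_mm": o.max_diameter_mm,
            "measured_volume_mm3": o.measured_volume_mm3,
        }
        for o in observations
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(
    observations: Iterable[NoduleObservation], path: str | Path, sep: str = ","
) -> None:
    """Write observations in normalized column order; missing volumes as empty."""
    cohort_to_dataframe(observations).to_csv(path, sep=sep, index=False)


def load_fixture(name: str) -> ContingencyTable:
    """Load one packaged cross-classification table by name.

    Names: ``pn_ldct``, ``pn_vdt``, ``screenee_ldct``, ``screenee_vdt``
    (rows = MV categories, columns = EV categories).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("nodulevol.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        table = ContingencyTable.read_csv(p)
    if table.grand_total != _FIXTURE_TOTALS[name]:
        raise RuntimeError(
            f"fixture {name} grand total {table.grand_total} != {_FIXTURE_TOTALS[name]}"
        )
    return table


def load_all_fixtures() -> dict[str, ContingencyTable]:
    return {name: load_fixture(name) for name in FIXTURE_NAMES}
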