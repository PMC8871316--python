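import math

import pytest
from hypothesis import HealthCheck, settings

from nodulevol import (
    NoduleObservation,
    diameter_from_volume,
    load_all_fixtures,
)

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# Published kappa values (2 d.p.) for the four packaged tables.
PUBLISHED_KAPPA = {
    "pn_ldct": 0.49,
    "pn_vdt": 0.37,
    "screenee_ldct": 0.52,
    "screenee_vdt": 0.34,
}

# Representative volumes, one per LDCT outcome band (mm³).
OUTCOME_REP_VOLUME = {0: 50.0, 1: 150.0, 2: 400.0}
# Representative true doubling times, one per VDT band (days).
VDT_REP_DAYS = {0: 200.0, 1: 500.0, 2: 800.0}


@pytest.fixture(scope="session")
def fixture_tables():
    return load_all_fixtures()


def outcome_cell_nodule(screenee_id, nodule_id, mv_band, ev_band):
    """One baseline nodule whose MV lands in mv_band and EV in ev_band."""
    return NoduleObservation(
        screenee_id=screenee_id,
        nodule_id=nodule_id,
        timepoint=0,
        days_from_baseline=0,
        max_diameter_mm=diameter_from_volume(OUTCOME_REP_VOLUME[ev_band]),
        measured_volume_mm3=OUTCOME_REP_VOLUME[mv_band],
    )


def vdt_cell_nodule_pair(screenee_id, nodule_id, mv_band, ev_band, delta_days=365.0):
    """Baseline + follow-up records whose MV-VDT lands in mv_band and EV-VDT in ev_band.

    VDT depends only on the volume ratio, so baseline MV and EV can be fixed
    (100 mm³ each) and the follow-up values grown at the band's
    representative doubling time.
    """
    v0 = 100.0
    base = NoduleObservation(
        screenee_id=screenee_id,
        nodule_id=nodule_id,
        timepoint=0,
        days_from_baseline=0,
        max_diameter_mm=diameter_from_volume(v0),
        measured_volume_mm3=v0,
    )
    mv2 = v0 * 2.0 ** (delta_days / VDT_REP_DAYS[mv_band])
    ev2 = v0 * 2.0 ** (delta_days / VDT_REP_DAYS[ev_band])
    follow = NoduleObservation(
        screenee_id=screenee_id,
        nodule_id=nodule_id,
        timepoint=1,
        days_from_baseline=delta_days,
        max_diameter_mm=diameter_from_volume(ev2),
        measured_volume_mm3=mv2,
    )
    return base, follow


def expand_outcome_table(counts, one_nodule_per_screenee):
    """Per-nodule records realising a 3x3 LDCT cross-tab.

    With ``one_nodule_per_screenee`` each item is its screenee's only
    (hence dominant) nodule; otherwise all items share one screenee.
    """
    observations = []
    serial = 0
    for i in range(3):
        for j in range(3):
            for _ in range(int(counts[i][j])):
                sid = f"P{serial:05d}" if one_nodule_per_screenee else "P00000"
                observations.append(outcome_cell_nodule(sid, f"n{serial}", i, j))
                serial += 1
    return observations


def expand_vdt_table(counts, one_nodule_per_screenee):
    """Baseline + follow-up records realising a 3x3 VDT cross-tab."""
    observations = []
    serial = 0
    for i in range(3):
        for j in range(3):
            for _ in range(int(counts[i][j])):
                sid = f"P{serial:05d}" if one_nodule_per_screenee else "P00000"
                observations.extend(vdt_cell_nodule_pair(sid, f"n{serial}", i, j))
                serial += 1
    return observations
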