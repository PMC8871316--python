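"""Cohort pipeline: dominance, PN/screenee cross-tabs, shifts, recall burden."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nodulevol import (
    ContingencyTable,
    NoduleObservation,
    OutcomeCategory,
    ScreeningThresholds,
    ScreeneeRecord,
    build_screenee_records,
    classify_outcome,
    compare_recall_burden,
    diameter_from_volume,
    pn_based_analysis,
    recall_burden,
    screenee_based_analysis,
    select_dominant,
    severity_shift_fraction,
)

from conftest import expand_outcome_table, expand_vdt_table

THR = ScreeningThresholds()


def _nodule(sid, nid, mv, diameter=None):
    if diameter is None:
        diameter = diameter_from_volume(mv)
    return NoduleObservation(sid, nid, 0, 0, diameter, mv)


class TestSelectDominant:
    def test_single_nodule(self):
        rec = ScreeneeRecord("s", [_nodule("s", "only", 80.0)], {})
        assert select_dominant(rec) == "only"

    def test_largest_mv_wins(self):
        rec = ScreeneeRecord(
            "s", [_nodule("s", "a", 50.0), _nodule("s", "b", 300.0)], {}
        )
        assert select_dominant(rec) == "b"

    def test_mv_tie_broken_by_diameter_then_id(self):
        rec = ScreeneeRecord(
            "s",
            [_nodule("s", "a", 200.0, diameter=7.0), _nodule("s", "b", 200.0, diameter=8.0)],
            {},
        )
        assert select_dominant(rec) == "b"
        rec2 = ScreeneeRecord(
            "s",
            [_nodule("s", "z", 200.0, diameter=7.0), _nodule("s", "a", 200.0, diameter=7.0)],
            {},
        )
        assert select_dominant(rec2) == "a"

    def test_by_ev_rule_uses_diameter_derived_volume(self):
        # small MV but big diameter: dominant under by_EV, not under by_MV
        rec = ScreeneeRecord(
            "s",
            [_nodule("s", "a", 300.0, diameter=5.0), _nodule("s", "b", 50.0, diameter=12.0)],
            {},
        )
        assert select_dominant(rec, "by_MV") == "a"
        assert select_dominant(rec, "by_EV") == "b"

    def test_worst_category_has_no_single_nodule(self):
        rec = ScreeneeRecord("s", [_nodule("s", "a", 50.0)], {})
        with pytest.raises(ValueError):
            select_dominant(rec, "worst_category")

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            ScreeneeRecord("s", [], {})


class TestTableReconstruction:
    """The analyses must reproduce any cross-tab realised as per-item records."""

    @pytest.mark.parametrize("name", ["pn_ldct", "screenee_ldct"])
    def test_outcome_tables(self, fixture_tables, name):
        table = fixture_tables[name]
        per_screenee = name.startswith("screenee")
        observations = expand_outcome_table(table.counts, per_screenee)
        cohort = build_screenee_records(observations, THR)
        if per_screenee:
            res = screenee_based_analysis(cohort, THR)["ldct_outcome"]
        else:
            res = pn_based_analysis(cohort, THR)["ldct_outcome"]
        assert (res.table.counts == table.counts).all()
        assert res.n_items == table.grand_total
        assert res.n_discordant == table.off_diagonal_sum

    @pytest.mark.parametrize("name", ["pn_vdt", "screenee_vdt"])
    def test_vdt_tables(self, fixture_tables, name):
        table = fixture_tables[name]
        per_screenee = name.startswith("screenee")
        observations = expand_vdt_table(table.counts, per_screenee)
        cohort = build_screenee_records(observations, THR)
        if per_screenee:
            res = screenee_based_analysis(cohort, THR)["vdt_category"]
        else:
            res = pn_based_analysis(cohort, THR)["vdt_category"]
        assert (res.table.counts == table.counts).all()

    def test_vdt_denominator_excludes_unfollowed(self):
        observations = expand_vdt_table([[2, 0, 0], [0, 0, 0], [0, 0, 1]], False)
        observations.append(_nodule("P00000", "extra", 90.0))  # no follow-up
        cohort = build_screenee_records(observations, THR)
        res = pn_based_analysis(cohort, THR)
        assert res["ldct_outcome"].n_items == 4
        assert res["vdt_category"].n_items == 3


class TestAnalysisProperties:
    def test_identical_measures_have_zero_discordance(self):
        observations = [_nodule(f"s{i}", "n", v) for i, v in enumerate([50, 150, 400])]
        cohort = build_screenee_records(observations, THR)
        for res in (
            pn_based_analysis(cohort, THR)["ldct_outcome"],
            screenee_based_analysis(cohort, THR)["ldct_outcome"],
        ):
            assert res.n_discordant == 0
            assert res.discordant_fraction == 0.0
            assert res.upward_shift_fraction is None

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=20, max_value=1000),  # MV
                st.floats(min_value=1.0, max_value=1.6),  # EV inflation factor
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_ev_at_least_mv_leaves_below_diagonal_empty(self, nodules):
        observations = [
            _nodule(f"s{i}", "n", mv, diameter=diameter_from_volume(mv * f))
            for i, (mv, f) in enumerate(nodules)
        ]
        cohort = build_screenee_records(observations, THR)
        res = pn_based_analysis(cohort, THR)["ldct_outcome"]
        assert res.table.below_diagonal_sum == 0
        assert res.n_items == len(observations)

    def test_brute_force_tally_matches_analysis(self):
        rng = np.random.default_rng(42)
        observations = [
            _nodule(
                f"s{i}",
                "n",
                float(rng.uniform(20, 600)),
                diameter=diameter_from_volume(float(rng.uniform(20, 600))),
            )
            for i in range(200)
        ]
        cohort = build_screenee_records(observations, THR)
        res = pn_based_analysis(cohort, THR)["ldct_outcome"]
        tally = np.zeros((3, 3), dtype=int)
        for o in observations:
            tally[
                classify_outcome(o.measured_volume_mm3, THR),
                classify_outcome(o.estimated_volume_mm3, THR),
            ] += 1
        assert (res.table.counts == tally).all()
        assert res.discordant_fraction == pytest.approx(
            1 - res.table.diagonal_sum / res.table.grand_total
        )

    def test_worst_category_takes_most_severe_per_measure(self):
        # nodule a: MV negative / EV indeterminate; nodule b: MV indeterminate / EV negative
        observations = [
            _nodule("s", "a", 50.0, diameter=diameter_from_volume(150.0)),
            _nodule("s", "b", 150.0, diameter=diameter_from_volume(50.0)),
        ]
        cohort = build_screenee_records(observations, THR)
        res = screenee_based_analysis(cohort, THR, rule="worst_category")["ldct_outcome"]
        # both measures are indeterminate at worst, though via different nodules
        assert res.table.counts[1, 1] == 1
        assert res.n_discordant == 0


class TestSeverityShift:
    def test_screenee_ldct_fixture_value(self, fixture_tables):
        frac = severity_shift_fraction(fixture_tables["screenee_ldct"])
        assert frac == pytest.approx(727 / 728)

    def test_pure_upper_triangle_and_symmetry(self):
        up = ContingencyTable(("a", "b"), np.array([[0, 5], [0, 0]]))
        assert severity_shift_fraction(up) == 1.0
        sym = ContingencyTable(("a", "b"), np.array([[0, 5], [5, 0]]))
        assert severity_shift_fraction(sym) == 0.5

    def test_descending_severity_counts_below_diagonal(self):
        t = ContingencyTable(("mal", "ind", "ben"), np.array([[0, 0, 0], [4, 0, 0], [0, 0, 0]]))
        assert severity_shift_fraction(t, ascending_severity=False) == 1.0

    def test_no_discordance_is_undefined(self):
        t = ContingencyTable(("a", "b"), np.diag([2, 3]))
        with pytest.raises(ValueError):
            severity_shift_fraction(t)


class TestRecallBurden:
    def test_schedule_counts(self):
        neg = [OutcomeCategory.NEGATIVE] * 4
        assert recall_burden(neg, THR, horizon_months=36) == 4  # one scan each
        assert recall_burden([OutcomeCategory.INDETERMINATE], THR, 36) == 3
        assert recall_burden([OutcomeCategory.POSITIVE], THR, 36) == 12

    def test_horizon_shorter_than_interval_schedules_nothing(self):
        assert recall_burden([OutcomeCategory.NEGATIVE], THR, horizon_months=24) == 0

    def test_comparison_and_monotonicity(self):
        mv = [OutcomeCategory.NEGATIVE, OutcomeCategory.NEGATIVE]
        ev = [OutcomeCategory.INDETERMINATE, OutcomeCategory.POSITIVE]
        out = compare_recall_burden(mv, ev, THR, 36)
        assert out == {"mv_scans": 2, "ev_scans": 15, "difference": 13}

    @given(
        st.lists(st.sampled_from(list(OutcomeCategory)), min_size=1, max_size=20),
        st.integers(min_value=0, max_value=2),
    )
    def test_upward_shift_never_reduces_burden(self, cats, bump_idx):
        bumped = list(cats)
        i = bump_idx % len(bumped)
        bumped[i] = OutcomeCategory(min(2, bumped[i] + 1))
        assert recall_burden(bumped, THR, 36) >= recall_burden(cats, THR, 36)


class TestBuildScreeneeRecords:
    def test_duplicate_key_rejected(self):
        obs = [_nodule("s", "n", 50.0), _nodule("s", "n", 60.0)]
        with pytest.raises(ValueError, match="duplicate"):
            build_screenee_records(obs, THR)

    def test_ineligible_screenee_dropped(self):
        obs = [
            NoduleObservation("small", "n", 0, 0, 2.0, 4.0),
            _nodule("ok", "n", 50.0),
        ]
        cohort = build_screenee_records(obs, THR)
        assert [r.screenee_id for r in cohort] == ["ok"]

    def test_followup_without_volume_ignored(self):
        obs = [
            _nodule("s", "n", 50.0),
            NoduleObservation("s", "n", 1, 365, 5.0, None),
        ]
        cohort = build_screenee_records(obs, THR)
        assert cohort[0].followups == {}
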