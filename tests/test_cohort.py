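"""Cohort construction: first-stay selection, worst-value extraction and
outcome stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_worst, make_events, make_stays, random_extraction_fixture
from icuref.cohort import (
    assign_outcome_groups,
    build_cohort_table,
    extract_worst_first_day,
    select_first_stays,
    survivor_quartiles,
    worst_value_column,
)
from icuref.exceptions import ConfigurationError, InputDataError
from icuref.panel import demo_panel
from icuref.reference import LabSpec, ReferenceInterval
from icuref.synthetic import SyntheticConfig, generate

ALB = LabSpec("albumin", ReferenceInterval(3.5, 5.0), directions=("minimum",))
BOTH = LabSpec("probe", ReferenceInterval(0, 10), directions=("minimum", "maximum"))


class TestSelectFirstStays:
    def test_earliest_intime_kept(self):
        stays = make_stays(
            [("P1", "B", 5, 2, 50, False), ("P1", "A", 0, 2, 50, False)]
        )
        out = select_first_stays(stays)
        assert out["stay_id"].tolist() == ["A"]

    def test_tie_broken_by_smallest_stay_id(self):
        stays = make_stays(
            [("P1", "B", 0, 2, 50, False), ("P1", "A", 0, 3, 50, False)]
        )
        assert select_first_stays(stays)["stay_id"].tolist() == ["A"]

    def test_adult_filter_and_masked_age_sentinel(self):
        stays = make_stays(
            [
                ("P1", "A", 0, 2, 10, False),   # child: removed
                ("P2", "B", 0, 2, 40, False),
                ("P3", "C", 0, 2, 308, False),  # masked age: retained
            ]
        )
        out = select_first_stays(stays, adult_age_min=18)
        assert sorted(out["stay_id"]) == ["B", "C"]

    def test_duplicate_stay_id_rejected(self):
        stays = make_stays(
            [("P1", "A", 0, 2, 50, False), ("P2", "A", 1, 2, 50, False)]
        )
        with pytest.raises(InputDataError):
            select_first_stays(stays)

    def test_row_count_equals_distinct_adult_subjects(self):
        cfg = SyntheticConfig(n_patients=500, seed=9, multi_stay_fraction=0.3)
        stays, _, _ = generate(cfg)
        out = select_first_stays(stays)
        assert len(out) == stays["subject_id"].nunique()
        # brute-force per-subject scan oracle
        for subject, grp in stays.groupby("subject_id"):
            expected = grp.sort_values(["intime", "stay_id"]).iloc[0]["stay_id"]
            got = out.loc[out["subject_id"] == subject, "stay_id"].item()
            assert got == expected


class TestExtractWorstFirstDay:
    def test_single_event_yields_min_and_max(self):
        stays = make_stays([("P1", "A", 0, 2, 50, False)])
        events = make_events([("P1", "A", "probe", 3, 7.0)])
        out = extract_worst_first_day(events, stays, [BOTH])
        assert len(out) == 2
        assert set(out["value"]) == {7.0}
        assert set(out["direction"]) == {"minimum", "maximum"}

    def test_minimum_only_direction(self):
        stays = make_stays([("P1", "A", 0, 2, 50, False)])
        events = make_events(
            [
                ("P1", "A", "albumin", 2, 3.1),
                ("P1", "A", "albumin", 10, 2.4),
                ("P1", "A", "albumin", 20, 3.6),
            ]
        )
        out = extract_worst_first_day(events, stays, [ALB])
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "minimum"
        assert out.iloc[0]["value"] == 2.4

    def test_window_is_half_open(self):
        stays = make_stays([("P1", "A", 0, 3, 50, False)])
        events = make_events(
            [
                ("P1", "A", "probe", 0, 1.0),    # at intime: in
                ("P1", "A", "probe", 24, 99.0),  # at intime+24h: out
            ]
        )
        out = extract_worst_first_day(events, stays, [BOTH], window_hours=24)
        assert out.loc[out["direction"] == "maximum", "value"].item() == 1.0

    def test_subject_fallback_when_stay_id_absent(self):
        stays = make_stays([("P1", "A", 0, 2, 50, False)])
        events = make_events([("P1", None, "probe", 5, 4.5)])
        out = extract_worst_first_day(events, stays, [BOTH])
        assert set(out["stay_id"]) == {"A"}
        assert len(out) == 2

    def test_non_numeric_value_reports_row(self):
        stays = make_stays([("P1", "A", 0, 2, 50, False)])
        events = make_events([("P1", "A", "probe", 5, "oops")])
        with pytest.raises(InputDataError, match="row"):
            extract_worst_first_day(events, stays, [BOTH])

    def test_absent_panel_test_warns_not_fails(self):
        stays = make_stays([("P1", "A", 0, 2, 50, False)])
        events = make_events([("P1", "A", "probe", 5, 1.0)])
        with pytest.warns(UserWarning, match="albumin"):
            out = extract_worst_first_day(events, stays, [BOTH, ALB])
        assert set(out["test_id"]) == {"probe"}

    def test_invalid_window_rejected(self):
        stays = make_stays([("P1", "A", 0, 2, 50, False)])
        with pytest.raises(ConfigurationError):
            extract_worst_first_day(make_events([]), stays, [BOTH], window_hours=0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        panel = [ALB, BOTH]
        all_stays, events = random_extraction_fixture(seed, panel)
        first = select_first_stays(all_stays)
        got = extract_worst_first_day(events, first, panel)
        expected = brute_force_worst(events, first, panel)
        key = ["stay_id", "test_id", "direction"]
        got = got.sort_values(key).reset_index(drop=True)
        expected = expected.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)

    @given(st.integers(0, 2**20))
    def test_event_order_invariance(self, seed):
        panel = [BOTH]
        all_stays, events = random_extraction_fixture(seed, panel, n_stays=8,
                                                      n_events=40)
        first = select_first_stays(all_stays)
        a = extract_worst_first_day(events, first, panel)
        shuffled = events.sample(frac=1.0, random_state=7).reset_index(drop=True)
        b = extract_worst_first_day(shuffled, first, panel)
        key = ["stay_id", "test_id", "direction"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )


class TestAssignOutcomeGroups:
    def test_one_stay_per_group(self):
        stays = make_stays(
            [
                ("P1", "A", 0, 1, 50, False),
                ("P2", "B", 0, 2, 50, False),
                ("P3", "C", 0, 3, 50, False),
                ("P4", "D", 0, 4, 50, False),
                ("P5", "E", 0, 5, 50, True),
            ]
        )
        groups = assign_outcome_groups(stays)
        assert groups["A"] == "Q1_BEST"
        assert groups["B"] == "Q2"
        assert groups["C"] == "Q3"
        assert groups["D"] == "Q4"
        assert groups["E"] == "DIED_WORST"

    def test_printed_best_group_size_at_full_scale(self):
        """35 515 survivors under the ceil(4r/n) rule give a best group of
        exactly 8878."""
        n = 35_515
        q = survivor_quartiles(np.arange(n, dtype=float), np.arange(n))
        counts = np.bincount(q)[1:]
        assert counts[0] == 8878
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1

    def test_equal_los_tie_break_matches_rank_oracle(self):
        stays = make_stays(
            [(f"P{i}", f"S{i}", 0, 2.0, 50, False) for i in range(8)]
        )
        groups = assign_outcome_groups(stays)
        # ties broken by stay_id: S0,S1 -> Q1 ... S6,S7 -> Q4
        expected = ["Q1_BEST", "Q1_BEST", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
        assert groups[[f"S{i}" for i in range(8)]].tolist() == expected

    def test_quartile_sizes_differ_by_at_most_one(self, small_cohort):
        _, stays, _, _ = small_cohort
        first = select_first_stays(stays)
        groups = assign_outcome_groups(first)
        sizes = groups.value_counts()
        quartiles = sizes[["Q1_BEST", "Q2", "Q3", "Q4"]]
        assert quartiles.max() - quartiles.min() <= 1

    @given(st.integers(0, 2**20))
    def test_row_order_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        stays = make_stays(
            [
                (f"P{i}", f"S{i}", 0, float(rng.uniform(0.5, 9)), 50,
                 bool(rng.random() < 0.2))
                for i in range(25)
            ]
        )
        base = assign_outcome_groups(stays)
        perm = assign_outcome_groups(
            stays.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        pd.testing.assert_series_equal(base.sort_index(), perm.sort_index())

    def test_errors(self):
        with pytest.raises(InputDataError):
            assign_outcome_groups(make_stays([]))
        few = make_stays(
            [("P1", "A", 0, 1, 50, False), ("P2", "B", 0, 1, 50, True)]
        )
        with pytest.raises(InputDataError, match="survivor"):
            assign_outcome_groups(few)


class TestBuildCohortTable:
    def _fixture(self):
        stays = make_stays(
            [
                ("P1", "A", 0, 1, 50, False),
                ("P2", "B", 0, 2, 60, False),
                ("P3", "C", 0, 3, 70, False),
                ("P4", "D", 0, 4, 70, False),
                ("P5", "E", 0, 5, 80, True),
            ]
        )
        groups = assign_outcome_groups(stays)
        return stays, groups

    def test_empty_records_gives_covariate_only_table(self):
        stays, groups = self._fixture()
        empty = pd.DataFrame(columns=["stay_id", "test_id", "direction", "value"])
        table = build_cohort_table(stays, empty, groups)
        assert len(table) == 5
        assert "outcome_group" in table.columns
        assert not any(c.endswith(("_min", "_max")) for c in table.columns)

    def test_wide_columns_for_mixed_direction_panel(self):
        stays, groups = self._fixture()
        records = pd.DataFrame(
            {
                "stay_id": ["A", "A", "A", "B", "C"],
                "test_id": ["albumin", "probe", "probe", "albumin", "probe"],
                "direction": ["minimum", "minimum", "maximum", "minimum", "maximum"],
                "value": [3.0, 1.0, 9.0, 2.5, 8.0],
            }
        )
        table = build_cohort_table(stays, records, groups)
        assert {"albumin_min", "probe_min", "probe_max"} <= set(table.columns)
        t = table.set_index("stay_id")
        assert t.loc["A", "albumin_min"] == 3.0
        assert np.isnan(t.loc["C", "albumin_min"])  # missingness preserved

    def test_unknown_stay_rejected(self):
        stays, groups = self._fixture()
        records = pd.DataFrame(
            {"stay_id": ["ZZ"], "test_id": ["probe"],
             "direction": ["minimum"], "value": [1.0]}
        )
        with pytest.raises(InputDataError):
            build_cohort_table(stays, records, groups)

    def test_missingness_matches_generator_configuration(self, small_cohort):
        cfg, stays, events, truth = small_cohort
        first = select_first_stays(stays)
        groups = assign_outcome_groups(first)
        records = extract_worst_first_day(events, first, demo_panel())
        table = build_cohort_table(first, records, groups)
        n = len(table)
        for analyte in cfg.panel:
            spec = next(s for s in demo_panel() if s.test_id == analyte.test_id)
            col = worst_value_column(analyte.test_id, spec.directions[0])
            observed = table[col].notna().sum() / n
            expected = 1.0 - analyte.missingness
            tol = 3 * np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) <= tol
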