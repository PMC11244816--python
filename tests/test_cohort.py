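"""Cohort filtering, age-band assignment and quarterly aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoquad import (
    AgeGroupScheme,
    CauseSet,
    DeathRecord,
    InvalidRecordError,
    PostNeonatalDeath,
    Quarter,
    age_at_death_hours,
    assign_age_band,
    build_quarter_tables,
    filter_analyzable,
    read_cohort_csv,
    read_life_tables_csv,
    write_cohort_csv,
    write_life_tables_csv,
)
from conftest import BAND_COUNTS, COHORT_TOTAL, N_NO_TIME, N_NO_VA


def _rec(i, death_offset_h=10.0, has_time=True, has_va=True):
    birth = pd.Timestamp("2012-03-01T08:00")
    return DeathRecord(
        record_id=f"r{i}",
        birth_dt=birth,
        death_dt=birth + pd.Timedelta(hours=death_offset_h) if has_time else None,
        has_va=has_va,
        cause="preterm" if has_va else None,
    )


class TestFilterAnalyzable:
    def test_printed_cohort_composition(self, printed_cohort):
        records, _ = printed_cohort
        retained, tally = filter_analyzable(records)
        assert len(records) == COHORT_TOTAL
        assert len(retained) == 957
        assert tally == {"no_time": N_NO_TIME, "no_va": N_NO_VA}

    def test_empty_input(self):
        retained, tally = filter_analyzable([])
        assert retained == [] and tally == {"no_time": 0, "no_va": 0}

    def test_complete_records_pass_through(self):
        records = [_rec(i) for i in range(10)]
        retained, tally = filter_analyzable(records)
        assert retained == records
        assert sum(tally.values()) == 0

    def test_missing_both_counts_under_no_time(self):
        records = [_rec(0, has_time=False, has_va=False)]
        retained, tally = filter_analyzable(records)
        assert retained == []
        assert tally == {"no_time": 1, "no_va": 0}

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()),
            max_size=60,
        )
    )
    @settings(deadline=None)
    def test_conservation(self, flags):
        records = [
            _rec(i, has_time=ht, has_va=hv) for i, (ht, hv) in enumerate(flags)
        ]
        retained, tally = filter_analyzable(records)
        assert len(retained) + sum(tally.values()) == len(records)


class TestAgeAtDeath:
    @pytest.mark.parametrize(
        "birth, death, expected",
        [
            ("2012-01-01T00:00", "2012-01-01T10:30", 10),
            ("2012-01-01T00:00", "2012-01-01T00:00", 0),
            ("2012-01-01T23:00", "2012-01-03T01:00", 26),
            ("2012-01-01T06:15", "2012-01-01T07:14", 0),
        ],
    )
    def test_completed_hours_floor(self, birth, death, expected):
        assert age_at_death_hours(pd.Timestamp(birth), pd.Timestamp(death)) == expected

    def test_death_before_birth_rejected(self):
        with pytest.raises(InvalidRecordError):
            age_at_death_hours(
                pd.Timestamp("2012-01-02"), pd.Timestamp("2012-01-01")
            )


class TestAssignAgeBand:
    @pytest.mark.parametrize(
        "age_hours, band",
        [(0, 0), (23, 0), (24, 1), (47, 1), (48, 2), (167, 2), (168, 3), (671, 3), (672, 3)],
    )
    def test_half_open_bands_closed_at_672(self, age_hours, band, scheme):
        assert assign_age_band(age_hours, scheme) == band

    def test_post_neonatal_signalled(self, scheme):
        with pytest.raises(PostNeonatalDeath):
            assign_age_band(673, scheme)

    def test_negative_age_rejected(self, scheme):
        with pytest.raises(InvalidRecordError):
            assign_age_band(-1, scheme)


class TestBuildQuarterTables:
    def test_study_range_yields_25_tables(self, printed_cohort):
        records, tallies = printed_cohort
        retained, _ = filter_analyzable(records)
        tables, tally = build_quarter_tables(retained, tallies)
        assert len(tables) == 25
        assert tables[0].quarter == Quarter(2010, 4)
        assert tables[-1].quarter == Quarter(2016, 4)
        assert tally == {"post_neonatal": 0, "out_of_range": 0}
        assert sum(int(t.deaths.sum()) for t in tables) == 957

    def test_age_band_shares_match_printed_percentages(self, printed_cohort):
        records, tallies = printed_cohort
        retained, _ = filter_analyzable(records)
        tables, _ = build_quarter_tables(retained, tallies)
        band_totals = sum(t.deaths.sum(axis=1) for t in tables)
        assert tuple(int(n) for n in band_totals) == BAND_COUNTS
        shares = [round(100 * n / 957) for n in band_totals]
        assert shares == [41, 15, 25, 19]

    def test_zero_death_quarter_emitted(self):
        tables, _ = build_quarter_tables([], {Quarter(2013, 1): 1000})
        (t,) = tables
        assert t.nmr == 0.0
        assert np.all(t.cum_q == 0.0)

    def test_cumulative_arithmetic(self, scheme):
        causes = CauseSet()
        q = Quarter(2013, 1)
        records = []
        i = 0
        for band, n in enumerate((5, 3, 0, 2)):
            lower = ((0,) + scheme.bounds[:-1])[band]
            for _ in range(n):
                birth = q.start + pd.Timedelta(hours=i)
                records.append(
                    DeathRecord(
                        f"d{i}", birth, birth + pd.Timedelta(hours=lower + 0.5),
                        True, "asphyxia",
                    )
                )
                i += 1
        tables, _ = build_quarter_tables(records, {q: 1000}, scheme, causes)
        got = tables[0].cause_q("asphyxia")
        assert np.allclose(got, (0.005, 0.008, 0.008, 0.010), atol=1e-15)

    def test_zero_births_rejected(self):
        with pytest.raises(ValueError, match="live_births"):
            build_quarter_tables([], {Quarter(2013, 1): 0})

    def test_unknown_cause_pools_into_other(self, scheme):
        q = Quarter(2013, 1)
        birth = q.start
        rec = DeathRecord("x", birth, birth + pd.Timedelta(hours=3), True, "tetanus")
        tables, _ = build_quarter_tables([rec], {q: 100}, scheme)
        assert tables[0].cause_nmr("other") == pytest.approx(0.01)

    def test_post_neonatal_tallied_not_dropped(self, scheme):
        q = Quarter(2013, 1)
        birth = q.start
        rec = DeathRecord("x", birth, birth + pd.Timedelta(hours=700), True, "sepsis")
        tables, tally = build_quarter_tables([rec], {q: 100}, scheme)
        assert tally["post_neonatal"] == 1
        assert tables[0].nmr == 0.0


class TestTableInvariants:
    def test_cum_q_monotone_and_envelope(self, seeded_tables):
        for t in seeded_tables:
            assert np.all(np.diff(t.cum_q, axis=0) >= 0.0)
            assert np.all(t.cum_q[-1] <= t.nmr + 1e-15)
            assert abs(t.cum_q[-1].sum() - t.nmr) < 1e-12

    def test_life_table_csv_roundtrip(self, seeded_tables, tmp_path):
        path = tmp_path / "tables.csv"
        write_life_tables_csv(seeded_tables, path)
        back = read_life_tables_csv(path)
        assert len(back) == len(seeded_tables)
        for a, b in zip(seeded_tables, back):
            assert a.quarter == b.quarter
            assert a.live_births == b.live_births
            assert a.causes == b.causes
            np.testing.assert_allclose(a.cum_q, b.cum_q, rtol=0, atol=1e-12)
            assert abs(a.nmr - b.nmr) <= 1e-12


class TestCohortCSV:
    def test_roundtrip(self, printed_cohort, tmp_path):
        records, _ = printed_cohort
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        back = read_cohort_csv(path)
        assert back == records

    def test_malformed_datetime_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "record_id,birth_datetime,death_datetime,has_va,cause\n"
            "r7,not-a-date,,1,preterm\n"
        )
        with pytest.raises(ValueError, match="r7"):
            read_cohort_csv(path)

    def test_unknown_cause_code_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "record_id,birth_datetime,death_datetime,has_va,cause\n"
            "r9,2012-01-01T00:00,2012-01-01T05:00,1,maleria\n"
        )
        with pytest.raises(ValueError, match="r9"):
            read_cohort_csv(path)

    def test_cause_without_va_rejected(self):
        with pytest.raises(InvalidRecordError):
            DeathRecord(
                "x", pd.Timestamp("2012-01-01"), None, has_va=False, cause="sepsis"
            )
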