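import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perinet.records import (
    FilterReport,
    characteristics_table,
    classify_rurality,
    filter_network_transports,
    rurality_of_records,
)

from conftest import make_records


class TestClassifyRurality:
    @pytest.mark.parametrize(
        "rucc,expected",
        [(1, "urban"), (2, "urban"), (3, "urban"),
         (4, "suburban"), (5, "suburban"), (6, "suburban"),
         (7, "rural"), (8, "rural"), (9, "rural")],
    )
    def test_partitions_codes(self, rucc, expected):
        assert classify_rurality(rucc) == expected

    @pytest.mark.parametrize("bad", [0, 10, -3])
    def test_out_of_range_raises_naming_value(self, bad):
        with pytest.raises(ValueError, match=str(bad)):
            classify_rurality(bad)


class TestFilter:
    def test_no_transports(self, toy_facilities):
        records = make_records([{} for _ in range(10)])
        retained, report = filter_network_transports(records, toy_facilities)
        assert retained.empty
        assert report.n_transported == 0 and report.n_retained == 0
        assert report.n_input == 10

    def test_cascade_counts(self, toy_facilities):
        records = make_records(
            [
                {"transported": True, "origin_facility": "A1",
                 "destination_facility": "A3"},
                {"transported": True, "origin_facility": "B1",
                 "destination_facility": "B2"},
                {"transported": True, "origin_facility": "A2",
                 "destination_facility": "A3"},
                # missing origin
                {"transported": True, "origin_facility": pd.NA,
                 "destination_facility": "A3"},
                # non-obstetric destination
                {"transported": True, "origin_facility": "A1",
                 "destination_facility": "X1"},
                {},  # not transported
            ]
        )
        retained, report = filter_network_transports(records, toy_facilities)
        assert report.n_transported == 5
        assert report.n_dropped_missing_endpoint == 1
        assert report.n_dropped_non_obstetric == 1
        assert report.n_retained == 3
        assert list(retained["record_id"]) == ["D0001", "D0002", "D0003"]

    def test_unrostered_id_counts_as_non_obstetric(self, toy_facilities):
        records = make_records(
            [{"transported": True, "origin_facility": "ZZZ",
              "destination_facility": "A3"}]
        )
        _, report = filter_network_transports(records, toy_facilities)
        assert report.n_dropped_non_obstetric == 1

    def test_idempotent(self, toy_facilities):
        records = make_records(
            [
                {"transported": True, "origin_facility": "A1",
                 "destination_facility": "A3"},
                {"transported": True, "origin_facility": pd.NA,
                 "destination_facility": "A3"},
                {},
            ]
        )
        once, r1 = filter_network_transports(records, toy_facilities)
        twice, r2 = filter_network_transports(once, toy_facilities)
        pd.testing.assert_frame_equal(once, twice)
        assert r2.n_retained == r1.n_retained
        assert r2.n_dropped_missing_endpoint == 0

    @given(
        n_clean=st.integers(0, 30),
        n_missing=st.integers(0, 10),
        n_nonob=st.integers(0, 10),
        n_plain=st.integers(0, 20),
    )
    @settings(max_examples=40, deadline=None)
    def test_report_identity_property(self, n_clean, n_missing, n_nonob,
                                      n_plain):
        """The cascade counts reconcile for arbitrary record mixes."""
        toy_facilities = pd.DataFrame(
            {
                "facility_id": ["A1", "A3", "X1"],
                "name": ["a", "b", "c"],
                "level": ["I", "RPC", "I"],
                "system": ["S1", "S2", "S3"],
                "dpr": ["RA", "RA", "RA"],
                "is_obstetric": [True, True, False],
            }
        )
        rows = (
            [{"transported": True, "origin_facility": "A1",
              "destination_facility": "A3"}] * n_clean
            + [{"transported": True, "origin_facility": pd.NA,
                "destination_facility": "A3"}] * n_missing
            + [{"transported": True, "origin_facility": "A1",
                "destination_facility": "X1"}] * n_nonob
            + [{}] * n_plain
        )
        if not rows:
            return
        records = make_records(rows)
        _, report = filter_network_transports(records, toy_facilities)
        assert (
            report.n_retained
            == report.n_transported
            - report.n_dropped_missing_endpoint
            - report.n_dropped_non_obstetric
        )
        assert report.n_retained == n_clean
        assert report.n_input == len(rows)

    def test_inconsistent_report_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FilterReport(10, 5, 1, 1, 4)


class TestCharacteristicsTable:
    def test_column_sums_equal_stratum_sizes(self):
        records = make_records(
            [
                {"transported": True, "race": "BlackAfricanAmerican"},
                {"transported": True},
                {"race": "Asian"},
                {},
            ]
        )
        table = characteristics_table(records, covariates=("race", "payor"))
        for cov in ("race", "payor"):
            sub = table[table["covariate"] == cov]
            sums = sub.groupby("stratum")["count"].sum()
            assert sums["transport"] == 2
            assert sums["non_transport"] == 2
            pct = sub.groupby("stratum")["pct"].sum()
            assert np.allclose(pct, 100.0)

    def test_all_unknown_race_is_own_level(self):
        records = make_records([{"race": "Unknown"}, {"race": "Unknown"}])
        table = characteristics_table(records, covariates=("race",))
        row = table[(table["level"] == "Unknown")
                    & (table["stratum"] == "non_transport")]
        assert row["pct"].iloc[0] == 100.0

    def test_published_rural_row_recovered(self, toy_counties):
        """A fixture with the published rural cell counts reproduces them."""
        # 30514 rural non-transport, 431 rural transport, scaled down 1:1000
        rows = (
            [{"county_of_residence": "C3"}] * 31
            + [{"county_of_residence": "C3", "transported": True,
                "origin_facility": "A1", "destination_facility": "A3"}] * 4
        )
        records = make_records(rows)
        records["rurality"] = rurality_of_records(records, toy_counties)
        table = characteristics_table(records, covariates=("rurality",))
        rural = table[table["level"] == "rural"].set_index("stratum")["count"]
        assert rural["non_transport"] == 31 and rural["transport"] == 4

    def test_unseen_covariate_errors(self):
        records = make_records([{}])
        with pytest.raises(KeyError):
            characteristics_table(records, covariates=("nonexistent",))


def test_rurality_of_records_unknown_county(toy_counties):
    records = make_records(
        [{"county_of_residence": "C1"}, {"county_of_residence": "Unknown"},
         {"county_of_residence": "C9"}]
    )
    out = rurality_of_records(records, toy_counties)
    assert list(out) == ["urban", "Unknown", "Unknown"]
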