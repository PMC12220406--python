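import math

import numpy as np
import pandas as pd
import pytest

from perinet.association import (
    TwoByTwo,
    build_design,
    collapse_sparse_levels,
    fit_logistic,
    label_inter_region,
    odds_ratio,
    univariate_or_table,
)
from perinet.reference import (
    GEORGIA_PUBLISHED_OR,
    GEORGIA_RURAL_CI,
    GEORGIA_TWO_BY_TWO,
)

from conftest import make_records


class TestOddsRatio:
    @pytest.mark.parametrize("contrast", sorted(GEORGIA_TWO_BY_TWO))
    def test_published_statewide_contrasts(self, contrast):
        """Each published unadjusted OR recomputes from its cell counts."""
        res = odds_ratio(GEORGIA_TWO_BY_TWO[contrast])
        assert round(res.or_, 3) == GEORGIA_PUBLISHED_OR[contrast]

    def test_rural_woolf_interval_matches_published(self):
        res = odds_ratio(GEORGIA_TWO_BY_TWO["rural_vs_urban"])
        assert res.ci_low == pytest.approx(GEORGIA_RURAL_CI[0], abs=0.005)
        assert res.ci_high == pytest.approx(GEORGIA_RURAL_CI[1], abs=0.005)

    def test_symmetric_table_or_one(self):
        res = odds_ratio(TwoByTwo(50, 50, 50, 50))
        assert res.or_ == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high

    def test_reciprocal_identity(self):
        t = TwoByTwo(12, 34, 56, 78)
        swapped = TwoByTwo(56, 78, 12, 34)
        assert odds_ratio(t).or_ * odds_ratio(swapped).or_ == pytest.approx(1.0)

    def test_scaling_cells_preserves_or_and_narrows_ci(self):
        t1 = odds_ratio(TwoByTwo(10, 20, 30, 40))
        t4 = odds_ratio(TwoByTwo(40, 80, 120, 160))
        assert t4.or_ == pytest.approx(t1.or_)
        width1 = math.log(t1.ci_high) - math.log(t1.ci_low)
        width4 = math.log(t4.ci_high) - math.log(t4.ci_low)
        assert width4 == pytest.approx(width1 / 2)

    def test_zero_cell_reported_literally(self):
        res = odds_ratio(TwoByTwo(0, 10, 5, 20))
        assert res.or_ == 0.0 and res.degenerate
        assert res.ci_low == 0.0 and res.ci_high == math.inf
        res_inf = odds_ratio(TwoByTwo(5, 0, 5, 20))
        assert res_inf.or_ == math.inf and res_inf.degenerate

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(TwoByTwo(0, 0, 0, 0))


class TestUnivariateTable:
    def test_payor_fixture_reproduces_published_medicaid_or(self):
        rows = []
        # scaled 1:1000 from published payor x transport counts
        for level, n0, n1 in [("Commercial", 311, 1), ("Medicaid", 354, 2),
                              ("TRICARE", 30, 1)]:
            rows += [{"payor": level}] * n0
            rows += [{"payor": level, "transported": True,
                      "origin_facility": "A1",
                      "destination_facility": "A3"}] * n1
        table = univariate_or_table(make_records(rows), "payor", "Commercial")
        med = table.set_index("level").loc["Medicaid"]
        expected = odds_ratio(TwoByTwo(2, 354, 1, 311)).or_
        assert med["or"] == pytest.approx(expected)

    def test_full_scale_medicaid_value(self):
        t = GEORGIA_TWO_BY_TWO["medicaid_vs_commercial"]
        assert round(odds_ratio(t).or_, 3) == 2.412

    def test_constant_covariate_warns_empty(self):
        records = make_records([{}] * 5)
        with pytest.warns(UserWarning, match="constant"):
            table = univariate_or_table(records, "payor", "Commercial")
        assert table.empty

    def test_missing_reference_errors(self):
        records = make_records([{"payor": "Medicaid"}] * 5)
        with pytest.raises(ValueError, match="Commercial"):
            univariate_or_table(records, "payor", "Commercial")


class TestLabelInterRegion:
    def test_flags(self, toy_facilities):
        records = make_records(
            [
                {"transported": True, "origin_facility": "A1",
                 "destination_facility": "A2"},       # intra, same system
                {"transported": True, "origin_facility": "A2",
                 "destination_facility": "B2"},       # cross, diff system
                {"transported": True, "origin_facility": "A3",
                 "destination_facility": "B1"},       # cross, same system
            ]
        )
        out = label_inter_region(records, toy_facilities)
        assert list(out["inter_region"]) == [False, True, True]
        assert list(out["same_system"]) == [True, False, True]

    def test_unrostered_endpoint_errors(self, toy_facilities):
        records = make_records(
            [{"transported": True, "origin_facility": "ZZ",
              "destination_facility": "A1"}]
        )
        with pytest.raises(KeyError, match="ZZ"):
            label_inter_region(records, toy_facilities)

    def test_counts_reconcile_with_network_split(self, toy_facilities):
        from perinet.network import build_network, inter_region_metrics

        records = make_records(
            [{"transported": True, "origin_facility": "A1",
              "destination_facility": "B1"}] * 3
            + [{"transported": True, "origin_facility": "A1",
                "destination_facility": "A2"}] * 7
        )
        out = label_inter_region(records, toy_facilities)
        net = build_network(records, toy_facilities)
        rep = inter_region_metrics(net, {"RA": ["RB"], "RB": ["RA"]})
        assert int(out["inter_region"].sum()) == rep.inter_volume
        assert int((~out["inter_region"]).sum()) == rep.intra_volume


class TestLogisticFit:
    def test_binary_covariate_equals_closed_form(self):
        df = pd.DataFrame(
            {
                "x": ["Yes"] * 100 + ["No"] * 900,
                "y": [True] * 30 + [False] * 70 + [True] * 90 + [False] * 810,
            }
        )
        fit = fit_logistic(df, [("x", "No")], outcome="y")
        closed = math.log((30 * 810) / (70 * 90))
        assert fit.coefficients["x[Yes]"] == pytest.approx(closed, abs=1e-6)
        assert fit.converged
        # Wald SE equals the Woolf SE for the saturated 2x2 model
        woolf_se = math.sqrt(1 / 30 + 1 / 70 + 1 / 90 + 1 / 810)
        assert fit.standard_errors["x[Yes]"] == pytest.approx(woolf_se,
                                                              abs=1e-6)

    def test_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        n = 5000
        df = pd.DataFrame(
            {
                "a": rng.choice(["u", "v", "w"], size=n),
                "b": rng.choice(["Yes", "No"], size=n),
            }
        )
        lp = -1.0 + 0.8 * (df["a"] == "v") - 0.5 * (df["b"] == "Yes")
        df["y"] = rng.random(n) < 1 / (1 + np.exp(-lp))
        fit = fit_logistic(df, [("a", "u"), ("b", "No")], outcome="y")
        X, names = build_design(df, [("a", "u"), ("b", "No")])
        ref = statsmodels.GLM(
            df["y"].astype(float), X,
            family=statsmodels.families.Binomial(),
        ).fit()
        ours = np.array([fit.coefficients[nm] for nm in names])
        assert np.allclose(ours, ref.params, atol=1e-8)
        ses = np.array([fit.standard_errors[nm] for nm in names])
        assert np.allclose(ses, ref.bse, atol=1e-6)

    def test_quasi_separation_flagged(self):
        df = pd.DataFrame(
            {
                "x": ["Yes"] * 20 + ["No"] * 20,
                "y": [True] * 20 + [False] * 20,
            }
        )
        fit = fit_logistic(df, [("x", "No")], outcome="y")
        assert fit.separation and not fit.converged

    def test_rank_deficient_design_names_aliased_terms(self):
        df = pd.DataFrame(
            {
                "x": ["Yes", "No"] * 20,
                "x2": ["Yes", "No"] * 20,  # perfect alias of x
                "y": [True, False] * 20,
            }
        )
        with pytest.raises(ValueError, match="aliased"):
            fit_logistic(df, [("x", "No"), ("x2", "No")], outcome="y")


def test_collapse_sparse_levels_pools_rare_categories():
    df = pd.DataFrame({"race": ["White"] * 50 + ["Asian"] * 3 + ["NHPI"] * 2})
    out = collapse_sparse_levels(df, "race", min_count=20, keep=("White",))
    assert set(out["race"]) == {"White", "Other"}
    assert (out["race"] == "Other").sum() == 5
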