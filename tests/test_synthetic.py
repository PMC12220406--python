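import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from perinet.association import TwoByTwo, odds_ratio
from perinet.community import detect_communities
from perinet.concordance import adjusted_rand
from perinet.records import rurality_of_records
from perinet.synthetic import (
    ConfigurationError,
    GeneratorConfig,
    calibrate_intercept,
    generate_counties,
    generate_facilities,
    generate_registry,
    plant_partition_network,
)


def small_config(**kwargs) -> GeneratorConfig:
    base = dict(n_regions=2, facilities_per_region=4, n_systems=3,
                n_counties=8, n_deliveries=2000, seed=5)
    base.update(kwargs)
    return GeneratorConfig(**base)


class TestFacilities:
    def test_every_region_has_rpc(self):
        config = GeneratorConfig(n_regions=6, seed=1)
        fac = generate_facilities(config)
        obstetric = fac[fac["is_obstetric"]]
        for region in config.region_ids:
            levels = set(obstetric.loc[obstetric["dpr"] == region, "level"])
            assert "RPC" in levels, region

    def test_unique_ids_and_determinism(self):
        config = small_config()
        fac1 = generate_facilities(config)
        fac2 = generate_facilities(small_config())
        assert fac1["facility_id"].is_unique
        pd.testing.assert_frame_equal(fac1, fac2)

    def test_forced_rpc_count(self):
        config = small_config(
            facilities_per_region=3,
            level_mix={"BirthCenter": 0.0, "I": 0.5, "II": 0.4, "III": 0.0,
                       "RPC": 0.1},
        )
        fac = generate_facilities(config)
        obstetric = fac[fac["is_obstetric"]]
        assert len(obstetric) == 6
        rpc = obstetric[obstetric["level"] == "RPC"]
        assert len(rpc) >= 2 and set(rpc["dpr"]) == {"R1", "R2"}

    def test_zero_rpc_mix_rejected_naming_region(self):
        config = small_config(
            level_mix={"BirthCenter": 0.1, "I": 0.5, "II": 0.3, "III": 0.1,
                       "RPC": 0.0}
        )
        with pytest.raises(ConfigurationError, match="R1"):
            generate_facilities(config)


class TestCounties:
    def test_every_region_nonempty(self):
        config = GeneratorConfig(n_counties=159, n_regions=6, seed=2)
        counties = generate_counties(config)
        assert set(counties["dpr"]) == set(config.region_ids)
        assert counties["county_id"].is_unique
        assert counties["rucc"].between(1, 9).all()

    def test_point_mass_rucc_all_urban(self):
        config = small_config(
            rucc_distribution=(1.0, 0, 0, 0, 0, 0, 0, 0, 0)
        )
        counties = generate_counties(config)
        assert (counties["rucc"] == 1).all()

    def test_determinism(self):
        c1 = generate_counties(small_config())
        c2 = generate_counties(small_config())
        pd.testing.assert_frame_equal(c1, c2)

    def test_fewer_counties_than_regions_rejected(self):
        with pytest.raises(ConfigurationError, match="n_counties"):
            generate_counties(small_config(n_counties=1, n_regions=2))


class TestDeliveries:
    def test_extreme_negative_intercept_yields_no_transports(self):
        config = small_config(transport_intercept=-40.0)
        fac, cty, dlv, _ = generate_registry(config)
        assert not dlv["transported"].any()
        assert dlv["origin_facility"].isna().all()
        assert dlv["destination_facility"].notna().all()

    def test_determinism(self):
        _, _, d1, _ = generate_registry(small_config())
        _, _, d2, _ = generate_registry(small_config())
        pd.testing.assert_frame_equal(d1, d2)

    def test_marginal_calibration_null_effects(self):
        """With all effects zero, prevalence matches logistic(intercept)
        within 3 Monte-Carlo standard errors at n=200,000."""
        effects = {c: {} for c in
                   ("rurality", "payor", "preterm", "plurality", "tobacco",
                    "n_medical_risk_factors")}
        config = GeneratorConfig(
            n_deliveries=200_000, transport_intercept=math.log(0.005 / 0.995),
            covariate_effects=effects, seed=11,
        )
        fac, cty, dlv, _ = generate_registry(config)
        p = expit(config.transport_intercept)
        phat = dlv["transported"].mean()
        se = math.sqrt(p * (1 - p) / len(dlv))
        assert abs(phat - p) < 3 * se

    def test_calibrated_intercept_hits_target_prevalence(self):
        config = GeneratorConfig(n_deliveries=200_000, seed=13)
        _, _, dlv, _ = generate_registry(config)
        phat = dlv["transported"].mean()
        # binomial error on ~0.42%
        se = math.sqrt(0.0042 * (1 - 0.0042) / len(dlv))
        assert abs(phat - 0.0042) < 4 * se

    def test_intra_affinity_one_keeps_all_transports_in_region(self):
        config = small_config(intra_region_affinity=1.0, n_deliveries=20_000,
                              transport_intercept=-3.0, endpoint_dropout=0.0,
                              p_unknown_county=0.0)
        fac, cty, dlv, _ = generate_registry(config)
        region = fac.set_index("facility_id")["dpr"]
        moved = dlv[dlv["transported"]]
        assert len(moved) > 100
        assert (
            moved["origin_facility"].map(region)
            == moved["destination_facility"].map(region)
        ).all()

    def test_upward_fraction_within_binomial_error(self):
        # default-size roster: small regions can lack a same-or-lower
        # destination for non-upward draws, which the fallback counter tracks
        config = GeneratorConfig(n_deliveries=100_000, transport_intercept=-3.0,
                                 endpoint_dropout=0.0, upward_fraction=0.95,
                                 seed=5)
        fac, _, dlv, truth = generate_registry(config)
        rank = fac.set_index("facility_id")["level"].map(
            {"BirthCenter": 0, "I": 1, "II": 2, "III": 3, "RPC": 4}
        )
        moved = dlv[dlv["transported"]]
        up = (
            moved["destination_facility"].map(rank).to_numpy()
            > moved["origin_facility"].map(rank).to_numpy()
        )
        n = len(moved)
        se = math.sqrt(0.95 * 0.05 / n)
        assert truth.n_destination_fallbacks <= 0.01 * n
        assert abs(up.mean() - 0.95) < 4 * se

    def test_rural_effect_recovered_as_unadjusted_or(self):
        """Planted rural log-OR is recovered as the empirical rural-vs-urban
        unadjusted OR at large n (rare outcome, independent covariates)."""
        effects = {
            "rurality": {"rural": math.log(5.65)},
            "payor": {}, "preterm": {}, "plurality": {}, "tobacco": {},
            "n_medical_risk_factors": {},
        }
        config = GeneratorConfig(n_deliveries=500_000, covariate_effects=effects,
                                 p_unknown_county=0.0, seed=17)
        fac, cty, dlv, truth = generate_registry(config)
        dlv = dlv.copy()
        dlv["rurality"] = rurality_of_records(dlv, cty)
        tab = pd.crosstab(dlv["rurality"] == "rural", dlv["transported"])
        res = odds_ratio(
            TwoByTwo(
                a=int(tab.loc[True, True]), b=int(tab.loc[True, False]),
                c=int(tab.loc[False, True]), d=int(tab.loc[False, False]),
            )
        )
        assert truth.true_covariate_effects["rurality"]["rural"] == math.log(5.65)
        assert abs(math.log(res.or_) - math.log(5.65)) < 0.25

    def test_ground_truth_mirrors_config(self):
        config = small_config()
        fac, cty, dlv, truth = generate_registry(config)
        assert set(truth.true_covariate_effects) == set(config.covariate_effects)
        assert truth.true_intra_region_affinity == config.intra_region_affinity
        assert set(truth.true_region_of_facility) == set(fac["facility_id"])


class TestPlantedPartition:
    def test_p_out_zero_gives_disjoint_recoverable_communities(self):
        net, planted = plant_partition_network(3, 6, 0.9, 0.0, seed=4)
        regions = {planted.assignment[n] for n in net.graph.nodes}
        for u, v in net.graph.edges:
            assert planted.assignment[u] == planted.assignment[v]
        assert regions == {0, 1, 2}
        detected = detect_communities(net)
        assert adjusted_rand(detected, planted) == 1.0

    def test_determinism(self):
        n1, _ = plant_partition_network(4, 8, 0.5, 0.05, seed=9)
        n2, _ = plant_partition_network(4, 8, 0.5, 0.05, seed=9)
        assert n1.edges == n2.edges

    def test_unidentifiable_benchmark_rejected(self):
        with pytest.raises(ValueError, match="p_in > p_out"):
            plant_partition_network(3, 6, 0.2, 0.2)

    def test_weight_law_poisson(self):
        net, _ = plant_partition_network(
            2, 10, 0.8, 0.05, weight_law={"kind": "poisson", "lam": 3.0},
            seed=2,
        )
        weights = np.array(list(net.edges.values()))
        assert (weights >= 1).all() and weights.max() > 1


def test_calibrate_intercept_closed_form_null_case():
    # with no effects the expected prevalence is exactly logistic(b0)
    b0 = calibrate_intercept(0.01, {"preterm": {}}, 0.0)
    assert abs(expit(b0) - 0.01) < 1e-10
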