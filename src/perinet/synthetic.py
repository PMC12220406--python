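"""Synthetic delivery-registry generator.

Real statewide birth records are restricted, so this module generates
facility rosters, county rosters, and record-level delivery tables with the
statistical structure the downstream analysis assumes, alongside the ground
truth needed for recovery tests:

* a five-tier facility hierarchy (Birth Center, Level I, II, III, RPC) with
  at least one regional perinatal center per designated region;
* counties carrying Rural-Urban Continuum Codes, with birth volume
  concentrated in urban counties;
* a logistic transport model over record covariates (rurality, payor,
  preterm birth, plurality, tobacco use, medical-risk count by default),
  with the intercept calibrated exactly so the expected transport prevalence
  matches a target (~0.42% in the statewide preset);
* destination choice by a two-stage categorical draw: a region gate (stay in
  the origin's region with probability ``intra_region_affinity``, otherwise
  move to an adjacent region with a small leak to non-neighbors), then a
  weighted pick among candidate facilities favoring the same health system
  and, for upward transports, the regional perinatal center.

Draws for facilities, counties and deliveries come from separate streams
split off the master seed, so enlarging one roster does not perturb the
others.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .community import Partition, _canonicalize
from .network import TransportNetwork
from .records import DELIVERY_COLUMNS, LEVEL_RANK, LEVELS

logger = logging.getLogger(__name__)

# Statewide marginal level counts used as sampling weights for covariates
# (total-column counts of a published 774,639-delivery cohort, Georgia
# 2017-2022).  Normalized at use; categorical codes are strings.
COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "race": {
        "AmericanIndianAlaskaNative": 1045,
        "Asian": 35909,
        "BlackAfricanAmerican": 277418,
        "Multiracial": 19772,
        "NativeHawaiianPacificIslander": 1492,
        "White": 439003,
        "Unknown": 5121,
    },
    "ethnicity": {"Hispanic": 114314, "NonHispanic": 655204, "Unknown": 5121},
    "education": {
        "LessThan9thGrade": 24378,
        "Grade9to11": 68786,
        "HighSchoolOrGED": 245291,
        "SomeCollegeOrHigher": 432938,
        "Unknown": 3246,
    },
    "payor": {
        "Commercial": 311793,
        "Medicaid": 356020,
        "OtherInsurance": 25650,
        "SelfPay": 49412,
        "TRICARE": 30659,
        "Unknown": 1105,
    },
    "apncu": {
        "Inadequate": 126895,
        "Intermediate": 51261,
        "Adequate": 246320,
        "AdequatePlus": 304279,
        "Unknown": 45884,
    },
    "tobacco": {"Yes": 30424, "No": 740635, "Unknown": 3580},
    "n_medical_risk_factors": {"0": 555791, "1": 177117, "2+": 39821, "Unknown": 1910},
    "preterm": {"Yes": 90389, "No": 684216, "Unknown": 34},
    "plurality": {"1": 747534, "2+": 27105},
    "fetal_presentation": {
        "Breech": 29944,
        "Cephalic": 737020,
        "Other": 6039,
        "Unknown": 1636,
    },
    "delivery_method": {"Cesarean": 266700, "Vaginal": 507331, "Unknown": 608},
    "infant_transfer": {"Yes": 6307, "No": 767315, "Unknown": 1017},
    "nicu_abnormal": {"Yes": 74211, "No": 700427, "Unknown": 1},
    # not tabulated in the published cohort; plausible statewide shares
    "wic": {"Yes": 0.40, "No": 0.60},
    "steroid_lung_maturation": {"Yes": 0.03, "No": 0.97},
    "maternal_transfusion": {"Yes": 0.003, "No": 0.997},
}

#: Births-by-rurality marginal (known-county deliveries of the same cohort).
RURALITY_BIRTH_COUNTS = {"urban": 631039, "suburban": 91221, "rural": 30945}

#: Default log odds-ratio effects on transport, matching the published
#: unadjusted OR structure (rare outcome, so marginal ~ conditional).
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "rurality": {
        "suburban": math.log(5.145),
        "rural": math.log(5.652),
        "Unknown": math.log(2.310),
    },
    "payor": {
        "Medicaid": math.log(2.412),
        "OtherInsurance": math.log(2.014),
        "SelfPay": math.log(1.052),
        "TRICARE": math.log(3.801),
    },
    "preterm": {"Yes": math.log(26.057)},
    "plurality": {"2+": math.log(5.050)},
    "tobacco": {"Yes": math.log(2.663)},
    "n_medical_risk_factors": {"1": math.log(2.218), "2+": math.log(4.918)},
}

_REQUIRED_EFFECT_COVARIATES = (
    "rurality",
    "payor",
    "preterm",
    "plurality",
    "tobacco",
    "n_medical_risk_factors",
)

DEFAULT_LEVEL_MIX = {"BirthCenter": 0.05, "I": 0.40, "II": 0.30, "III": 0.17,
                     "RPC": 0.08}

# Georgia's 159 counties skew rural in count even though births skew urban.
DEFAULT_RUCC_DISTRIBUTION = (0.20, 0.14, 0.12, 0.09, 0.09, 0.08, 0.11, 0.10, 0.07)


def ring_adjacency(region_ids: Sequence[str]) -> dict[str, list[str]]:
    """Symmetric ring adjacency over regions (each touches two neighbors)."""
    n = len(region_ids)
    if n == 1:
        return {region_ids[0]: []}
    return {
        region_ids[i]: sorted({region_ids[(i - 1) % n], region_ids[(i + 1) % n]})
        for i in range(n)
    }


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic registry.

    Defaults mirror the published statewide cohort: ~0.42% transport
    prevalence, ~17% inter-region transport share (``intra_region_affinity``
    0.83), 95% upward transports, a same-health-system destination
    preference, and a 16% endpoint-dropout share so the network-eligible
    fraction lands near 0.36%.
    """

    n_regions: int = 6
    facilities_per_region: int | Sequence[int] = 13
    level_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_MIX)
    )
    n_systems: int = 12
    system_span_regions: float = 0.3
    n_counties: int = 159
    rucc_distribution: Sequence[float] = DEFAULT_RUCC_DISTRIBUTION
    n_deliveries: int = 80_000
    transport_intercept: float | None = None  # None -> calibrate to target
    target_prevalence: float = 0.0042
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COVARIATE_EFFECTS.items()}
    )
    intra_region_affinity: float = 0.83
    same_system_affinity: float = 3.0
    rpc_preference: float = 20.0
    upward_fraction: float = 0.95
    endpoint_dropout: float = 0.16
    n_nonobstetric_facilities: int = 3
    nonneighbor_leak: float = 0.03
    p_unknown_county: float = 21434 / 774639
    region_adjacency: Mapping[str, Sequence[str]] | None = None
    covariate_marginals: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_systems", "n_counties", "n_deliveries"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if abs(sum(self.level_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("level_mix proportions must sum to 1")
        if set(self.level_mix) - set(LEVELS):
            raise ConfigurationError(
                f"unknown levels in level_mix: {set(self.level_mix) - set(LEVELS)}"
            )
        if len(self.rucc_distribution) != 9:
            raise ConfigurationError("rucc_distribution needs 9 proportions")
        if abs(sum(self.rucc_distribution) - 1.0) > 1e-9:
            raise ConfigurationError("rucc_distribution must sum to 1")
        if not 0.0 < self.intra_region_affinity <= 1.0:
            raise ConfigurationError("intra_region_affinity must be in (0, 1]")
        if self.same_system_affinity < 1.0:
            raise ConfigurationError("same_system_affinity must be >= 1")
        if not 0.0 <= self.upward_fraction <= 1.0:
            raise ConfigurationError("upward_fraction must be in [0, 1]")
        missing = set(_REQUIRED_EFFECT_COVARIATES) - set(self.covariate_effects)
        if missing:
            raise ConfigurationError(
                f"covariate_effects must include {sorted(missing)}"
            )
        if isinstance(self.facilities_per_region, Sequence) and not isinstance(
            self.facilities_per_region, (str, bytes)
        ):
            if len(self.facilities_per_region) != self.n_regions:
                raise ConfigurationError(
                    "facilities_per_region list length must equal n_regions"
                )

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    def adjacency(self) -> dict[str, list[str]]:
        if self.region_adjacency is not None:
            return {r: sorted(v) for r, v in self.region_adjacency.items()}
        return ring_adjacency(self.region_ids)

    def marginals(self) -> Mapping[str, Mapping[str, float]]:
        out = dict(COVARIATE_MARGINALS)
        if self.covariate_marginals is not None:
            out.update(self.covariate_marginals)
        return out

    def intercept(self) -> float:
        if self.transport_intercept is not None:
            return float(self.transport_intercept)
        return calibrate_intercept(
            self.target_prevalence,
            self.covariate_effects,
            self.p_unknown_county,
            self.marginals(),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Recovery targets returned alongside a generated registry."""

    true_covariate_effects: dict[str, dict[str, float]]
    true_region_of_facility: dict[str, str]
    true_intra_region_affinity: float
    true_intercept: float
    true_upward_fraction: float
    n_destination_fallbacks: int = 0


def _normalize(weights: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    levels = list(weights)
    p = np.asarray([weights[k] for k in levels], dtype=float)
    return levels, p / p.sum()


def _effect_marginal(
    covariate: str,
    p_unknown_county: float,
    marginals: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Marginal level probabilities used for exact intercept calibration."""
    if covariate == "rurality":
        known = 1.0 - p_unknown_county
        _, p = _normalize(RURALITY_BIRTH_COUNTS)
        out = {
            cls: float(p[i]) * known
            for i, cls in enumerate(RURALITY_BIRTH_COUNTS)
        }
        out["Unknown"] = p_unknown_county
        return out
    levels, p = _normalize(marginals[covariate])
    return {lvl: float(pi) for lvl, pi in zip(levels, p)}


def calibrate_intercept(
    target_prevalence: float,
    covariate_effects: Mapping[str, Mapping[str, float]],
    p_unknown_county: float,
    marginals: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Solve for the logistic intercept giving the target expected prevalence.

    Covariates are independent, so the expected prevalence is an exact finite
    sum over the product of effect-bearing covariate marginals; the root is
    found by bisection on the intercept.
    """
    marginals = marginals if marginals is not None else COVARIATE_MARGINALS
    spaces = []
    for cov in covariate_effects:
        marg = _effect_marginal(cov, p_unknown_county, marginals)
        eff = covariate_effects[cov]
        spaces.append([(eff.get(lvl, 0.0), p) for lvl, p in marg.items()])
    cells: list[tuple[float, float]] = [(0.0, 1.0)]
    for space in spaces:
        cells = [
            (s + e, p * q) for (s, p) in cells for (e, q) in space if p * q > 0
        ]
    shifts = np.array([s for s, _ in cells])
    probs = np.array([p for _, p in cells])

    def expected(b0: float) -> float:
        return float(probs @ expit(b0 + shifts)) - target_prevalence

    return float(brentq(expected, -30.0, 10.0, xtol=1e-12))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("facilities", "counties", "deliveries", "planted")
    return {name: np.random.default_rng([seed, i]) for i, name in enumerate(names)}


def generate_facilities(config: GeneratorConfig) -> pd.DataFrame:
    """Facility roster with one forced RPC per region.

    Levels beyond the forced RPC follow ``level_mix``; health systems are
    anchored to a home region and cross regions with probability
    ``system_span_regions``.  Deterministic given the config seed.
    """
    if config.level_mix.get("RPC", 0.0) <= 0.0:
        raise ConfigurationError(
            f"level_mix implies zero RPCs; region {config.region_ids[0]} "
            "would have no regional perinatal center"
        )
    rng = _streams(config.seed)["facilities"]
    per_region = config.facilities_per_region
    if isinstance(per_region, int):
        per_region = [per_region] * config.n_regions
    systems = [f"S{i + 1:02d}" for i in range(config.n_systems)]
    system_home = {
        s: config.region_ids[i % config.n_regions] for i, s in enumerate(systems)
    }
    mix_levels, mix_p = _normalize(config.level_mix)
    rows = []
    fid = 0
    for region, n_f in zip(config.region_ids, per_region):
        if n_f <= 0:
            raise ConfigurationError(f"region {region} has no facilities")
        levels = ["RPC"] + list(
            rng.choice(mix_levels, size=n_f - 1, p=mix_p)
        )
        for level in levels:
            fid += 1
            home_systems = [s for s in systems if system_home[s] == region]
            if home_systems and rng.random() >= config.system_span_regions:
                system = home_systems[rng.integers(len(home_systems))]
            else:
                system = systems[rng.integers(len(systems))]
            rows.append(
                {
                    "facility_id": f"F{fid:03d}",
                    "name": f"Facility {fid:03d}",
                    "level": level,
                    "system": system,
                    "dpr": region,
                    "is_obstetric": True,
                }
            )
    for j in range(config.n_nonobstetric_facilities):
        fid += 1
        rows.append(
            {
                "facility_id": f"F{fid:03d}",
                "name": f"Non-obstetric Facility {fid:03d}",
                "level": "I",
                "system": systems[rng.integers(len(systems))],
                "dpr": config.region_ids[rng.integers(config.n_regions)],
                "is_obstetric": False,
            }
        )
    return pd.DataFrame(rows)


def generate_counties(config: GeneratorConfig) -> pd.DataFrame:
    """County roster with RUCC codes; every region gets at least one county."""
    if config.n_counties < config.n_regions:
        raise ConfigurationError(
            f"n_counties ({config.n_counties}) < n_regions ({config.n_regions}): "
            "each region needs at least one county"
        )
    rng = _streams(config.seed)["counties"]
    rucc = rng.choice(np.arange(1, 10), size=config.n_counties,
                      p=np.asarray(config.rucc_distribution))
    regions = np.array(
        config.region_ids
        + list(
            rng.choice(config.region_ids, size=config.n_counties - config.n_regions)
        )
    )
    rng.shuffle(regions)
    # shuffling can empty a region; force coverage deterministically
    for i, region in enumerate(config.region_ids):
        if region not in regions:
            regions[i] = region
    return pd.DataFrame(
        {
            "county_id": [f"C{i + 1:03d}" for i in range(config.n_counties)],
            "rucc": rucc.astype(int),
            "dpr": regions,
        }
    )


def _sample_levels(rng, weights: Mapping[str, float], n: int) -> np.ndarray:
    levels, p = _normalize(weights)
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p)


def _choose_destination(
    rng,
    origin_idx: int,
    upward: bool,
    dest_region: str,
    fac_region: np.ndarray,
    fac_rank: np.ndarray,
    fac_system: np.ndarray,
    config: GeneratorConfig,
) -> tuple[int, bool]:
    """Pick a destination facility index; returns (index, used_upward)."""
    origin_rank = fac_rank[origin_idx]
    in_region = fac_region == dest_region
    in_region[origin_idx] = False
    directed = (fac_rank > origin_rank) if upward else (fac_rank <= origin_rank)
    # region gate takes precedence over transport direction when relaxing,
    # so intra_region_affinity=1 keeps every transport in-region exactly
    for stage, (candidates, is_up) in enumerate(
        (
            (in_region & directed, upward),
            (in_region, False),
            (np.arange(len(in_region)) != origin_idx, False),
        )
    ):
        idx = np.flatnonzero(candidates)
        if len(idx):
            w = np.ones(len(idx))
            w[fac_system[idx] == fac_system[origin_idx]] *= config.same_system_affinity
            if is_up:
                w[fac_rank[idx] == LEVEL_RANK["RPC"]] *= config.rpc_preference
            return int(rng.choice(idx, p=w / w.sum())), stage == 0
    raise RuntimeError("no destination candidates at all")  # single-facility roster


def generate_deliveries(
    config: GeneratorConfig,
    facilities: pd.DataFrame,
    counties: pd.DataFrame,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Record-level delivery table plus ground truth.

    Covariates are drawn independently from the statewide marginals; the
    transport flag is Bernoulli(logistic(intercept + sum of configured
    effects)); transported records get an origin in the residence county's
    region and a destination by the gated, system-weighted draw described in
    the module docstring.  A configurable fraction of transports is degraded
    (missing origin or non-obstetric destination) to exercise the
    network-eligibility filter.
    """
    if facilities.empty or counties.empty:
        raise ConfigurationError("rosters must be nonempty")
    rng = _streams(config.seed)["deliveries"]
    n = config.n_deliveries
    obstetric = facilities[facilities["is_obstetric"].astype(bool)].reset_index(
        drop=True
    )
    non_obstetric_ids = facilities.loc[
        ~facilities["is_obstetric"].astype(bool), "facility_id"
    ].to_numpy()
    fac_ids = obstetric["facility_id"].to_numpy()
    fac_region = obstetric["dpr"].to_numpy()
    fac_rank = obstetric["level"].map(LEVEL_RANK).to_numpy()
    fac_system = obstetric["system"].to_numpy()
    adjacency = config.adjacency()
    region_ids = config.region_ids

    # counties grouped by rurality class for the two-stage county draw
    county_class = counties["rucc"].map(
        lambda r: "urban" if r <= 3 else ("suburban" if r <= 6 else "rural")
    )
    class_to_counties = {
        cls: counties.loc[county_class == cls, "county_id"].to_numpy()
        for cls in RURALITY_BIRTH_COUNTS
    }
    available = {c: w for c, w in RURALITY_BIRTH_COUNTS.items()
                 if len(class_to_counties[c])}
    if not available:
        raise ConfigurationError("county roster has no classifiable counties")
    cls_levels, cls_p = _normalize(available)

    unknown_county = rng.random(n) < config.p_unknown_county
    drawn_class = rng.choice(np.asarray(cls_levels, dtype=object), size=n, p=cls_p)
    county = np.empty(n, dtype=object)
    for cls in cls_levels:
        mask = (drawn_class == cls) & ~unknown_county
        pool = class_to_counties[cls]
        county[mask] = pool[rng.integers(len(pool), size=int(mask.sum()))]
    county[unknown_county] = "Unknown"
    rurality = np.where(unknown_county, "Unknown", drawn_class)

    marginals = config.marginals()
    data: dict[str, np.ndarray] = {}
    for cov, weights in marginals.items():
        data[cov] = _sample_levels(rng, weights, n)

    lp = np.full(n, config.intercept())
    true_intercept = float(lp[0])
    for cov, eff in config.covariate_effects.items():
        values = rurality if cov == "rurality" else data[cov]
        shift = pd.Series(values).map(lambda v: eff.get(v, 0.0)).to_numpy(float)
        lp += shift
    transported = rng.random(n) < expit(lp)

    county_region = dict(zip(counties["county_id"], counties["dpr"]))
    # delivery facility for non-transported records: uniform in the residence
    # region (random region when the county is unknown)
    region_of_record = np.array(
        [
            county_region.get(c, region_ids[rng.integers(len(region_ids))])
            for c in county
        ],
        dtype=object,
    )
    region_facilities = {
        r: np.flatnonzero(fac_region == r) for r in region_ids
    }
    destination = np.empty(n, dtype=object)
    origin = np.full(n, pd.NA, dtype=object)
    for r in region_ids:
        mask = (region_of_record == r) & ~transported
        pool = region_facilities[r]
        destination[mask] = fac_ids[pool[rng.integers(len(pool), size=int(mask.sum()))]]

    n_fallback = 0
    upward_pool = {
        r: idx[fac_rank[idx] < LEVEL_RANK["RPC"]]
        for r, idx in region_facilities.items()
    }
    other_region_p = {}
    for r in region_ids:
        others = [x for x in region_ids if x != r]
        w = np.array(
            [1.0 if x in set(adjacency.get(r, ())) else config.nonneighbor_leak
             for x in others]
        )
        other_region_p[r] = (others, w / w.sum()) if others else ([], None)

    for i in np.flatnonzero(transported):
        r = region_of_record[i]
        upward = rng.random() < config.upward_fraction
        pool = upward_pool[r] if upward else region_facilities[r]
        if len(pool) == 0:
            pool, upward = region_facilities[r], False
        origin_idx = int(pool[rng.integers(len(pool))])
        if rng.random() < config.intra_region_affinity or not other_region_p[r][0]:
            dest_region = r
        else:
            others, p = other_region_p[r]
            dest_region = others[rng.choice(len(others), p=p)]
        dest_idx, first_stage = _choose_destination(
            rng, origin_idx, upward, dest_region, fac_region, fac_rank,
            fac_system, config
        )
        if not first_stage:
            n_fallback += 1
        origin[i] = fac_ids[origin_idx]
        destination[i] = fac_ids[dest_idx]

    # degrade a share of transports so the eligibility filter has real work
    t_idx = np.flatnonzero(transported)
    dropout = t_idx[rng.random(len(t_idx)) < config.endpoint_dropout]
    for i in dropout:
        if len(non_obstetric_ids) and rng.random() < 0.5:
            destination[i] = non_obstetric_ids[rng.integers(len(non_obstetric_ids))]
        else:
            origin[i] = pd.NA

    age = np.clip(rng.normal(28.6, 5.89, size=n), 12, 55).round(1)
    deliveries = pd.DataFrame(
        {
            "record_id": [f"D{i + 1:07d}" for i in range(n)],
            "maternal_age": age,
            **{cov: data[cov] for cov in marginals},
            "county_of_residence": county,
            "transported": transported,
            "origin_facility": pd.array(origin, dtype="string"),
            "destination_facility": pd.array(destination, dtype="string"),
        }
    )
    deliveries = deliveries[
        [c for c in DELIVERY_COLUMNS if c in deliveries.columns]
    ]
    truth = GroundTruth(
        true_covariate_effects={k: dict(v) for k, v in
                                config.covariate_effects.items()},
        true_region_of_facility=dict(zip(facilities["facility_id"],
                                         facilities["dpr"])),
        true_intra_region_affinity=config.intra_region_affinity,
        true_intercept=true_intercept,
        true_upward_fraction=config.upward_fraction,
        n_destination_fallbacks=n_fallback,
    )
    if n_fallback:
        logger.info("%d transports fell back to a non-upward destination",
                    n_fallback)
    return deliveries, truth


def generate_registry(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience: facilities, counties, deliveries, ground truth."""
    facilities = generate_facilities(config)
    counties = generate_counties(config)
    deliveries, truth = generate_deliveries(config, facilities, counties)
    return facilities, counties, deliveries, truth


def plant_partition_network(
    n_communities: int,
    nodes_per_community: int,
    p_in: float,
    p_out: float,
    weight_law: Mapping | None = None,
    seed: int = 0,
) -> tuple[TransportNetwork, Partition]:
    """Weighted planted-partition benchmark for the community detector.

    Within-community node pairs get an edge with probability ``p_in``,
    between-community pairs with ``p_out``; each realized edge receives a
    random orientation and a weight of 1 plus an optional Poisson draw
    (``weight_law={"kind": "poisson", "lam": ...}``).
    """
    if not p_in > p_out >= 0:
        raise ValueError("need p_in > p_out >= 0 for an identifiable benchmark")
    rng = np.random.default_rng([seed, 3])
    graph = nx.DiGraph()
    n = n_communities * nodes_per_community
    nodes = [f"N{i:03d}" for i in range(n)]
    labels = {nodes[i]: i // nodes_per_community for i in range(n)}
    graph.add_nodes_from(nodes)
    for i, j in itertools.combinations(range(n), 2):
        p = p_in if labels[nodes[i]] == labels[nodes[j]] else p_out
        if rng.random() < p:
            w = 1
            if weight_law is not None:
                if weight_law.get("kind") != "poisson":
                    raise ValueError(f"unsupported weight law: {weight_law}")
                w += int(rng.poisson(weight_law.get("lam", 1.0)))
            u, v = (nodes[i], nodes[j]) if rng.random() < 0.5 else (nodes[j], nodes[i])
            graph.add_edge(u, v, weight=w)
    assignment = _canonicalize(labels)
    partition = Partition(
        assignment=assignment,
        n_communities=len(set(assignment.values())),
        modularity=float("nan"),
    )
    return TransportNetwork(graph), partition
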