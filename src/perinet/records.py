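"""Core data model: delivery records, facility/county rosters, and the
inclusion cascade that selects network-eligible transports.

The canonical in-memory containers are pandas DataFrames with documented
column dictionaries (see :data:`DELIVERY_COLUMNS`, :data:`FACILITY_COLUMNS`,
:data:`COUNTY_COLUMNS`).  A delivery row describes one birth; a transported
delivery additionally carries the origin facility (the transferring facility)
while ``destination_facility`` is always the facility where the birth
occurred.  Facilities carry an ordered level of care (Birth Center < Level I
< Level II < Level III < RPC), a health-system identifier, and the designated
perinatal region (DPR) they belong to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered facility levels of care, lowest capability first.  The regional
#: perinatal center (RPC) offers the highest level of care in its region.
LEVELS = ("BirthCenter", "I", "II", "III", "RPC")
LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVELS)}

#: Rurality classes derived from Rural-Urban Continuum Codes.
RURALITY_CLASSES = ("urban", "suburban", "rural")

UNKNOWN = "Unknown"

#: Column dictionary for the delivery table.  Categorical codes are strings.
DELIVERY_COLUMNS = (
    "record_id",
    "maternal_age",
    "race",
    "ethnicity",
    "education",
    "payor",
    "apncu",
    "tobacco",
    "n_medical_risk_factors",
    "preterm",
    "plurality",
    "fetal_presentation",
    "delivery_method",
    "infant_transfer",
    "nicu_abnormal",
    "wic",
    "steroid_lung_maturation",
    "maternal_transfusion",
    "county_of_residence",
    "transported",
    "origin_facility",
    "destination_facility",
)

FACILITY_COLUMNS = ("facility_id", "name", "level", "system", "dpr", "is_obstetric")
COUNTY_COLUMNS = ("county_id", "rucc", "dpr")

#: Covariates tabulated in the transport/non-transport characteristics table.
CHARACTERISTIC_COVARIATES = (
    "race",
    "ethnicity",
    "rurality",
    "education",
    "payor",
    "apncu",
    "tobacco",
    "n_medical_risk_factors",
    "preterm",
    "plurality",
    "fetal_presentation",
    "delivery_method",
    "infant_transfer",
    "nicu_abnormal",
)


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the network-eligibility inclusion cascade.

    ``n_retained = n_transported - n_dropped_missing_endpoint -
    n_dropped_non_obstetric`` holds by construction and is re-asserted on
    instantiation.
    """

    n_input: int
    n_transported: int
    n_dropped_missing_endpoint: int
    n_dropped_non_obstetric: int
    n_retained: int

    def __post_init__(self) -> None:
        expected = (
            self.n_transported
            - self.n_dropped_missing_endpoint
            - self.n_dropped_non_obstetric
        )
        if self.n_retained != expected:
            raise ValueError(
                f"inconsistent FilterReport: retained {self.n_retained} != "
                f"{self.n_transported} - {self.n_dropped_missing_endpoint} - "
                f"{self.n_dropped_non_obstetric}"
            )
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"FilterReport.{name} is negative: {value}")


def classify_rurality(rucc: int) -> str:
    """Collapse a Rural-Urban Continuum Code (1-9) to a three-class label.

    Codes 1-3 are urban, 4-6 suburban, 7-9 rural.
    """
    rucc = int(rucc)
    if not 1 <= rucc <= 9:
        raise ValueError(f"RUCC must be in 1..9, got {rucc}")
    if rucc <= 3:
        return "urban"
    if rucc <= 6:
        return "suburban"
    return "rural"


def rurality_of_records(
    records: pd.DataFrame, counties: pd.DataFrame
) -> pd.Series:
    """Rurality class of each record's county of residence.

    Records with an unknown or unrostered county get ``"Unknown"``; the
    characteristics table carries Unknown as an explicit level.
    """
    county_class = counties.set_index("county_id")["rucc"].map(
        lambda r: classify_rurality(r)
    )
    out = records["county_of_residence"].map(county_class)
    return out.fillna(UNKNOWN)


def _missing_mask(series: pd.Series) -> pd.Series:
    return series.isna() | (series.astype("string").fillna("") == "")


def filter_network_transports(
    records: pd.DataFrame, facilities: pd.DataFrame
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the network-eligibility inclusion cascade.

    Keeps transported deliveries with both endpoints present and both
    endpoints obstetric per the facility roster.  Facility IDs absent from
    the roster are treated as non-obstetric drops (counted and logged).
    Row order of retained records is preserved; the filter is idempotent.
    """
    n_input = len(records)
    transported = records[records["transported"].astype(bool)]
    n_transported = len(transported)

    missing = _missing_mask(transported["origin_facility"]) | _missing_mask(
        transported["destination_facility"]
    )
    with_endpoints = transported[~missing]
    n_missing = int(missing.sum())

    obstetric = set(
        facilities.loc[facilities["is_obstetric"].astype(bool), "facility_id"]
    )
    rostered = set(facilities["facility_id"])
    origin_ok = with_endpoints["origin_facility"].isin(obstetric)
    dest_ok = with_endpoints["destination_facility"].isin(obstetric)
    keep = origin_ok & dest_ok
    n_non_obstetric = int((~keep).sum())

    unknown_ids = (
        set(with_endpoints.loc[~keep, "origin_facility"])
        | set(with_endpoints.loc[~keep, "destination_facility"])
    ) - rostered
    if unknown_ids:
        logger.warning(
            "%d facility IDs absent from roster treated as non-obstetric: %s",
            len(unknown_ids),
            sorted(unknown_ids)[:10],
        )

    retained = with_endpoints[keep]
    report = FilterReport(
        n_input=n_input,
        n_transported=n_transported,
        n_dropped_missing_endpoint=n_missing,
        n_dropped_non_obstetric=n_non_obstetric,
        n_retained=len(retained),
    )
    return retained, report


def characteristics_table(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = CHARACTERISTIC_COVARIATES,
    stratifier: str = "transported",
) -> pd.DataFrame:
    """Two-way counts and within-stratum percentages per covariate level.

    Returns a long table with columns (covariate, level, stratum, count, pct)
    where ``pct`` is the within-stratum column percentage.  Unknown is its own
    level.  Percentages within a (covariate, stratum) column sum to 100 up to
    rounding.  Unseen covariates raise.
    """
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise KeyError(f"covariates absent from records: {missing}")
    strata = records[stratifier].astype(bool)
    rows = []
    for cov in covariates:
        values = records[cov].astype("string").fillna(UNKNOWN)
        tab = pd.crosstab(values, strata)
        for stratum in tab.columns:
            total = tab[stratum].sum()
            for level, count in tab[stratum].items():
                pct = 100.0 * count / total if total else float("nan")
                rows.append(
                    {
                        "covariate": cov,
                        "level": level,
                        "stratum": "transport" if stratum else "non_transport",
                        "count": int(count),
                        "pct": pct,
                    }
                )
    return pd.DataFrame(rows, columns=["covariate", "level", "stratum", "count", "pct"])


def validate_facilities(facilities: pd.DataFrame) -> None:
    """Schema checks for a facility roster."""
    missing = set(FACILITY_COLUMNS) - set(facilities.columns)
    if missing:
        raise ValueError(f"facility roster missing columns: {sorted(missing)}")
    bad = set(facilities["level"]) - set(LEVELS)
    if bad:
        raise ValueError(f"unknown facility levels: {sorted(bad)}")
    if facilities["facility_id"].duplicated().any():
        dupes = facilities.loc[facilities["facility_id"].duplicated(), "facility_id"]
        raise ValueError(f"duplicate facility IDs: {sorted(set(dupes))}")


def validate_counties(counties: pd.DataFrame) -> None:
    """Schema checks for a county roster."""
    missing = set(COUNTY_COLUMNS) - set(counties.columns)
    if missing:
        raise ValueError(f"county roster missing columns: {sorted(missing)}")
    rucc = counties["rucc"].astype(int)
    if ((rucc < 1) | (rucc > 9)).any():
        bad = sorted(set(rucc[(rucc < 1) | (rucc > 9)]))
        raise ValueError(f"RUCC codes out of range 1..9: {bad}")
    if counties["county_id"].duplicated().any():
        raise ValueError("duplicate county IDs")


def read_deliveries(path) -> pd.DataFrame:
    """Read a delivery table, validating the header."""
    df = pd.read_csv(path, dtype={"county_of_residence": "string",
                                  "origin_facility": "string",
                                  "destination_facility": "string"})
    missing = set(DELIVERY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"delivery table missing columns: {sorted(missing)}")
    df["transported"] = df["transported"].astype(bool)
    return df


def read_facilities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_facilities(df)
    df["is_obstetric"] = df["is_obstetric"].astype(bool)
    return df


def read_counties(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_counties(df)
    return df
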