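"""County-level maternal transport rates and rurality-stratified summaries.

A county's rate is the number of transports among residents of that county
per 1000 births to residents of that county.  Rates use all transported
deliveries by default (not just the network-eligible subset): the rate is a
statement about where transported people live, with no obstetric-endpoint
restriction.  Class summaries are unweighted means over counties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import classify_rurality

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountyRateTable:
    """Per-county births, transports, rate and rurality class.

    ``table`` columns: county_id, resident_births, resident_transports,
    rate (per 1000 resident births; NaN when a county has zero births),
    rurality, zero_flag.  ``n_unknown_county`` tallies records excluded for
    an unknown county of residence.
    """

    table: pd.DataFrame
    n_unknown_county: int


def county_rates(
    records: pd.DataFrame,
    counties: pd.DataFrame,
    network_subset: pd.DataFrame | None = None,
) -> CountyRateTable:
    """Transports per 1000 resident births by county of residence.

    One row per rostered county, including zero-transport counties (flagged).
    Pass ``network_subset`` (the filtered records) to restrict the numerator
    to network-eligible transports instead of all transported deliveries.
    """
    known = records[records["county_of_residence"].isin(set(counties["county_id"]))]
    n_unknown = len(records) - len(known)
    births = known.groupby("county_of_residence").size()
    numerator_source = network_subset if network_subset is not None else known
    transports = (
        numerator_source[numerator_source["transported"].astype(bool)]
        .groupby("county_of_residence")
        .size()
    )
    table = counties[["county_id", "rucc"]].copy()
    table["resident_births"] = (
        table["county_id"].map(births).fillna(0).astype(int)
    )
    table["resident_transports"] = (
        table["county_id"].map(transports).fillna(0).astype(int)
    )
    zero_births = table["resident_births"] == 0
    if zero_births.any():
        warnings.warn(
            f"{int(zero_births.sum())} counties have zero resident births; "
            "their rates are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["rate"] = np.where(
            zero_births,
            np.nan,
            1000.0 * table["resident_transports"] / table["resident_births"],
        )
    table["rurality"] = table["rucc"].map(classify_rurality)
    table["zero_flag"] = table["resident_transports"] == 0
    table = table.drop(columns="rucc")
    return CountyRateTable(table=table, n_unknown_county=int(n_unknown))


def rurality_summary(rate_table: CountyRateTable, ddof: int = 0) -> pd.DataFrame:
    """Unweighted mean and SD of county rates per rurality class.

    Uses population SD (``ddof=0``) by default; counties with undefined
    rates are excluded and counted in ``n_excluded``.  Zero-transport
    counties are included in the mean.
    """
    rows = []
    for cls in ("urban", "suburban", "rural"):
        sub = rate_table.table[rate_table.table["rurality"] == cls]
        defined = sub["rate"].dropna()
        if defined.empty:
            warnings.warn(f"no counties with defined rates in class {cls!r}",
                          stacklevel=2)
            rows.append(
                {"rurality": cls, "n_counties": 0, "n_excluded": len(sub),
                 "mean_rate": np.nan, "sd_rate": np.nan}
            )
            continue
        rows.append(
            {
                "rurality": cls,
                "n_counties": int(len(defined)),
                "n_excluded": int(len(sub) - len(defined)),
                "mean_rate": float(defined.mean()),
                "sd_rate": float(defined.std(ddof=ddof)),
            }
        )
    return pd.DataFrame(rows)


def quantile_bins(rate_table: CountyRateTable, k: int = 5) -> pd.Series:
    """Rate-ordered quantile bin (1..k) per county.

    Ties are broken by county ID for reproducibility, so bin sizes differ by
    at most one.  Degenerate input (all defined rates equal) collapses to a
    single bin with a warning.  Counties with undefined rates get no bin
    (NA); use ``zero_flag`` to hash out zero-transport counties separately.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table = rate_table.table
    defined = table[table["rate"].notna()]
    if len(defined) < k:
        raise ValueError(f"need at least k={k} counties with defined rates")
    out = pd.Series(pd.NA, index=table.index, dtype="Int64", name="quantile_bin")
    if defined["rate"].nunique() == 1:
        warnings.warn("all county rates identical; single quantile bin",
                      stacklevel=2)
        out[defined.index] = 1
        return out
    ordered = defined.sort_values(["rate", "county_id"]).index
    sizes = np.full(k, len(ordered) // k)
    sizes[: len(ordered) % k] += 1
    bins = np.repeat(np.arange(1, k + 1), sizes)
    out[ordered] = bins
    return out
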