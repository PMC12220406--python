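"""Agreement between detected transport communities and designated regions.

The cross-tabulation of facilities by (community, region) yields dominance
labels (the modal region per community and vice versa), percent-mismatch
summaries, and a Pearson chi-square test of independence.  Percent mismatch
of a community is the share of its facilities lying outside the community's
dominant region (and symmetrically for regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .community import Partition


@dataclass(frozen=True)
class MismatchTable:
    """Community x region contingency table with dominance and mismatch."""

    counts: pd.DataFrame  # rows: community labels; columns: region IDs
    dominant_region_per_community: dict[int, str]
    dominant_community_per_region: dict[str, int]
    pct_mismatch_rows: pd.Series  # per community
    pct_mismatch_cols: pd.Series  # per region
    chi2: float
    df: int
    p_value: float
    tied_dominance: list = field(default_factory=list)


def chi_square_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction.  Rows or columns summing to zero are dropped
    with a warning before computing the statistic and df = (R-1)(C-1); the
    p-value is the upper tail of the chi-square distribution.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() <= 0:
        raise ValueError("contingency table is empty")
    row_keep = table.sum(axis=1) > 0
    col_keep = table.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        warnings.warn(
            "dropping all-zero rows/columns before chi-square", stacklevel=2
        )
        table = table[np.ix_(row_keep, col_keep)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zeros")
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = expected > 0
    stat = float(((table - expected) ** 2 / np.where(mask, expected, 1.0))[mask].sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    if (expected < 5).any():
        warnings.warn(
            "some expected counts are below 5; chi-square approximation "
            "may be poor",
            stacklevel=2,
        )
    return stat, df, p


def mismatch_table(partition: Partition, facilities: pd.DataFrame) -> MismatchTable:
    """Cross-tabulate partitioned facilities against their designated regions.

    Dominance is the argmax count per row/column; ties resolve to the lowest
    region/community ID and are flagged in ``tied_dominance``.
    """
    dpr = facilities.set_index("facility_id")["dpr"]
    rows = []
    for fac, comm in partition.assignment.items():
        if fac not in dpr.index or pd.isna(dpr.loc[fac]):
            raise KeyError(f"facility {fac} has no designated region")
        rows.append({"facility_id": fac, "community": comm, "dpr": dpr.loc[fac]})
    assigned = pd.DataFrame(rows)
    counts = pd.crosstab(assigned["community"], assigned["dpr"])
    counts = counts.sort_index().sort_index(axis=1)

    ties: list = []

    def _argmax(series: pd.Series, owner) -> Hashable:
        top = series.max()
        winners = sorted(series[series == top].index, key=str)
        if len(winners) > 1:
            ties.append((owner, winners))
        return winners[0]

    dom_region = {
        comm: _argmax(counts.loc[comm], ("community", comm))
        for comm in counts.index
    }
    dom_comm = {
        region: _argmax(counts[region], ("dpr", region))
        for region in counts.columns
    }
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)
    pct_rows = pd.Series(
        {
            comm: 100.0 * (row_totals[comm] - counts.loc[comm, dom_region[comm]])
            / row_totals[comm]
            for comm in counts.index
        },
        name="pct_mismatch",
    )
    pct_cols = pd.Series(
        {
            region: 100.0 * (col_totals[region] - counts.loc[dom_comm[region], region])
            / col_totals[region]
            for region in counts.columns
        },
        name="pct_mismatch",
    )
    chi2, df, p = chi_square_independence(counts.to_numpy())
    return MismatchTable(
        counts=counts,
        dominant_region_per_community=dom_region,
        dominant_community_per_region=dom_comm,
        pct_mismatch_rows=pct_rows,
        pct_mismatch_cols=pct_cols,
        chi2=chi2,
        df=df,
        p_value=p,
        tied_dominance=ties,
    )


def adjusted_rand(
    partition_a: Mapping[Hashable, int] | Partition,
    partition_b: Mapping[Hashable, int] | Partition,
) -> float:
    """Chance-corrected agreement between two partitions of one node set."""
    a = partition_a.assignment if isinstance(partition_a, Partition) else partition_a
    b = partition_b.assignment if isinstance(partition_b, Partition) else partition_b
    if set(a) != set(b):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a, key=str)
    return float(
        adjusted_rand_score([a[n] for n in nodes], [b[n] for n in nodes])
    )
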