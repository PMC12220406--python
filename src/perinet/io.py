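"""Readers/writers for pipeline artifacts (CSV/JSON/YAML/GraphML)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

from .community import Partition
from .concordance import MismatchTable
from .network import InterRegionReport, TransportNetwork
from .rates import CountyRateTable
from .synthetic import GroundTruth


def write_registry(
    outdir,
    facilities: pd.DataFrame,
    counties: pd.DataFrame,
    deliveries: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
    region_adjacency: Mapping | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    facilities.to_csv(outdir / "facilities.csv", index=False)
    counties.to_csv(outdir / "counties.csv", index=False)
    deliveries.to_csv(outdir / "deliveries.csv", index=False)
    if ground_truth is not None:
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(asdict(ground_truth), fh, sort_keys=True)
    if region_adjacency is not None:
        write_region_adjacency(outdir / "region_adjacency.yaml", region_adjacency)


def write_region_adjacency(path, adjacency: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({r: sorted(v) for r, v in adjacency.items()}, fh,
                       sort_keys=True)


def read_region_adjacency(path) -> dict[str, list[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(r): [str(x) for x in (v or [])] for r, v in raw.items()}


def write_characteristics_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_county_rates(path, rate_table: CountyRateTable,
                       bins: pd.Series | None = None) -> None:
    """Choropleth-ready county table (county_id, rate, bin, rurality, flag)."""
    out = rate_table.table.copy()
    if bins is not None:
        out["quantile_bin"] = bins
    out.to_csv(path, index=False)


def write_edge_list(path, network: TransportNetwork) -> None:
    g = network.graph
    rows = []
    for u, v, d in g.edges(data=True):
        rows.append(
            {
                "origin": u,
                "destination": v,
                "weight": int(d["weight"]),
                "origin_dpr": g.nodes[u]["dpr"],
                "destination_dpr": g.nodes[v]["dpr"],
                "cross_flag": g.nodes[u]["dpr"] != g.nodes[v]["dpr"],
                "same_system_flag": g.nodes[u]["system"] == g.nodes[v]["system"],
            }
        )
    pd.DataFrame(
        rows,
        columns=["origin", "destination", "weight", "origin_dpr",
                 "destination_dpr", "cross_flag", "same_system_flag"],
    ).to_csv(path, index=False)


def write_graphml(path, network: TransportNetwork,
                  partition: Partition | None = None) -> None:
    g = network.graph.copy()
    if partition is not None:
        for node, label in partition.assignment.items():
            if node in g.nodes:
                g.nodes[node]["community"] = int(label)
    nx.write_graphml(g, path)


def write_inter_region_report(path, report: InterRegionReport) -> None:
    payload = {
        "pct_nodes_cross": report.pct_nodes_cross,
        "pct_edges_cross": report.pct_edges_cross,
        "pct_volume_cross": report.pct_volume_cross,
        "neighbor_share": report.neighbor_share,
        "intra_volume": report.intra_volume,
        "inter_volume": report.inter_volume,
        "total_volume": report.total_volume,
        "per_region": report.per_region.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)


def write_communities(path, partition: Partition,
                      facilities: pd.DataFrame) -> None:
    dpr = facilities.set_index("facility_id")["dpr"]
    rows = [
        {"facility_id": fac, "community_label": label,
         "dpr": dpr.get(fac, "Unknown")}
        for fac, label in sorted(partition.assignment.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_mismatch(csv_path, json_path, table: MismatchTable) -> None:
    table.counts.to_csv(csv_path)
    payload = {
        "chi2": table.chi2,
        "df": table.df,
        "p_value": table.p_value,
        "dominant_region_per_community": {
            str(k): v for k, v in table.dominant_region_per_community.items()
        },
        "dominant_community_per_region": {
            str(k): int(v) for k, v in table.dominant_community_per_region.items()
        },
        "pct_mismatch_rows": {str(k): v for k, v in
                              table.pct_mismatch_rows.items()},
        "pct_mismatch_cols": {str(k): v for k, v in
                              table.pct_mismatch_cols.items()},
        "tied_dominance": [list(map(str, t[1])) for t in table.tied_dominance],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_or_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_model_fit(path, fit) -> None:
    payload = {
        "coefficients": fit.coefficients,
        "standard_errors": fit.standard_errors,
        "converged": fit.converged,
        "separation": fit.separation,
        "n_iterations": fit.n_iterations,
        "log_likelihood": fit.log_likelihood,
        "or_table": fit.or_table.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
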