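"""Directed weighted facility transport network and its summary metrics.

Nodes are obstetric facilities that appear in at least one retained
transport; a directed edge (origin -> destination) carries the number of
transports observed on that route.  Level-of-care flow is summarized on the
ordered scale Birth Center < Level I < II < III < RPC; inter-region metrics
quantify how much transport crosses designated perinatal region (DPR)
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .records import LEVELS, LEVEL_RANK


class TransportNetwork:
    """Weighted directed transport graph with facility attributes.

    Thin wrapper over :class:`networkx.DiGraph`; edge attribute ``weight``
    is the transport count for that origin-destination route.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return {
            (u, v): int(d["weight"]) for u, v, d in self.graph.edges(data=True)
        }

    @property
    def total_volume(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    @property
    def n_routes(self) -> int:
        return self.graph.number_of_edges()

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class LOCFlowMatrix:
    """Origin x destination level-of-care transport counts."""

    matrix: pd.DataFrame  # 5x5, index=origin level, columns=destination level
    upward_count: int
    upward_to_rpc_count: int

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


@dataclass(frozen=True)
class InterRegionReport:
    """Cross-region transport summary.

    Percentages are on the 0-100 scale.  ``neighbor_share`` is the percentage
    of inter-region volume moving between adjacent regions; it is NaN when
    there is no inter-region volume.
    """

    pct_nodes_cross: float
    pct_edges_cross: float
    pct_volume_cross: float
    neighbor_share: float
    intra_volume: int
    inter_volume: int
    total_volume: int
    per_region: pd.DataFrame = field(repr=False)


def build_network(
    retained_records: pd.DataFrame, facilities: pd.DataFrame
) -> TransportNetwork:
    """Aggregate retained transport records into the weighted directed graph.

    Only facilities appearing in at least one retained transport become
    nodes; isolated roster facilities are excluded from the graph (callers
    can compare against the roster for the alternate denominator).  A record
    whose origin equals its destination is rejected: a transport must change
    facility.
    """
    graph = nx.DiGraph()
    attrs = facilities.set_index("facility_id")
    if len(retained_records):
        same = retained_records["origin_facility"] == retained_records[
            "destination_facility"
        ]
        if same.any():
            bad = retained_records.loc[same, "record_id"].tolist()[:5]
            raise ValueError(
                f"transport records with origin == destination (e.g. {bad})"
            )
        counts = (
            retained_records.groupby(
                ["origin_facility", "destination_facility"], sort=True
            )
            .size()
            .sort_index()
        )
        for (u, v), w in counts.items():
            graph.add_edge(u, v, weight=int(w))
        for node in graph.nodes:
            if node not in attrs.index:
                raise KeyError(f"facility {node} absent from roster")
            row = attrs.loc[node]
            graph.nodes[node].update(
                level=str(row["level"]),
                system=str(row["system"]),
                dpr=str(row["dpr"]),
                is_obstetric=bool(row["is_obstetric"]),
            )
    return TransportNetwork(graph)


def loc_flow(network: TransportNetwork) -> LOCFlowMatrix:
    """Level-of-care flow matrix and upward-transport counts.

    ``upward_count`` sums transports whose destination level strictly exceeds
    the origin level; ``upward_to_rpc_count`` restricts those to RPC
    destinations.
    """
    mat = pd.DataFrame(
        np.zeros((5, 5), dtype=int), index=list(LEVELS), columns=list(LEVELS)
    )
    for u, v, d in network.graph.edges(data=True):
        for node in (u, v):
            if "level" not in network.graph.nodes[node]:
                raise KeyError(f"facility {node} has no level attribute")
        lu = network.graph.nodes[u]["level"]
        lv = network.graph.nodes[v]["level"]
        mat.loc[lu, lv] += int(d["weight"])
    arr = mat.to_numpy()
    upper = np.triu(arr, k=1)
    upward = int(upper.sum())
    upward_to_rpc = int(upper[:, LEVEL_RANK["RPC"]].sum())
    return LOCFlowMatrix(matrix=mat, upward_count=upward,
                         upward_to_rpc_count=upward_to_rpc)


def inter_region_metrics(
    network: TransportNetwork,
    region_adjacency: Mapping[str, set[str] | list[str]],
    roster: pd.DataFrame | None = None,
) -> InterRegionReport:
    """Cross-region transport metrics.

    A node counts as "crossing" if it is an endpoint of at least one
    cross-region edge in either direction.  Node percentages use the active
    node set by default; pass ``roster`` to add an all-roster denominator
    column to ``per_region``.  Every region present in the network must
    appear in ``region_adjacency``.
    """
    g = network.graph
    regions_present = {g.nodes[n]["dpr"] for n in g.nodes}
    missing = regions_present - set(region_adjacency)
    if missing:
        raise KeyError(f"regions absent from adjacency: {sorted(missing)}")

    total = network.total_volume
    inter = intra = 0
    neighbor_volume = 0
    n_cross_edges = 0
    cross_nodes: set[str] = set()
    for u, v, d in g.edges(data=True):
        w = int(d["weight"])
        ru, rv = g.nodes[u]["dpr"], g.nodes[v]["dpr"]
        if ru == rv:
            intra += w
        else:
            inter += w
            n_cross_edges += 1
            cross_nodes.update((u, v))
            if rv in set(region_adjacency[ru]):
                neighbor_volume += w

    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    pct_nodes = 100.0 * len(cross_nodes) / n_nodes if n_nodes else 0.0
    pct_edges = 100.0 * n_cross_edges / n_edges if n_edges else 0.0
    pct_volume = 100.0 * inter / total if total else 0.0
    neighbor_share = 100.0 * neighbor_volume / inter if inter else float("nan")

    rows = []
    for region in sorted(regions_present):
        members = [n for n in g.nodes if g.nodes[n]["dpr"] == region]
        crossing = [n for n in members if n in cross_nodes]
        region_inter = sum(
            int(d["weight"])
            for u, v, d in g.edges(data=True)
            if (g.nodes[u]["dpr"] == region) != (g.nodes[v]["dpr"] == region)
        )
        row = {
            "dpr": region,
            "n_active_facilities": len(members),
            "n_cross_facilities": len(crossing),
            "pct_nodes_cross": 100.0 * len(crossing) / len(members)
            if members
            else 0.0,
            "inter_volume": region_inter,
        }
        if roster is not None:
            n_roster = int(
                (
                    (roster["dpr"] == region)
                    & roster["is_obstetric"].astype(bool)
                ).sum()
            )
            row["n_roster_facilities"] = n_roster
            row["pct_roster_cross"] = (
                100.0 * len(crossing) / n_roster if n_roster else 0.0
            )
        rows.append(row)

    return InterRegionReport(
        pct_nodes_cross=pct_nodes,
        pct_edges_cross=pct_edges,
        pct_volume_cross=pct_volume,
        neighbor_share=neighbor_share,
        intra_volume=int(intra),
        inter_volume=int(inter),
        total_volume=int(total),
        per_region=pd.DataFrame(rows),
    )
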