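"""Haplotype networks and temporal presence summaries.

Builds a minimum spanning network (MSN) over collapsed haplotypes: a
minimum spanning tree grown Kruskal-style in ascending mutation count, with
the option to retain every tie edge whose weight equals the weight at which
its endpoints' components merged. With tie retention this is the epsilon=0
variant of the networks commonly drawn for intraspecific mitochondrial
data; inferred median (unsampled) nodes are deliberately not reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .alignment_io import HaplotypeTable

__all__ = [
    "HaplotypeNetwork",
    "pairwise_differences",
    "minimum_spanning_network",
    "temporal_presence_table",
    "write_network_tables",
]

#: chronological order used to decide which period counts as "most recent"
PERIOD_ORDER = ("pleistocene", "historical", "modern")


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Connected haplotype graph; edge weights are mutation counts."""

    graph: nx.Graph
    keep_ties: bool

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> list[tuple[int, int, int]]:
        return sorted(
            (min(u, v), max(u, v), int(d["weight"]))
            for u, v, d in self.graph.edges(data=True)
        )

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


def pairwise_differences(table: HaplotypeTable) -> np.ndarray:
    """Symmetric matrix of Hamming distances between haplotype strings."""
    if table.n_haplotypes == 0:
        raise ValueError("haplotype table is empty")
    lengths = {len(h) for h in table.haplotypes}
    if len(lengths) > 1:
        raise ValueError(f"haplotype strings of unequal length: {sorted(lengths)}")
    arr = np.array([list(h) for h in table.haplotypes])
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)


def minimum_spanning_network(
    dist: np.ndarray,
    keep_ties: bool = True,
    table: HaplotypeTable | None = None,
) -> HaplotypeNetwork:
    """Minimum spanning network from a haplotype distance matrix.

    Edges are processed in ascending (weight, node pair) order. In tree mode
    exactly H-1 edges are kept (a minimum spanning tree with deterministic
    tie-breaking). With ``keep_ties``, within each weight class every edge
    joining two components that were still separate at the start of that
    class is retained, so alternative connections at the merging weight
    survive.

    When a :class:`HaplotypeTable` is given, its per-group counts are stored
    as node attributes.
    """
    dist = np.asarray(dist)
    H = dist.shape[0]
    if H == 0:
        raise ValueError("empty distance matrix")
    if dist.shape != (H, H) or not np.array_equal(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")

    g = nx.Graph()
    g.add_nodes_from(range(H))
    if table is not None:
        for grp in sorted(table.group_counts):
            counts = table.counts(grp)
            for h in range(H):
                g.nodes[h][f"count_{grp}"] = int(counts[h])

    parent = list(range(H))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        (int(dist[i, j]), i, j) for i in range(H) for j in range(i + 1, H)
    )
    pos = 0
    while pos < len(edges):
        w = edges[pos][0]
        block = []
        while pos < len(edges) and edges[pos][0] == w:
            block.append(edges[pos])
            pos += 1
        if keep_ties:
            # retain every edge joining components still separate at the
            # start of this weight class, then merge
            snapshot = [find(x) for x in range(H)]
            merges = []
            for _, i, j in block:
                if snapshot[i] != snapshot[j]:
                    g.add_edge(i, j, weight=w)
                    merges.append((i, j))
            for i, j in merges:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        else:
            # plain Kruskal: union immediately so cycles within a weight
            # class are rejected
            for _, i, j in block:
                ri, rj = find(i), find(j)
                if ri != rj:
                    g.add_edge(i, j, weight=w)
                    parent[ri] = rj

    return HaplotypeNetwork(graph=g, keep_ties=keep_ties)


def temporal_presence_table(table: HaplotypeTable) -> pd.DataFrame:
    """Label each haplotype by its presence across sampling periods.

    * ``shared``: present in two or more periods;
    * ``private_<period>``: present only in the most recent period sampled;
    * ``lost``: present only in an earlier period, hence absent from the
      most recent one.

    The labels partition the haplotypes. Groups must be keyed by period.
    """
    periods = [p for p in PERIOD_ORDER if p in table.group_counts]
    if not periods:
        raise ValueError(
            "group counts are not keyed by period; collapse with group_by='period'"
        )
    latest = periods[-1]
    rows = []
    for h in range(table.n_haplotypes):
        present = [p for p in periods if table.counts(p)[h] > 0]
        if len(present) >= 2:
            label = "shared"
        elif present[0] == latest:
            label = f"private_{latest}"
        else:
            label = "lost"
        row: dict[str, object] = {"haplotype_id": f"H{h + 1}"}
        for p in periods:
            row[f"count_{p}"] = int(table.counts(p)[h])
        row["label"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def write_network_tables(
    net: HaplotypeNetwork,
    table: HaplotypeTable,
    edges_path,
    nodes_path,
    graphml_path=None,
) -> None:
    """Write edge-list and node TSVs (and optionally GraphML) for a network."""
    pd.DataFrame(
        [
            {"hap_a": f"H{a + 1}", "hap_b": f"H{b + 1}", "mutations": w}
            for a, b, w in net.edges
        ]
    ).to_csv(edges_path, sep="\t", index=False)
    groups = sorted(table.group_counts)
    pd.DataFrame(
        [
            {
                "haplotype_id": f"H{h + 1}",
                **{f"count_{g}": int(table.counts(g)[h]) for g in groups},
            }
            for h in range(table.n_haplotypes)
        ]
    ).to_csv(nodes_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)
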