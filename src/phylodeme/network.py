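"""Statistical-parsimony haplotype networks.

Haplotype pairs are connected in order of increasing Hamming distance, up
to the parsimony connection limit.  A pair at distance d is joined —
routing through d-1 inferred intermediate haplotypes of frequency 0 —
only if the current network does not already realize a path of at most d
single-mutation steps between them; equal-length alternative routes
between sampled haplotypes therefore survive as loops.  Candidate order
is deterministic: distance ascending, then summed haplotype frequency
descending, then lexicographic haplotype ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from phylodeme.haplotypes import HaplotypeTable, connection_limit


@dataclass
class HaplotypeNetwork:
    """A statistical-parsimony network over a haplotype table."""

    graph: nx.Graph
    table: HaplotypeTable
    limit: int

    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("inferred", False)]

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def sampled_edge_pairs(self) -> set[frozenset]:
        """Directly realized connections between sampled haplotypes.

        Each inferred-intermediate chain is contracted to the pair of
        sampled haplotypes it joins.
        """
        pairs = set()
        g = self.graph
        for u, v in g.edges():
            ends = []
            for start in (u, v):
                if not g.nodes[start].get("inferred", False):
                    ends.append(start)
            if len(ends) == 2:
                pairs.add(frozenset(ends))
        # walk chains of intermediates
        for node, data in g.nodes(data=True):
            if data.get("inferred", False) and data.get("chain_ends"):
                pairs.add(frozenset(data["chain_ends"]))
        return pairs


def build_network(table: HaplotypeTable, limit: int | None = None) -> HaplotypeNetwork:
    """Connect haplotypes by single mutational steps up to ``limit``.

    With ``limit`` omitted it is computed from the table's clean column
    count at 95% confidence.
    """
    if len(table.haplotype_ids) < 1:
        raise ValueError("network requires at least one haplotype")
    if limit is None:
        limit = connection_limit(max(len(table.included_columns), 1), 0.95)
    g = nx.Graph(connection_limit=int(limit))
    totals = table.total_counts()
    for h in table.haplotype_ids:
        g.add_node(h, frequency=int(totals[h]), inferred=False,
                   **{f"count_{d}": int(table.counts.loc[h, d]) for d in table.deme_labels})
    D = table.distance_matrix()
    ids = table.haplotype_ids
    candidates = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = int(D.iloc[i, j])
            if d == 0:
                raise ValueError(f"haplotypes {ids[i]} and {ids[j]} are identical over clean columns")
            if d <= limit:
                a, b = sorted((ids[i], ids[j]))
                candidates.append((d, -(int(totals[ids[i]]) + int(totals[ids[j]])), a, b))
    candidates.sort()
    n_inferred = 0
    for d, _negfreq, a, b in candidates:
        try:
            cur = nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            cur = None
        if cur is not None and cur <= d:
            continue
        prev = a
        ends = (a, b)
        for step in range(d - 1):
            n_inferred += 1
            mid = f"mv{n_inferred}"
            g.add_node(mid, frequency=0, inferred=True, chain_ends=ends,
                       **{f"count_{dl}": 0 for dl in table.deme_labels})
            g.add_edge(prev, mid, steps=1)
            prev = mid
        g.add_edge(prev, b, steps=1)
    return HaplotypeNetwork(g, table, int(limit))


def write_graphml(net: HaplotypeNetwork, path) -> None:
    g = net.graph.copy()
    for _, data in g.nodes(data=True):
        data.pop("chain_ends", None)
        data["inferred"] = bool(data.get("inferred", False))
    nx.write_graphml(g, path)
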