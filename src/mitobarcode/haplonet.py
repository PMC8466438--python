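"""Median-joining haplotype networks.

Implements the median-joining construction of Bandelt, Forster & Roehl:
starting from the minimum-spanning network (MSN) over observed
haplotypes, quasi-median (Steiner) sequences of connected triplets are
added iteratively when they shorten the network, then inferred nodes
that no longer lie on any minimal path are pruned.  The relaxation
parameter epsilon (default 0, the Network-software default) widens the
set of feasible links; all sites carry equal weight.

Only A/C/G/T columns participate: alignment columns with gaps or
ambiguity codes are excluded upstream by the haplotype collapser, as the
quasi-median is undefined for ambiguity codes.

Determinism: candidate medians and links are processed in lexicographic
order of haplotype sequence, so the result depends only on the input
haplotype set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from mitobarcode.barcode_stats import HaplotypeTable

_MAX_ROUNDS_DEFAULT = 20


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class MJNetwork:
    """Haplotype network: observed nodes (count > 0) plus inferred
    median vectors (count 0), edges weighted by Hamming distance."""

    graph: nx.Graph
    epsilon: int = 0

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["inferred"]]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["inferred"]]

    def total_length(self) -> int:
        """Summed weight of all network links (ties kept)."""
        return sum(w for _, _, w in self.graph.edges(data="weight"))

    def spanning_length(self) -> int:
        """Weight of a minimum spanning tree of the network itself.

        With distance ties the minimum-spanning network carries every
        co-minimal link, so ``total_length`` can exceed the length of a
        single spanning tree; this is the tie-free measure of how much
        inferred medians shortened the network.
        """
        return sum(d["weight"] for _, _, d in
                   nx.minimum_spanning_edges(self.graph, data=True))


def _msn_edges(nodes: list[str], epsilon: int = 0) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum-spanning network.

    An edge (u, v) of weight w is feasible iff u and v are not already
    connected using only edges of weight < w - epsilon.  For
    epsilon = 0 this is exactly the union of all minimum spanning trees
    of the node set (ties keep every co-minimal link).
    """
    if len(nodes) <= 1:
        return []
    ns = sorted(nodes)
    pairs = sorted((hamming(a, b), a, b) for a, b in itertools.combinations(ns, 2))

    comp_cache: dict[int, dict[str, int]] = {}

    def components_upto(t: int) -> dict[str, int]:
        if t not in comp_cache:
            g = nx.Graph()
            g.add_nodes_from(ns)
            g.add_edges_from((x, y) for ww, x, y in pairs if ww <= t)
            mapping: dict[str, int] = {}
            for i, cc in enumerate(sorted(nx.connected_components(g), key=min)):
                for n in cc:
                    mapping[n] = i
            comp_cache[t] = mapping
        return comp_cache[t]

    edges = []
    for w, a, b in pairs:
        comp = components_upto(w - epsilon - 1)
        if comp[a] != comp[b]:
            edges.append((a, b, w))
    return edges


def quasi_medians(a: str, b: str, c: str) -> list[str]:
    """Column-wise quasi-medians of a triplet.

    Majority state per column; columns where all three states differ
    contribute each of the three states, multiplying the candidates.
    Returned in lexicographic order.
    """
    options: list[tuple[str, ...]] = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            options.append((x,))
        elif y == z:
            options.append((y,))
        else:
            options.append(tuple(sorted({x, y, z})))
    return sorted("".join(t) for t in itertools.product(*options))


def _mst_length(nodes: list[str]) -> int:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(sorted(nodes), 2):
        g.add_edge(a, b, weight=hamming(a, b))
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))


def median_joining(
    tab: HaplotypeTable,
    epsilon: int = 0,
    max_rounds: int = _MAX_ROUNDS_DEFAULT,
) -> MJNetwork:
    """Build the median-joining network of a haplotype table.

    Raises ``RuntimeError`` if median addition has not closed after
    ``max_rounds`` iterations (never silently truncates).
    """
    observed = sorted({seq for seq, _, _ in tab.haplotypes})
    if len({len(s) for s in observed}) > 1:
        raise ValueError("haplotype sequences must have equal length")
    counts = {seq: 0 for seq in observed}
    members: dict[str, list[str]] = {seq: [] for seq in observed}
    for seq, cnt, ids in tab.haplotypes:
        counts[seq] += cnt
        members[seq].extend(ids)

    nodes = list(observed)
    for round_no in range(max_rounds + 1):
        msn = _msn_edges(nodes, epsilon)
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for a, b, _ in msn:
            adj[a].add(b)
            adj[b].add(a)
        added = False
        # triplets connected in the MSN (at least two of three links)
        for trip in itertools.combinations(sorted(nodes), 3):
            a, b, c = trip
            links = sum(1 for u, v in itertools.combinations(trip, 2) if v in adj[u])
            if links < 2:
                continue
            span = _mst_length(list(trip))
            for qm in quasi_medians(a, b, c):
                if qm in counts:
                    continue
                star = hamming(qm, a) + hamming(qm, b) + hamming(qm, c)
                if star < span:
                    nodes.append(qm)
                    counts[qm] = 0
                    members[qm] = []
                    added = True
                    break  # one median per triplet per round
        if not added:
            break
        if round_no == max_rounds:
            raise RuntimeError(
                f"median addition did not converge in {max_rounds} rounds")

    # obsolete-node deletion: drop inferred nodes whose removal does not
    # lengthen the network over the remaining set
    pruned = True
    while pruned:
        pruned = False
        msn = _msn_edges(nodes, epsilon)
        total = sum(w for _, _, w in msn)
        degree: dict[str, int] = {n: 0 for n in nodes}
        for a, b, _ in msn:
            degree[a] += 1
            degree[b] += 1
        for node in sorted(n for n in nodes if counts[n] == 0):
            if degree[node] <= 1:
                nodes.remove(node)
                pruned = True
                break
            trial = [n for n in nodes if n != node]
            trial_msn = _msn_edges(trial, epsilon)
            if sum(w for _, _, w in trial_msn) <= total:
                nodes.remove(node)
                pruned = True
                break

    graph = nx.Graph(epsilon=epsilon)
    for n in nodes:
        graph.add_node(n, count=counts[n], inferred=counts[n] == 0,
                       members=",".join(members[n]))
    for a, b, w in _msn_edges(nodes, epsilon):
        graph.add_edge(a, b, weight=w)
    return MJNetwork(graph=graph, epsilon=epsilon)


# ---------------------------------------------------------------------------
# export


def export_network(net: MJNetwork, path: str | Path, fmt: str = "GML") -> None:
    """Serialize the network as GML or DOT (re-importable attributes)."""
    path = Path(path)
    fmt = fmt.upper()
    if fmt == "GML":
        nx.write_gml(net.graph, str(path))
    elif fmt == "DOT":
        lines = ["graph haplonet {"]
        for n, d in sorted(net.graph.nodes(data=True)):
            shape = "point" if d["inferred"] else "circle"
            lines.append(
                f'  "{n}" [count={d["count"]}, inferred={int(d["inferred"])}, '
                f'shape={shape}];')
        for a, b, w in sorted(net.graph.edges(data="weight")):
            lines.append(f'  "{a}" -- "{b}" [label={w}, weight={w}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_gml(path: str | Path) -> MJNetwork:
    graph = nx.read_gml(str(path))
    eps = graph.graph.get("epsilon", 0)
    return MJNetwork(graph=graph, epsilon=eps)
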