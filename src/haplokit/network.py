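"""Median-joining haplotype networks.

The network connects observed sequence classes through an ε-relaxed
minimum-spanning structure: a candidate link (u, v) with Hamming weight w is
retained iff w <= f(u, v) + ε, where f(u, v) is the minimax connection
weight (the smallest threshold at which u and v become connected in a
Kruskal sweep). With ε = 0 this retains exactly the union of all minimum
spanning trees. Median vectors — per-column majority consensus of three
mutually linked nodes — are inserted greedily while they reduce the
spanning cost of the node set, then unobserved nodes of degree <= 2 are
pruned. Characters are the variable columns only, equally weighted, with
the gap as an ordinary fifth state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .variants import HaplotypeTable


@dataclass(frozen=True)
class NetworkNode:
    label: str
    key: tuple[str, ...]
    counts: Mapping[str, int]  # population -> individuals (empty for medians)
    is_median: bool = False

    @property
    def size(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[tuple[str, str, int], ...]  # (labelA, labelB, weight), A < B
    epsilon: int

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.label,
                key="".join(node.key),
                size=node.size,
                is_median=node.is_median,
                **{f"count_{pop}": c for pop, c in sorted(node.counts.items())},
            )
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def cost(self) -> int:
        """Spanning (connection) cost of the final node set: total weight of
        a minimum spanning tree over all pairwise Hamming distances."""
        return _mst_cost({n.label: n.key for n in self.nodes})


def _hamming(a: Sequence[str], b: Sequence[str]) -> int:
    return sum(x != y for x, y in zip(a, b))


def hamming_matrix(tbl: HaplotypeTable) -> np.ndarray:
    """Pairwise Hamming distances between haplotype keys, in label order."""
    keys = [key for _, key in tbl.haplotypes]
    n = len(keys)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _hamming(keys[i], keys[j])
    return out


def _mst_cost(keys: Mapping[str, tuple[str, ...]]) -> int:
    labels = sorted(keys)
    if len(labels) <= 1:
        return 0
    g = nx.Graph()
    g.add_nodes_from(labels)
    for a, b in combinations(labels, 2):
        g.add_edge(a, b, weight=_hamming(keys[a], keys[b]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def _minimax_weights(
    keys: Mapping[str, tuple[str, ...]]
) -> dict[frozenset, int]:
    """Kruskal merge weights: f(u,v) = threshold at which u,v first connect."""
    labels = sorted(keys)
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        (_hamming(keys[a], keys[b]), a, b) for a, b in combinations(labels, 2)
    )
    f: dict[frozenset, int] = {}
    i = 0
    while i < len(edges):
        w = edges[i][0]
        batch = []
        while i < len(edges) and edges[i][0] == w:
            batch.append(edges[i])
            i += 1
        # record merges for the whole weight class before union-ing, so ties
        # within a class all count as connecting at this threshold
        comps: dict[str, list[str]] = {}
        for lab in labels:
            comps.setdefault(find(lab), []).append(lab)
        merged_roots: list[set[str]] = []
        for w_, a, b in batch:
            ra, rb = find(a), find(b)
            if ra != rb:
                for u in comps[ra]:
                    for v in comps[rb]:
                        pair = frozenset((u, v))
                        if pair not in f:
                            f[pair] = w
                parent[ra] = rb
                comps[rb] = comps[rb] + comps[ra]
    return f


def _relaxed_links(
    keys: Mapping[str, tuple[str, ...]], epsilon: int
) -> set[tuple[str, str, int]]:
    """ε-relaxed minimum-spanning link set."""
    labels = sorted(keys)
    if len(labels) < 2:
        return set()
    f = _minimax_weights(keys)
    links = set()
    for a, b in combinations(labels, 2):
        w = _hamming(keys[a], keys[b])
        if w <= f[frozenset((a, b))] + epsilon:
            links.add((a, b, w))
    return links


def _median_key(
    keys: Sequence[tuple[str, ...]],
) -> tuple[str, ...]:
    """Per-column majority of three keys; a three-way tie resolves to the
    state of the first key (deterministic label order)."""
    out = []
    for states in zip(*keys):
        counts: dict[str, int] = {}
        for s in states:
            counts[s] = counts.get(s, 0) + 1
        best = max(counts.values())
        if best == 1:
            out.append(states[0])
        else:
            out.append(next(s for s in states if counts[s] == best))
    return tuple(out)


def build_mjn(tbl: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Median-joining network over the table's haplotype classes.

    Iterates: (i) build the ε-relaxed link set; (ii) for every mutually
    linked triple compute its median key and, among unseen medians that
    strictly reduce the spanning cost, add the best (largest reduction,
    lexicographic key tie-break); repeat to fixpoint; (iii) prune unobserved
    nodes of degree <= 2, lowest label first, recomputing links after each
    removal. A single haplotype yields a single-node network.
    """
    keys: dict[str, tuple[str, ...]] = {lab: key for lab, key in tbl.haplotypes}
    observed = set(keys)
    mv_index = 0

    while True:
        links = _relaxed_links(keys, epsilon)
        adjacent = {frozenset((a, b)) for a, b, _ in links}
        current_cost = _mst_cost(keys)
        existing = set(keys.values())
        best: tuple[int, tuple[str, ...]] | None = None
        for a, b, c in combinations(sorted(keys), 3):
            if not (
                frozenset((a, b)) in adjacent
                and frozenset((a, c)) in adjacent
                and frozenset((b, c)) in adjacent
            ):
                continue
            med = _median_key([keys[a], keys[b], keys[c]])
            if med in existing:
                continue
            new_cost = _mst_cost({**keys, "__cand__": med})
            if new_cost < current_cost:
                cand = (new_cost, med)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        mv_index += 1
        keys[f"mv{mv_index}"] = best[1]

    # prune unobserved nodes of degree <= 2
    while True:
        links = _relaxed_links(keys, epsilon)
        degree: dict[str, int] = {lab: 0 for lab in keys}
        for a, b, _ in links:
            degree[a] += 1
            degree[b] += 1
        prunable = sorted(
            lab for lab in keys if lab not in observed and degree[lab] <= 2
        )
        if not prunable:
            break
        del keys[prunable[0]]

    links = _relaxed_links(keys, epsilon)
    nodes = tuple(
        NetworkNode(
            label=lab,
            key=keys[lab],
            counts=tbl.population_counts(lab) if lab in observed else {},
            is_median=lab not in observed,
        )
        for lab in sorted(keys)
    )
    edges = tuple(sorted(links))
    return HaplotypeNetwork(nodes=nodes, edges=edges, epsilon=epsilon)


# ---------------------------------------------------------------------------
# export / import


def export_network(
    net: HaplotypeNetwork, path: str | Path, fmt: str = "graphml"
) -> None:
    """Write the network as ``graphml``, ``dot`` or ``edge_tsv``.

    Nodes carry total size and per-population counts; edges carry the
    mutational-step weight. ``edge_tsv`` re-imports to the same topology via
    :func:`read_edge_tsv`.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph(), str(path))
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph haplotype_network {\n")
            for node in net.nodes:
                shape = "diamond" if node.is_median else "circle"
                fh.write(
                    f'  "{node.label}" [size={node.size}, shape={shape}];\n'
                )
            for a, b, w in net.edges:
                fh.write(f'  "{a}" -- "{b}" [label={w}, weight={w}];\n')
            fh.write("}\n")
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("nodeA\tnodeB\tweight\n")
            for a, b, w in net.edges:
                fh.write(f"{a}\t{b}\t{w}\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (graphml, dot, edge_tsv)")


def write_node_table(net: HaplotypeNetwork, path: str | Path) -> None:
    """Node attribute table: label, key, total size, per-population counts."""
    pops = sorted({p for node in net.nodes for p in node.counts})
    with open(path, "w") as fh:
        fh.write("label\tkey\tis_median\tsize" + "".join(f"\t{p}" for p in pops) + "\n")
        for node in net.nodes:
            row = [node.label, "".join(node.key), str(node.is_median).lower(),
                   str(node.size)]
            row += [str(node.counts.get(p, 0)) for p in pops]
            fh.write("\t".join(row) + "\n")


def read_edge_tsv(path: str | Path) -> set[tuple[str, str, int]]:
    edges = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("nodeA"):
            raise ValueError(f"{path}: missing edge-list header")
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            edges.add((a, b, int(w)))
    return edges
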