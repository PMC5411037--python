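"""Median-joining haplotype network construction.

The network combines the minimum-spanning network (the union of all minimum
spanning trees, relaxed by a tolerance epsilon) over observed haplotypes
with inferred median (consensus) vectors of haplotype triplets that shorten
the network, followed by a maximum-parsimony cleaning step that discards
median vectors that no longer pay for themselves.

Only variable alignment columns participate; node sequences are reported in
the supplied alignment's coordinates (positions 1-based).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import HaplotypeDataset

__all__ = ["median_joining_network", "HaploNetwork", "NetworkNode"]

_AMBIGUOUS = (b"N", b"-")


@dataclass
class NetworkNode:
    label: str
    sequence: str  # states at the variable sites, in position order
    count: int  # total observed frequency (0 for median vectors)
    locality_counts: dict[str, int]
    is_median: bool


@dataclass
class HaploNetwork:
    nodes: list[NetworkNode]
    edges: list[tuple[int, int, int, tuple[int, ...]]]  # (i, j, steps, positions)
    variable_positions: tuple[int, ...]  # 1-based alignment coordinates

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, node in enumerate(self.nodes):
            g.add_node(i, **vars(node))
        for i, j, w, pos in self.edges:
            g.add_edge(i, j, weight=w, positions=pos)
        return g

    def total_length(self) -> int:
        return sum(w for _, _, w, _ in self.edges)

    def min_distance_between(self, group_a: set[str], group_b: set[str]) -> int:
        """Shortest path length (in mutation steps) between two sets of
        observed haplotype labels."""
        g = self.graph()
        index = {n.label: i for i, n in enumerate(self.nodes)}
        best = None
        for a, b in itertools.product(group_a, group_b):
            d = nx.shortest_path_length(
                g, index[a], index[b], weight="weight"
            )
            best = d if best is None else min(best, d)
        return best


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum(a != b))


def _msn_edges(vectors: list[np.ndarray], epsilon: int) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network edges (Kruskal-style with epsilon slack).

    Distance bands are processed in increasing order; an edge at distance d
    is feasible when its endpoints are not connected by accepted edges of
    weight <= d - 1 - epsilon. With epsilon = 0 this is the union of all
    minimum spanning trees; epsilon > 0 keeps additional near-minimal links.
    """
    n = len(vectors)
    pairs = sorted(
        (_hamming(vectors[i], vectors[j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    bands = sorted({w for w, _, _ in pairs})
    out: list[tuple[int, int, int]] = []
    for d in bands:
        h = nx.Graph()
        h.add_nodes_from(range(n))
        h.add_edges_from((i, j) for i, j, w in out if w <= d - 1 - epsilon)
        comp = {u: c for c, nodes in enumerate(nx.connected_components(h)) for u in nodes}
        for w, i, j in pairs:
            if w == d and comp[i] != comp[j]:
                out.append((i, j, w))
    return out


def _mst_length(vectors: list[np.ndarray]) -> int:
    n = len(vectors)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=_hamming(vectors[i], vectors[j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
    )


def _median_vector(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray | None:
    """Per-site majority consensus; None where some site has three states."""
    out = a.copy()
    for s in range(a.size):
        states = (a[s], b[s], c[s])
        vals, counts = np.unique(states, return_counts=True)
        if vals.size == 3:
            return None
        out[s] = vals[np.argmax(counts)]
    return out


def median_joining_network(
    haplotypes: HaplotypeDataset, epsilon: int = 0
) -> HaploNetwork:
    """Build the median-joining network of an alignment.

    Iterates: (1) minimum-spanning network over the current node set;
    (2) propose median (majority-consensus) vectors for triplets that are
    mutually close in the network and add, greedily, those that reduce the
    minimum-spanning-tree length; (3) when no median helps, drop inferred
    vectors whose removal does not lengthen the tree (maximum-parsimony
    cleaning) and emit the final minimum-spanning network.

    Ties among equal-cost links are broken lexicographically by node label
    for reproducibility.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    pops, counts_matrix = haplotypes.haplotype_counts_by_population()
    hap_strings, _, counts = haplotypes.haplotype_table()
    if len(hap_strings) < 2:
        raise ValueError("need >= 2 distinct haplotypes")

    seqs = np.array([list(s) for s in hap_strings], dtype="S1")
    if np.isin(seqs, _AMBIGUOUS).any():
        variable = [
            j
            for j in range(seqs.shape[1])
            if np.unique(seqs[~np.isin(seqs[:, j], _AMBIGUOUS), j]).size > 1
        ]
        bad = [
            j for j in variable if np.isin(seqs[:, j], _AMBIGUOUS).any()
        ]
        if bad:
            raise ValueError(
                f"ambiguous characters at variable site(s) {[b + 1 for b in bad]}"
            )
    variable = [
        j for j in range(seqs.shape[1]) if np.unique(seqs[:, j]).size > 1
    ]
    vectors = [seqs[i, variable].copy() for i in range(len(hap_strings))]
    n_observed = len(vectors)

    # --- median-joining iterations -----------------------------------
    while True:
        edges = _msn_edges(vectors, epsilon)
        g = nx.Graph()
        g.add_nodes_from(range(len(vectors)))
        g.add_edges_from((i, j) for i, j, _ in edges)
        base_len = _mst_length(vectors)
        candidates: dict[bytes, np.ndarray] = {}
        existing = {v.tobytes() for v in vectors}
        for i, j, k in itertools.combinations(range(len(vectors)), 3):
            if not (g.has_edge(i, j) or g.has_edge(i, k) or g.has_edge(j, k)):
                continue
            m = _median_vector(vectors[i], vectors[j], vectors[k])
            if m is None:
                continue
            key = m.tobytes()
            if key not in existing:
                candidates[key] = m
        best_gain, best_vec = 0, None
        for key in sorted(candidates):  # lexicographic tie-break
            m = candidates[key]
            gain = base_len - _mst_length(vectors + [m])
            if gain > best_gain:
                best_gain, best_vec = gain, m
        if best_vec is None:
            break
        vectors.append(best_vec)

    # --- maximum-parsimony cleaning ----------------------------------
    changed = True
    while changed:
        changed = False
        base_len = _mst_length(vectors)
        for idx in range(len(vectors) - 1, n_observed - 1, -1):
            trimmed = vectors[:idx] + vectors[idx + 1 :]
            if _mst_length(trimmed) <= base_len:
                del vectors[idx]
                changed = True
                break

    # --- final network -------------------------------------------------
    edges = _msn_edges(vectors, epsilon)
    nodes = []
    for i, v in enumerate(vectors):
        if i < n_observed:
            nodes.append(
                NetworkNode(
                    label=f"H{i + 1}",
                    sequence=v.tobytes().decode(),
                    count=int(counts[i]),
                    locality_counts={
                        p: int(counts_matrix[i, k])
                        for k, p in enumerate(pops)
                        if counts_matrix[i, k] > 0
                    },
                    is_median=False,
                )
            )
        else:
            nodes.append(
                NetworkNode(
                    label=f"mv{i - n_observed + 1}",
                    sequence=v.tobytes().decode(),
                    count=0,
                    locality_counts={},
                    is_median=True,
                )
            )
    out_edges = []
    for i, j, w in edges:
        pos = tuple(
            variable[s] + 1
            for s in range(len(variable))
            if vectors[i][s] != vectors[j][s]
        )
        out_edges.append((i, j, w, pos))
    return HaploNetwork(
        nodes, out_edges, tuple(v + 1 for v in variable)
    )


def network_edge_table(net: HaploNetwork):
    import pandas as pd

    rows = [
        {
            "from": net.nodes[i].label,
            "to": net.nodes[j].label,
            "steps": w,
            "positions": ";".join(map(str, pos)),
        }
        for i, j, w, pos in net.edges
    ]
    return pd.DataFrame(rows)


def node_frequency_table(net: HaploNetwork):
    import pandas as pd

    pops = sorted({p for n in net.nodes for p in n.locality_counts})
    rows = []
    for n in net.nodes:
        row = {"haplotype": n.label, "median": n.is_median, "total": n.count}
        row.update({p: n.locality_counts.get(p, 0) for p in pops})
        rows.append(row)
    return pd.DataFrame(rows)
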