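"""Haplotype networks and grouping trees.

The minimum-spanning network follows the goeBURST convention: a
Kruskal-style MST over Hamming (mutational-step) distances where
equal-weight candidate edges are ranked by a tie-break chain on their
endpoints — more single-step neighbours first, then more double-step
neighbours, then higher haplotype abundance, then the lexicographically
smaller id. Group-to-group "mutational steps" are reported both as the
minimum pairwise Hamming distance between member haplotypes (primary) and
as the MST path length.

A neighbour-joining tree on Kimura two-parameter distances provides the
grouping view in place of heavyweight likelihood phylogenetics.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable

logger = logging.getLogger(__name__)

K2P_CEILING = 10.0


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    def __getitem__(self, pair):
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return self.d[i, j]


def hamming_matrix(table: HaplotypeTable) -> DistanceMatrix:
    """Pairwise Hamming distances (mutational steps) between haplotypes."""
    seqs = table.seqs
    if not seqs:
        raise ValueError("no haplotypes")
    M = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    d = (M[:, None, :] != M[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(list(table.ids), d)


# ---------------------------------------------------------------------------
# goeBURST minimum-spanning network


def _tiebreak_key(dm: DistanceMatrix, counts: dict):
    """Per-node goeBURST rank components: (-SLV, -DLV, -count, id)."""
    d = dm.d
    slv = (d == 1).sum(axis=1)
    dlv = (d == 2).sum(axis=1)
    keys = {}
    for i, hid in enumerate(dm.ids):
        keys[hid] = (-int(slv[i]), -int(dlv[i]), -counts[hid], hid)
    return keys


def goeburst_mst(table: HaplotypeTable, dm: DistanceMatrix) -> nx.Graph:
    """Kruskal MST with goeBURST tie-breaking; returns the full network.

    The returned graph holds every haplotype as a node (attributes: count,
    group if assigned later) and the MST edges flagged ``in_mst=True``.
    Deterministic for a given input order.
    """
    if set(dm.ids) != set(table.ids):
        raise ValueError("distance matrix does not cover the haplotype table")
    counts = dict(zip(table.ids, table.counts))
    keys = _tiebreak_key(dm, counts)

    G = nx.Graph()
    for hid, seq, count, members in table.haplotypes:
        G.add_node(hid, count=count, seq=seq)

    edges = []
    ids = dm.ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        u, v = ids[i], ids[j]
        # order the endpoint keys so the edge rank is endpoint-symmetric:
        # the better (smaller-key) endpoint decides first
        ku, kv = sorted((keys[u], keys[v]))
        edges.append((dm.d[i, j], ku, kv, u, v))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    uf = {hid: hid for hid in ids}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for w, _, _, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            uf[ru] = rv
            G.add_edge(u, v, weight=float(w), in_mst=True)
    return G


def mst_total_weight(G: nx.Graph) -> float:
    return sum(d["weight"] for _, _, d in G.edges(data=True) if d.get("in_mst"))


def group_min_steps(dm: DistanceMatrix, groups: dict) -> dict:
    """Minimum pairwise Hamming distance between every pair of groups."""
    unknown = [h for h in dm.ids if h not in groups]
    if unknown:
        raise ValueError(f"haplotypes without a group label: {unknown}")
    labels = sorted(set(groups.values()))
    members = {g: [i for i, h in enumerate(dm.ids) if groups[h] == g] for g in labels}
    out = {}
    for g1, g2 in itertools.combinations_with_replacement(labels, 2):
        sub = dm.d[np.ix_(members[g1], members[g2])]
        if g1 == g2:
            val = 0.0
        else:
            val = float(sub.min())
        out[(g1, g2)] = out[(g2, g1)] = val
    return out


def group_mst_path_steps(G: nx.Graph, groups: dict) -> dict:
    """Alternative reading: shortest MST path length between groups."""
    T = nx.Graph(
        (u, v, d) for u, v, d in G.edges(data=True) if d.get("in_mst")
    )
    T.add_nodes_from(G.nodes)
    labels = sorted(set(groups.values()))
    lengths = dict(nx.all_pairs_dijkstra_path_length(T, weight="weight"))
    out = {}
    for g1, g2 in itertools.combinations(labels, 2):
        best = math.inf
        for u in (h for h in G.nodes if groups[h] == g1):
            for v in (h for h in G.nodes if groups[h] == g2):
                best = min(best, lengths.get(u, {}).get(v, math.inf))
        out[(g1, g2)] = out[(g2, g1)] = best
    return out


# ---------------------------------------------------------------------------
# Kimura 2-parameter distances


def k2p_distance(a: str, b: str, ceiling: float = K2P_CEILING) -> float:
    """K2P distance with pairwise deletion of non-ACGT columns.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the transition and
    transversion proportions. Saturated pairs (log argument <= 0) are set to
    ``ceiling`` with a warning.
    """
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    purines = {"A", "G"}
    ts = tv = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        compared += 1
        if x != y:
            if (x in purines) == (y in purines):
                ts += 1
            else:
                tv += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / compared, tv / compared
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        logger.warning("K2P saturation; distance set to ceiling %.1f", ceiling)
        return ceiling
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(ids: list, seqs: list, ceiling: float = K2P_CEILING) -> DistanceMatrix:
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j], ceiling)
    return DistanceMatrix(list(ids), d)


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class PhyloTree:
    """Unrooted tree as an undirected graph with branch lengths."""

    graph: nx.Graph
    leaves: list = field(default_factory=list)

    def newick(self) -> str:
        # root arbitrarily at the highest-degree internal node (or the only
        # node) and serialize
        internal = [n for n in self.graph.nodes if n not in set(self.leaves)]
        root = internal[0] if internal else self.leaves[0]

        def rec(node, parent):
            children = [x for x in self.graph.neighbors(node) if x != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{rec(c, node)}:{self.graph[node][c]['length']:.6f}"
                for c in children
            )
            return f"({inner})"

        return rec(root, None) + ";"

    def path_length(self, u, v) -> float:
        return nx.shortest_path_length(self.graph, u, v, weight="length")


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining with nonnegative branch lengths.

    A negative branch estimate is clamped to zero and the deficit moved to
    the sister branch, preserving the pair's path length.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    ids = list(dm.ids)
    D = dm.d.copy()
    G = nx.Graph()
    active = list(range(n))
    labels = {i: ids[i] for i in range(n)}
    next_internal = 0

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        a, b = divmod(int(Q.argmin()), m)
        if a > b:
            a, b = b, a
        fa, fb = active[a], active[b]
        # branch lengths to the new node
        la = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = sub[a, b] - la
        # clamp negatives, transfer deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"_nj{next_internal}"
        next_internal += 1
        G.add_edge(labels[fa], new, length=la)
        G.add_edge(labels[fb], new, length=lb)
        # distances from the new node to the rest
        newrow = np.zeros(D.shape[0] + 1)
        for c in active:
            if c in (fa, fb):
                continue
            newrow[c] = 0.5 * (D[fa, c] + D[fb, c] - D[fa, fb])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow) - 1] = newrow[:-1]
        D[: len(newrow) - 1, -1] = newrow[:-1]
        idx_new = D.shape[0] - 1
        labels[idx_new] = new
        active = [c for c in active if c not in (fa, fb)] + [idx_new]

    fa, fb = active
    final = max(D[fa, fb], 0.0)
    G.add_edge(labels[fa], labels[fb], length=final)
    return PhyloTree(G, leaves=ids)


# ---------------------------------------------------------------------------
# Exports


def annotate_groups(G: nx.Graph, groups: dict) -> None:
    for node in G.nodes:
        G.nodes[node]["group"] = groups.get(node, "")


def write_graphml(G: nx.Graph, path) -> None:
    H = nx.Graph()
    for node, data in G.nodes(data=True):
        H.add_node(node, **{k: v for k, v in data.items() if k != "seq"})
    for u, v, data in G.edges(data=True):
        H.add_edge(u, v, **data)
    nx.write_graphml(H, path)


def write_dot(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("graph haplonet {\n")
        for node, data in G.nodes(data=True):
            attrs = f'label="{node} (n={data.get("count", 1)})"'
            if data.get("group"):
                attrs += f', group="{data["group"]}"'
            fh.write(f'  "{node}" [{attrs}];\n')
        for u, v, data in G.edges(data=True):
            style = "solid" if data.get("in_mst") else "dashed"
            fh.write(
                f'  "{u}" -- "{v}" [label="{int(data["weight"])}", style={style}];\n'
            )
        fh.write("}\n")
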