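"""Partition density and its maximization over d-sorted links.

For a link set of N links partitioned into connected components, where
component c has m_c links and n_c nodes, the partition density is

    D = (2 / N) * sum_c  m_c * (m_c - (n_c - 1)) / ((n_c - 1) * (n_c - 2))

with the sum restricted to components of more than two nodes.  A linear
chain (m_c = n_c - 1) contributes 0 and a complete clique
(m_c = n_c (n_c - 1) / 2) drives D to 1; D interpolates between these
extremes of link connectivity.

The optimizer streams links in ascending order of the distance d, maintains
connected components incrementally with a union-find structure carrying
per-component link and node tallies, records D after every distinct d value
(links tied in d enter as a block), and returns the partition at maximal D,
breaking ties toward the larger link count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "DensityProfile",
    "partition_density",
    "components",
    "optimize_over_d",
    "LinkUnionFind",
]

Node = Hashable


def _term(m: int, n: int) -> float:
    """Eq-style per-community density term; 0 for communities of <= 2 nodes."""
    if n <= 2:
        return 0.0
    return m * (m - (n - 1)) / ((n - 1) * (n - 2))


class LinkUnionFind:
    """Union-find over a fixed node set with per-component link/node tallies.

    Maintains the total per-component density term sum incrementally so the
    partition density of the current link set is O(1) to read.
    """

    def __init__(self, nodes: Sequence[Node]):
        self.nodes = list(nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.arange(n)
        self.rank = np.zeros(n, dtype=np.int32)
        self.n_nodes = np.ones(n, dtype=np.int64)
        self.m_links = np.zeros(n, dtype=np.int64)
        self.n_links_included = 0
        self.term_sum = 0.0

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    def add_link(self, u: Node, v: Node) -> None:
        iu, iv = self.index[u], self.index[v]
        ru, rv = self.find(iu), self.find(iv)
        self.n_links_included += 1
        if ru == rv:
            self.term_sum -= _term(self.m_links[ru], self.n_nodes[ru])
            self.m_links[ru] += 1
            self.term_sum += _term(self.m_links[ru], self.n_nodes[ru])
            return
        self.term_sum -= _term(self.m_links[ru], self.n_nodes[ru])
        self.term_sum -= _term(self.m_links[rv], self.n_nodes[rv])
        if self.rank[ru] < self.rank[rv]:
            ru, rv = rv, ru
        self.parent[rv] = ru
        if self.rank[ru] == self.rank[rv]:
            self.rank[ru] += 1
        self.n_nodes[ru] += self.n_nodes[rv]
        self.m_links[ru] += self.m_links[rv] + 1
        self.term_sum += _term(self.m_links[ru], self.n_nodes[ru])

    @property
    def density(self) -> float:
        if self.n_links_included == 0:
            return 0.0
        return 2.0 * self.term_sum / self.n_links_included

    def to_partition(self) -> "Partition":
        community_of = {v: int(self.find(i)) for i, v in enumerate(self.nodes)}
        return Partition.from_assignment(community_of, n_links_by_community=self._links_by_root())

    def _links_by_root(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i in range(len(self.nodes)):
            root = int(self.find(i))
            if self.parent[root] == root:
                out[root] = int(self.m_links[root])
        return out


@dataclass
class Partition:
    """Node -> community assignment with per-community link/node tallies."""

    community_of: dict[Node, int]
    m_c: dict[int, int] = field(default_factory=dict)  # links per community
    n_c: dict[int, int] = field(default_factory=dict)  # nodes per community

    @classmethod
    def from_assignment(
        cls,
        community_of: Mapping[Node, int],
        links: Iterable[tuple[Node, Node]] | None = None,
        n_links_by_community: Mapping[int, int] | None = None,
    ) -> "Partition":
        community_of = dict(community_of)
        n_c: dict[int, int] = {}
        for cid in community_of.values():
            n_c[cid] = n_c.get(cid, 0) + 1
        m_c: dict[int, int] = {cid: 0 for cid in n_c}
        if n_links_by_community is not None:
            for cid, m in n_links_by_community.items():
                m_c[cid] = int(m)
        elif links is not None:
            for u, v in links:
                cu, cv = community_of[u], community_of[v]
                if cu != cv:
                    raise ValueError(f"link ({u}, {v}) crosses communities {cu} and {cv}")
                m_c[cu] += 1
        return cls(community_of=community_of, m_c=m_c, n_c=n_c)

    @property
    def n_links_included(self) -> int:
        return sum(self.m_c.values())

    @property
    def n_communities(self) -> int:
        return len(self.n_c)

    def communities(self) -> dict[int, list[Node]]:
        out: dict[int, list[Node]] = {cid: [] for cid in self.n_c}
        for node, cid in self.community_of.items():
            out[cid].append(node)
        return out

    def density(self) -> float:
        return partition_density(self)

    def relabeled(self) -> "Partition":
        """Renumber communities 0..C-1 in order of first node appearance."""
        mapping: dict[int, int] = {}
        for node in sorted(self.community_of, key=str):
            cid = self.community_of[node]
            if cid not in mapping:
                mapping[cid] = len(mapping)
        return Partition(
            community_of={v: mapping[c] for v, c in self.community_of.items()},
            m_c={mapping[c]: m for c, m in self.m_c.items()},
            n_c={mapping[c]: n for c, n in self.n_c.items()},
        )


def partition_density(partition: Partition) -> float:
    """Partition density D of a partition with consistent tallies.

    N (the normalizing link count) is the number of links currently included
    in the partition, so the chain -> 0 and clique -> 1 limits hold for
    partial link sets.  An empty link set has D = 0 by convention.
    """
    n_links = partition.n_links_included
    if n_links == 0:
        return 0.0
    total = 0.0
    for cid, m in partition.m_c.items():
        total += _term(m, partition.n_c[cid])
    return 2.0 * total / n_links


def components(
    links: Iterable[tuple[Node, Node]] | pd.DataFrame,
    all_nodes: Iterable[Node],
) -> Partition:
    """Connected-component partition of ``all_nodes`` under ``links``.

    Nodes untouched by any link become singleton communities.
    """
    if isinstance(links, pd.DataFrame):
        links = list(zip(links["node_a"], links["node_b"]))
    uf = LinkUnionFind(list(all_nodes))
    for u, v in links:
        uf.add_link(u, v)
    return uf.to_partition()


@dataclass
class DensityProfile:
    """D recorded after each distinct d value during the link sweep."""

    table: pd.DataFrame  # columns: k (links included), d, D
    argmax_index: int

    @property
    def best_k(self) -> int:
        return int(self.table["k"].iloc[self.argmax_index])

    @property
    def best_d(self) -> float:
        return float(self.table["d"].iloc[self.argmax_index])

    @property
    def best_density(self) -> float:
        return float(self.table["D"].iloc[self.argmax_index])


def optimize_over_d(
    selection: pd.DataFrame,
    all_nodes: Iterable[Node],
) -> tuple[Partition, pd.DataFrame, DensityProfile]:
    """Sweep d-sorted links, maximizing partition density.

    ``selection`` is a scaled-link table sorted by ascending d.  Links tied
    at one d value are added as a block and D is evaluated only at distinct
    d values.  Returns the best partition (ties broken toward the larger
    link count), the retained prefix of ``selection``, and the full profile.
    """
    all_nodes = list(all_nodes)
    if len(selection) == 0:
        raise ValueError("cannot optimize over an empty link selection")
    d = selection["d"].to_numpy(dtype=float)
    if np.any(np.diff(d) < 0):
        raise ValueError("selection must be sorted by ascending d")
    ua = selection["node_a"].to_numpy()
    ub = selection["node_b"].to_numpy()
    uf = LinkUnionFind(all_nodes)
    rows = []
    best = (-np.inf, -1)  # (D, k)
    i = 0
    n = len(selection)
    while i < n:
        j = i
        while j < n and d[j] == d[i]:
            uf.add_link(ua[j], ub[j])
            j += 1
        density = uf.density
        rows.append((j, float(d[i]), density))
        if density >= best[0] - 1e-15:
            if density > best[0] + 1e-15 or j > best[1]:
                best = (density, j)
        i = j
    table = pd.DataFrame(rows, columns=["k", "d", "D"])
    argmax_index = int(table.index[table["k"] == best[1]][0])
    profile = DensityProfile(table=table, argmax_index=argmax_index)
    retained = selection.iloc[: best[1]].reset_index(drop=True)
    best_partition = components(retained, all_nodes)
    return best_partition, retained, profile
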