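"""Unrooted phylogenetic trees represented as split systems.

A :class:`PhyloTree` stores a leaf-label set plus the non-trivial
bipartitions (splits) of the topology, each normalized as the side that
excludes the alphabetically first taxon, encoded as an integer bitmask over
the sorted taxon list.  This makes split-level operations (strict consensus,
congruence indices, support-based collapsing) exact set algebra, while an
adjacency view is materialized on demand for traversal-based algorithms
(parsimony, quartet distances).  Newick parsing and writing go through
dendropy.
"""

from __future__ import annotations

import itertools
from collections import deque
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeError",
    "strict_consensus",
    "enumerate_topologies",
    "random_resolved_tree",
]


class TreeError(ValueError):
    """Raised for malformed or incompatible tree inputs."""


def _popcount(x: int) -> int:
    return bin(x).count("1")


class PhyloTree:
    """An unrooted leaf-labelled tree (possibly multifurcating).

    Parameters
    ----------
    taxa : sequence of str
        Leaf labels; stored sorted.  Labels must be unique.
    clades : iterable of int
        Non-trivial splits as bitmasks over the *sorted* taxon order,
        normalized to the side excluding taxon 0.  Trivial splits are
        silently dropped.
    support : mapping int -> float, optional
        Per-split support values (e.g. posterior probabilities), keyed by
        normalized split mask.
    """

    __slots__ = ("taxa", "clades", "support", "_index", "_adj_cache")

    def __init__(
        self,
        taxa: Sequence[str],
        clades: Iterable[int] = (),
        support: Mapping[int, float] | None = None,
    ):
        taxa = tuple(sorted(taxa))
        if len(set(taxa)) != len(taxa):
            raise TreeError("duplicate leaf labels")
        if len(taxa) < 2:
            raise TreeError("a tree needs at least 2 leaves")
        self.taxa = taxa
        n = len(taxa)
        full = (1 << n) - 1
        norm = set()
        for m in clades:
            if m & 1:
                m ^= full
            p = _popcount(m)
            if 2 <= p <= n - 2:
                norm.add(m)
        self.clades = frozenset(norm)
        self.support = dict(support) if support else {}
        self._index = {t: i for i, t in enumerate(taxa)}
        self._adj_cache = None
        self._check_compatible()

    # ------------------------------------------------------------------
    # basics

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def is_resolved(self) -> bool:
        """True when fully bifurcating (n-3 non-trivial splits)."""
        return len(self.clades) == max(self.n_taxa - 3, 0)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PhyloTree)
            and self.taxa == other.taxa
            and self.clades == other.clades
        )

    def __hash__(self):
        return hash((self.taxa, self.clades))

    def __repr__(self):
        return f"<PhyloTree n_taxa={self.n_taxa} n_splits={len(self.clades)}>"

    def _check_compatible(self):
        # pairwise compatibility guarantees the splits form a tree
        cl = sorted(self.clades)
        full = (1 << self.n_taxa) - 1
        for a, b in itertools.combinations(cl, 2):
            if a & b and a | b != full and (a & b) not in (a, b):
                raise TreeError("incompatible splits do not form a tree")

    # ------------------------------------------------------------------
    # constructors

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls.from_dendropy(t)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise TreeError("unlabelled leaf")
        taxa = tuple(sorted(labels))
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        full = (1 << n) - 1
        clades: dict[int, float | None] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node._mask = 1 << idx[node.taxon.label]
                continue
            m = 0
            for ch in node.child_nodes():
                m |= ch._mask
            node._mask = m
            norm = m ^ full if m & 1 else m
            p = _popcount(norm)
            if 2 <= p <= n - 2:
                sup = None
                if node.label is not None:
                    try:
                        sup = float(node.label)
                    except ValueError:
                        sup = None
                if norm not in clades or clades[norm] is None:
                    clades[norm] = sup
        support = {m: s for m, s in clades.items() if s is not None}
        return cls(taxa, clades.keys(), support)

    # ------------------------------------------------------------------
    # adjacency view

    def adjacency(self) -> dict[int, list[int]]:
        """Adjacency lists; leaves are nodes ``0..n-1`` in sorted-taxon order."""
        if self._adj_cache is None:
            self._adj_cache = _adjacency_from_clades(self.n_taxa, self.clades)
        return {k: list(v) for k, v in self._adj_cache.items()}

    @classmethod
    def from_adjacency(
        cls, adj: Mapping[int, Sequence[int]], taxa: Sequence[str]
    ) -> "PhyloTree":
        """Build from adjacency lists whose leaves ``0..n-1`` follow *taxa* order.

        *taxa* need not be sorted; leaf ids are remapped to the sorted order.
        """
        n = len(taxa)
        order = sorted(range(n), key=lambda i: taxa[i])
        rank = {old: new for new, old in enumerate(order)}
        clades = []
        for child_mask in _edge_masks(adj, n):
            m = 0
            b = child_mask
            while b:
                low = b & -b
                m |= 1 << rank[int(low).bit_length() - 1]
                b ^= low
            clades.append(m)
        return cls(taxa, clades)

    # ------------------------------------------------------------------
    # manipulation

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Restriction to a leaf subset (splits projected, trivia dropped)."""
        keep = [t for t in self.taxa if t in set(keep)]
        if len(keep) < 2:
            raise TreeError("restriction needs at least 2 retained leaves")
        old = [self._index[t] for t in keep]
        clades = []
        for m in self.clades:
            pm = 0
            for new_i, old_i in enumerate(old):
                if m >> old_i & 1:
                    pm |= 1 << new_i
            clades.append(pm)
        return PhyloTree(keep, clades)

    def rooted_clades(self, root_taxon: str) -> set[int]:
        """Splits re-expressed as clades of the tree rooted at *root_taxon*.

        Each split contributes the side that excludes the root leaf.
        """
        if root_taxon not in self._index:
            raise TreeError(f"root taxon {root_taxon!r} not in tree")
        rbit = 1 << self._index[root_taxon]
        full = (1 << self.n_taxa) - 1
        return {m ^ full if m & rbit else m for m in self.clades}

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for l in labels:
            m |= 1 << self._index[l]
        return m

    def labels_of(self, mask: int) -> frozenset:
        return frozenset(t for i, t in enumerate(self.taxa) if mask >> i & 1)

    # ------------------------------------------------------------------
    # distances / newick

    def topo_distances(self) -> np.ndarray:
        """All-pairs leaf-to-leaf path lengths in edges (unit branch lengths)."""
        adj = self.adjacency()
        n = self.n_taxa
        n_nodes = 1 + max(adj)
        out = np.zeros((n, n), dtype=np.int32)
        for src in range(n):
            dist = np.full(n_nodes, -1, dtype=np.int32)
            dist[src] = 0
            q = deque([src])
            while q:
                u = q.popleft()
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        q.append(v)
            out[src] = dist[:n]
        return out

    def to_newick(self, include_support: bool = False) -> str:
        adj = self.adjacency()
        root = adj[0][0]  # internal node adjacent to leaf 0
        full = (1 << self.n_taxa) - 1

        def sub(node: int, parent: int) -> tuple[str, int]:
            if node < self.n_taxa:
                return self.taxa[node], 1 << node
            parts, mask = [], 0
            for nb in adj[node]:
                if nb == parent:
                    continue
                s, m = sub(nb, node)
                parts.append(s)
                mask |= m
            lab = ""
            if include_support:
                norm = mask ^ full if mask & 1 else mask
                if norm in self.support:
                    lab = format(self.support[norm], "g")
            return "(" + ",".join(parts) + ")" + lab, mask

        if self.n_taxa == 2:
            return f"({self.taxa[0]},{self.taxa[1]});"
        parts = [self.taxa[0]]
        for nb in adj[root]:
            if nb != 0:
                parts.append(sub(nb, root)[0])
        return "(" + ",".join(parts) + ");"

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(include_support=True),
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )


# ----------------------------------------------------------------------
# helpers


def _edge_masks(adj: Mapping[int, Sequence[int]], n_leaves: int) -> list[int]:
    """Leaf bitmask below each internal edge, rooted at leaf 0 (raw leaf ids)."""
    masks = []
    seen_mask: dict[int, int] = {}
    order, parent = postorder(adj, root=0)
    for node in order:
        if node < n_leaves:
            seen_mask[node] = 1 << node
        else:
            m = 0
            for nb in adj[node]:
                if nb != parent[node]:
                    m |= seen_mask[nb]
            seen_mask[node] = m
            masks.append(m)
    return masks


def postorder(
    adj: Mapping[int, Sequence[int]], root: int = 0
) -> tuple[list[int], dict[int, int]]:
    """Iterative postorder node list and parent map, rooted at *root*."""
    parent = {root: -1}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    order.reverse()
    return order, parent


def _adjacency_from_clades(n: int, clades: Iterable[int]) -> dict[int, list[int]]:
    """Build adjacency lists realizing a compatible split set.

    Leaves are nodes ``0..n-1``; internal nodes get ids from ``n`` upward.
    """
    full = (1 << n) - 1
    root_mask = full ^ 1
    # node records: mask -> children masks; insert descending by size
    children: dict[int, list[int]] = {root_mask: []}
    ordered = sorted(set(clades), key=_popcount, reverse=True)
    for cl in ordered:
        node = root_mask
        while True:
            nxt = next(
                (c for c in children[node] if c & cl == cl and c != cl), None
            )
            if nxt is None:
                break
            node = nxt
        children[cl] = []
        children[node].append(cl)
    for i in range(1, n):
        bit = 1 << i
        node = root_mask
        while True:
            nxt = next((c for c in children[node] if c & bit), None)
            if nxt is None:
                break
            node = nxt
        children[node].append(bit)

    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    next_id = n

    def build(mask: int) -> int:
        nonlocal next_id
        if _popcount(mask) == 1:
            return mask.bit_length() - 1
        me = next_id
        next_id += 1
        adj[me] = []
        for cm in children[mask]:
            ch = build(cm)
            adj[me].append(ch)
            adj[ch].append(me)
        return me

    root_id = build(root_mask)
    adj[0].append(root_id)
    adj[root_id].append(0)
    return adj


# ----------------------------------------------------------------------
# module-level operations


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise TreeError("strict consensus of an empty tree set")
    taxa = trees[0].taxa
    if any(t.taxa != taxa for t in trees):
        raise TreeError("strict consensus requires identical leaf sets")
    common = frozenset.intersection(*(t.clades for t in trees))
    return PhyloTree(taxa, common)


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """All distinct unrooted binary topologies (1, 3, 15, 105, 945, ... trees)."""
    taxa = tuple(sorted(taxa))
    n = len(taxa)
    if n < 3:
        yield PhyloTree(taxa)
        return
    for adj in _enumerate_adj(n):
        yield PhyloTree.from_adjacency(adj, taxa)


def _enumerate_adj(n: int) -> Iterator[dict[int, list[int]]]:
    hub = n
    base = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}

    def rec(adj, leaf, next_internal):
        if leaf == n:
            yield adj
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        for u, v in edges:
            w = next_internal
            adj2 = {k: list(vs) for k, vs in adj.items()}
            adj2[u][adj2[u].index(v)] = w
            adj2[v][adj2[v].index(u)] = w
            adj2[w] = [u, v, leaf]
            adj2[leaf] = [w]
            yield from rec(adj2, leaf + 1, next_internal + 1)

    yield from rec(base, 3, n + 1)


def random_resolved_tree(taxa: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform-ish random binary topology via random sequential addition."""
    taxa = tuple(sorted(taxa))
    n = len(taxa)
    if n < 4:
        return PhyloTree(taxa)
    order = [int(i) for i in rng.permutation(n)]
    a, b, c = order[:3]
    hub = n
    adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    nxt = n + 1
    for leaf in order[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = nxt
        nxt += 1
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
    return PhyloTree.from_adjacency(adj, taxa)
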