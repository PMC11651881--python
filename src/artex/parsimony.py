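"""Implied-weights parsimony: character fits, heuristic search, consensus,
and most-parsimonious ancestral state sets.

Scoring model
-------------
For each character, ``s`` is its minimum number of changes on a given tree
(Fitch/Hartigan counting for unordered characters, a linear-cost Wagner
dynamic program for ordered ones), ``m`` its minimum over all possible
trees, and ``e = s - m`` its extra (homoplastic) steps.  The Goloboff fit
is ``f = k / (k + e)`` with concavity ``k`` (default 1), and the search
objective is the total fit ``F = sum_c f_c``, maximized.  Characters whose
extra steps are identically zero on every topology (constant,
autapomorphic, or otherwise parsimony-uninformative characters) carry a
constant fit of 1 and are excluded from the search's inner loop.

The heuristic search uses random-addition-sequence starting trees refined
by SPR or TBR branch swapping (first-improvement, seeded ordering), holds
all distinct topologies tied at the best fit found, and is exactly
reproducible for a given seed.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass

import numpy as np

from .matrix import GAP, CharacterMatrix, MatrixError
from .treeutils import (
    PhyloTree,
    TreeError,
    _enumerate_adj,
    postorder,
    strict_consensus,
)

__all__ = [
    "CharacterFit",
    "ParsimonyScore",
    "SearchConfig",
    "SearchResult",
    "char_steps",
    "min_steps",
    "iw_score",
    "search",
    "exhaustive_search",
    "strict_consensus",
    "ancestral_states",
]

_TOL = 1e-9
_FULL_MASK = (1 << 10) - 1
_INF = 10**9

try:  # optional JIT for the search inner loop; the numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _steps_kernel(
    kids, kids_off, n_leaves, tips_u, tips_lo, tips_hi, steps_u, steps_o
):
    """Fitch (unordered) and interval (ordered) step counts, postorder.

    ``kids``/``kids_off`` flatten per-entry child references: a reference
    ``r < n_leaves`` is a leaf (tip row), otherwise internal entry
    ``r - n_leaves``.  The final entry merges the root leaf with the rest.
    """
    n_entries = kids_off.shape[0] - 1
    n_u = tips_u.shape[1]
    n_o = tips_lo.shape[1]
    st_u = np.empty((n_entries, n_u), dtype=np.int16)
    st_lo = np.empty((n_entries, n_o), dtype=np.int8)
    st_hi = np.empty((n_entries, n_o), dtype=np.int8)
    for e in range(n_entries):
        first = True
        for ci in range(kids_off[e], kids_off[e + 1]):
            r = kids[ci]
            if first:
                if r < n_leaves:
                    for j in range(n_u):
                        st_u[e, j] = tips_u[r, j]
                    for j in range(n_o):
                        st_lo[e, j] = tips_lo[r, j]
                        st_hi[e, j] = tips_hi[r, j]
                else:
                    s = r - n_leaves
                    for j in range(n_u):
                        st_u[e, j] = st_u[s, j]
                    for j in range(n_o):
                        st_lo[e, j] = st_lo[s, j]
                        st_hi[e, j] = st_hi[s, j]
                first = False
                continue
            if r < n_leaves:
                for j in range(n_u):
                    a = st_u[e, j]
                    b = tips_u[r, j]
                    inter = a & b
                    if inter == 0:
                        steps_u[j] += 1
                        st_u[e, j] = a | b
                    else:
                        st_u[e, j] = inter
                for j in range(n_o):
                    lo = max(st_lo[e, j], tips_lo[r, j])
                    hi = min(st_hi[e, j], tips_hi[r, j])
                    if lo > hi:
                        steps_o[j] += lo - hi
                        st_lo[e, j] = hi
                        st_hi[e, j] = lo
                    else:
                        st_lo[e, j] = lo
                        st_hi[e, j] = hi
            else:
                s = r - n_leaves
                for j in range(n_u):
                    a = st_u[e, j]
                    b = st_u[s, j]
                    inter = a & b
                    if inter == 0:
                        steps_u[j] += 1
                        st_u[e, j] = a | b
                    else:
                        st_u[e, j] = inter
                for j in range(n_o):
                    lo = max(st_lo[e, j], st_lo[s, j])
                    hi = min(st_hi[e, j], st_hi[s, j])
                    if lo > hi:
                        steps_o[j] += lo - hi
                        st_lo[e, j] = hi
                        st_hi[e, j] = lo
                    else:
                        st_lo[e, j] = lo
                        st_hi[e, j] = hi


# ----------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class CharacterFit:
    index: int
    steps: int
    min_steps: int
    extra: int
    fit: float


@dataclass
class ParsimonyScore:
    total_fit: float
    per_character: list
    k: float

    @property
    def total_steps(self) -> int:
        return sum(c.steps for c in self.per_character)


@dataclass
class SearchConfig:
    k: float = 1.0
    n_addition_replicates: int = 10
    swap: str = "tbr"
    max_trees_held: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("concavity k must be positive")
        if self.n_addition_replicates < 1:
            raise ValueError("need at least one addition replicate")
        if self.swap not in ("spr", "tbr"):
            raise ValueError("swap must be 'spr' or 'tbr'")


@dataclass
class SearchResult:
    trees: list
    best_fit: float
    overflowed: bool = False

    def __len__(self):
        return len(self.trees)


# ----------------------------------------------------------------------
# cell -> state-set helpers


def _tip_mask(cell) -> int:
    if cell is None or cell == GAP:
        return _FULL_MASK
    if isinstance(cell, frozenset):
        m = 0
        for s in cell:
            m |= 1 << s
        return m
    return 1 << cell


def _tip_interval(cell, max_state: int = 9) -> tuple[int, int]:
    if cell is None or cell == GAP:
        return (0, max_state)
    if isinstance(cell, frozenset):
        return (min(cell), max(cell))
    return (cell, cell)


def _tip_states(cell, max_state: int = 9) -> frozenset:
    if cell is None or cell == GAP:
        return frozenset(range(max_state + 1))
    if isinstance(cell, frozenset):
        return cell
    return frozenset((cell,))


# ----------------------------------------------------------------------
# per-character step counts on a given tree


def _leaf_rows(tree: PhyloTree, matrix: CharacterMatrix) -> list[int]:
    rows = []
    for t in tree.taxa:
        try:
            rows.append(matrix.taxa.index(t))
        except ValueError:
            raise MatrixError(f"tree leaf {t!r} has no matrix row") from None
    return rows

def char_steps(tree: PhyloTree, matrix: CharacterMatrix, char: int) -> int:
    """Minimum changes of character *char* on *tree* (handles polytomies).

    Unordered characters use Hartigan's counting generalization of the
    Fitch algorithm; ordered characters a linear-cost dynamic program.
    Missing and polymorphic tips contribute their state sets.
    """
    rows = _leaf_rows(tree, matrix)
    cells = [matrix.cells[r][char] for r in rows]
    if all(c is None or c == GAP for c in cells):
        return 0
    adj = tree.adjacency()
    if matrix.ordered[char]:
        return _ordered_steps_dp(adj, tree.n_taxa, cells)
    return _hartigan_steps(adj, tree.n_taxa, [_tip_mask(c) for c in cells])


def _hartigan_steps(adj, n_leaves: int, tipmasks: list[int]) -> int:
    order, parent = postorder(adj, root=0)
    sets: dict[int, int] = {}
    steps = 0
    for node in order:
        if node < n_leaves and node != 0:
            sets[node] = tipmasks[node]
            continue
        if node == 0:
            children_sets = [tipmasks[0], sets[adj[0][0]]]
        else:
            children_sets = [
                sets[nb] for nb in adj[node] if nb != parent[node]
            ]
        counts: dict[int, int] = {}
        for cs in children_sets:
            b = cs
            while b:
                low = b & -b
                counts[low] = counts.get(low, 0) + 1
                b ^= low
        kmax = max(counts.values())
        vu = 0
        for bit, c in counts.items():
            if c == kmax:
                vu |= bit
        sets[node] = vu
        steps += len(children_sets) - kmax
    return steps


def _ordered_steps_dp(adj, n_leaves: int, cells) -> int:
    smax = 0
    for c in cells:
        if c is not None and c != GAP:
            smax = max(smax, max(c) if isinstance(c, frozenset) else c)
    n_states = smax + 1
    states = np.arange(n_states)
    cost_step = np.abs(states[:, None] - states[None, :])  # |i - j|

    def tipcost(leaf) -> np.ndarray:
        allowed = _tip_states(cells[leaf], smax)
        v = np.full(n_states, _INF, dtype=np.int64)
        v[[s for s in allowed if s <= smax]] = 0
        return v

    order, parent = postorder(adj, root=0)
    down: dict[int, np.ndarray] = {}
    for node in order:
        if node < n_leaves and node != 0:
            down[node] = tipcost(node)
            continue
        if node == 0:
            acc = tipcost(0) + np.min(cost_step + down[adj[0][0]][None, :], axis=1)
            return int(acc.min())
        acc = np.zeros(n_states, dtype=np.int64)
        for nb in adj[node]:
            if nb != parent[node]:
                acc = acc + np.min(cost_step + down[nb][None, :], axis=1)
        down[node] = np.minimum(acc, _INF)
    raise AssertionError("unreachable")


# ----------------------------------------------------------------------
# minimum steps over all trees


def min_steps(matrix: CharacterMatrix, char: int) -> int:
    """Minimum changes of a character on *any* tree (homoplasy baseline)."""
    cells = [row[char] for row in matrix.cells]
    observed = [c for c in cells if c is not None and c != GAP]
    if len(observed) <= 1:
        return 0
    if matrix.ordered[char]:
        los, his = zip(*(_tip_interval(c) for c in observed))
        return max(0, max(los) - min(his))
    masks = [_tip_mask(c) for c in observed]
    union = 0
    for m in masks:
        union |= m
    bits = [1 << i for i in range(10) if union >> i & 1]
    # exact minimum hitting set over <=10 states
    for r in range(1, len(bits) + 1):
        for combo in itertools.combinations(bits, r):
            pick = 0
            for b in combo:
                pick |= b
            if all(m & pick for m in masks):
                return r - 1
    return len(bits) - 1  # unreachable in practice


# ----------------------------------------------------------------------
# implied-weights score of one tree


def iw_score(tree: PhyloTree, matrix: CharacterMatrix, k: float = 1.0) -> ParsimonyScore:
    """Goloboff total fit ``F = sum_c k/(k + e_c)`` of *tree* under concavity *k*."""
    if k <= 0:
        raise ValueError("concavity k must be positive")
    fits = []
    total = 0.0
    for j in range(matrix.n_char):
        s = char_steps(tree, matrix, j)
        m = min_steps(matrix, j)
        e = max(s - m, 0)
        f = k / (k + e)
        fits.append(CharacterFit(index=j, steps=s, min_steps=m, extra=e, fit=f))
        total += f
    return ParsimonyScore(total_fit=total, per_character=fits, k=k)


# ----------------------------------------------------------------------
# fast encoded scoring for tree search


class _Encoded:
    """Deduplicated, vectorized character patterns for one matrix.

    Leaf ids follow ``sorted(matrix.taxa)`` so that scored adjacencies can
    be converted to :class:`PhyloTree` directly.
    """

    def __init__(self, matrix: CharacterMatrix, k: float):
        self.k = float(k)
        self.taxa = tuple(sorted(matrix.taxa))
        rows = [matrix.taxa.index(t) for t in self.taxa]
        n = len(rows)
        u_patterns: dict[tuple, list] = {}
        o_patterns: dict[tuple, list] = {}
        base = 0.0
        for j in range(matrix.n_char):
            cells = [matrix.cells[r][j] for r in rows]
            observed = [c for c in cells if c is not None and c != GAP]
            if len(observed) <= 1:
                base += 1.0
                continue
            if matrix.ordered[j]:
                ivs = tuple(_tip_interval(c) for c in cells)
                los, his = zip(*(_tip_interval(c) for c in observed))
                if max(los) <= min(his):  # a state satisfies every tip
                    base += 1.0
                    continue
                o_patterns.setdefault(ivs, [0, j])[0] += 1
            else:
                masks = tuple(_tip_mask(c) for c in cells)
                inter = _FULL_MASK
                for c in observed:
                    inter &= _tip_mask(c)
                if inter:
                    base += 1.0
                    continue
                if not any(isinstance(c, frozenset) for c in observed):
                    counts: dict[int, int] = {}
                    for c in observed:
                        counts[c] = counts.get(c, 0) + 1
                    if sum(1 for v in counts.values() if v >= 2) <= 1:
                        base += 1.0  # steps equal the minimum on every tree
                        continue
                u_patterns.setdefault(masks, [0, j])[0] += 1
        self.base_fit = base
        self.n_leaves = n

        def _m_of(j):
            return min_steps(matrix, j)

        if u_patterns:
            keys = list(u_patterns)
            self.u_tip = np.ascontiguousarray(np.array(keys, dtype=np.int16).T)  # (n, n_u)
            self.u_w = np.array([u_patterns[p][0] for p in keys], dtype=np.float64)
            self.u_m = np.array(
                [_m_of(u_patterns[p][1]) for p in keys], dtype=np.int64
            )
        else:
            self.u_tip = np.zeros((n, 0), dtype=np.int16)
            self.u_w = np.zeros(0)
            self.u_m = np.zeros(0, dtype=np.int64)
        if o_patterns:
            keys = list(o_patterns)
            lo = np.array([[iv[0] for iv in p] for p in keys], dtype=np.int8)
            hi = np.array([[iv[1] for iv in p] for p in keys], dtype=np.int8)
            self.o_lo = np.ascontiguousarray(lo.T)  # (n, n_o)
            self.o_hi = np.ascontiguousarray(hi.T)
            self.o_w = np.array([o_patterns[p][0] for p in keys], dtype=np.float64)
            self.o_m = np.array(
                [_m_of(o_patterns[p][1]) for p in keys], dtype=np.int64
            )
        else:
            self.o_lo = np.zeros((n, 0), dtype=np.int8)
            self.o_hi = np.zeros((n, 0), dtype=np.int8)
            self.o_w = np.zeros(0)
            self.o_m = np.zeros(0, dtype=np.int64)
        self.n_u = self.u_w.size
        self.n_o = self.o_w.size

    def _fit_total(self, steps_u, steps_o) -> float:
        k = self.k
        total = self.base_fit
        if self.n_u:
            e = np.maximum(steps_u - self.u_m, 0)
            total += float(np.sum(self.u_w * (k / (k + e))))
        if self.n_o:
            e = np.maximum(steps_o - self.o_m, 0)
            total += float(np.sum(self.o_w * (k / (k + e))))
        return total

    def _flatten(self, adj):
        """Postorder entry/children arrays for the JIT kernel."""
        n_leaves = self.n_leaves
        root = min(n for n in adj if n < n_leaves)
        order, parent = postorder(adj, root=root)
        slot: dict[int, int] = {}
        kids_flat: list[int] = []
        off = [0]
        s = 0
        for node in order:
            if node < n_leaves and node != root:
                continue
            if node == root:
                child = adj[root][0]
                refs = [
                    root,
                    child if child < n_leaves else n_leaves + slot[child],
                ]
            else:
                refs = [
                    nb if nb < n_leaves else n_leaves + slot[nb]
                    for nb in adj[node]
                    if nb != parent[node]
                ]
                slot[node] = s
                s += 1
            kids_flat.extend(refs)
            off.append(len(kids_flat))
        return (
            np.array(kids_flat, dtype=np.int64),
            np.array(off, dtype=np.int64),
        )

    def score(self, adj) -> float:
        """Total implied-weights fit of one (partial or complete) binary tree."""
        if _HAVE_NUMBA:
            kids, off = self._flatten(adj)
            steps_u = np.zeros(self.n_u, dtype=np.int64)
            steps_o = np.zeros(self.n_o, dtype=np.int64)
            _steps_kernel(
                kids, off, self.n_leaves, self.u_tip, self.o_lo, self.o_hi,
                steps_u, steps_o,
            )
            return self._fit_total(steps_u, steps_o)
        return self._score_numpy(adj)

    def _score_numpy(self, adj) -> float:
        n_leaves = self.n_leaves
        root = min(k for k in adj if k < n_leaves)
        order, parent = postorder(adj, root=root)
        steps_u = np.zeros(self.n_u, dtype=np.int64)
        steps_o = np.zeros(self.n_o, dtype=np.int64)
        su: dict[int, np.ndarray] = {}
        slo: dict[int, np.ndarray] = {}
        shi: dict[int, np.ndarray] = {}

        def fetch(node):
            if node < n_leaves:
                return self.u_tip[node], self.o_lo[node], self.o_hi[node]
            return su[node], slo[node], shi[node]

        for node in order:
            if node < n_leaves and node != root:
                continue
            nbs = (
                [adj[root][0]]
                if node == root
                else [nb for nb in adj[node] if nb != parent[node]]
            )
            if node == root:
                acc_u, acc_lo, acc_hi = (
                    self.u_tip[root],
                    self.o_lo[root],
                    self.o_hi[root],
                )
            else:
                acc_u, acc_lo, acc_hi = fetch(nbs[0])
                nbs = nbs[1:]
            for nb in nbs:
                cu, clo, chi = fetch(nb)
                if self.n_u:
                    inter = acc_u & cu
                    zero = inter == 0
                    if zero.any():
                        steps_u += zero
                        acc_u = np.where(zero, acc_u | cu, inter)
                    else:
                        acc_u = inter
                if self.n_o:
                    lo2 = np.maximum(acc_lo, clo)
                    hi2 = np.minimum(acc_hi, chi)
                    gap = lo2 - hi2
                    disjoint = gap > 0
                    if disjoint.any():
                        steps_o += np.where(disjoint, gap, 0)
                        acc_lo, acc_hi = (
                            np.where(disjoint, hi2, lo2),
                            np.where(disjoint, lo2, hi2),
                        )
                    else:
                        acc_lo, acc_hi = lo2, hi2
            su[node], slo[node], shi[node] = acc_u, acc_lo, acc_hi
        return self._fit_total(steps_u, steps_o)


# ----------------------------------------------------------------------
# neighborhoods


def _copy_adj(adj):
    return {k: list(v) for k, v in adj.items()}


def _component(adj, start, blocked):
    seen = {blocked, start}
    out = [start]
    q = deque([start])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                out.append(v)
                q.append(v)
    return out


def _spr_neighbors(adj):
    """Yield adjacency dicts one SPR move away (copies; may repeat topologies)."""
    pairs = [
        (u, v) for u in adj for v in adj[u] if len(adj[v]) == 3
    ]
    for u, v in pairs:
        a, b = (x for x in adj[v] if x != u)
        comp = _component(adj, v, blocked=u)
        comp_set = set(comp)
        edges = [
            (x, y)
            for x in comp
            if x != v
            for y in adj[x]
            if x < y and y != v and y in comp_set
        ]
        edges.append((min(a, b), max(a, b)))
        for x, y in edges:
            if {x, y} == {a, b}:
                continue  # reattachment at the original edge: same tree
            adj2 = _copy_adj(adj)
            adj2[a][adj2[a].index(v)] = b
            adj2[b][adj2[b].index(v)] = a
            adj2[v] = [u, x, y]
            adj2[x][adj2[x].index(y)] = v
            adj2[y][adj2[y].index(x)] = v
            yield adj2


def _tbr_neighbors(adj):
    """Yield adjacency dicts one TBR move away (superset of SPR)."""
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    for u, v in edges:
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue  # leaf-side bisections are covered by SPR below
        side_u = [x for x in _component(adj, u, blocked=v) if x != u]
        side_v = [x for x in _component(adj, v, blocked=u) if x != v]
        pu = [x for x in adj[u] if x != v]
        pv = [x for x in adj[v] if x != u]
        su = set(side_u)
        sv = set(side_v)
        eu = [
            (x, y) for x in side_u for y in adj[x] if x < y and y != u and y in su
        ] + [(min(pu), max(pu))]
        ev = [
            (x, y) for x in side_v for y in adj[x] if x < y and y != v and y in sv
        ] + [(min(pv), max(pv))]
        for x1, y1 in eu:
            for x2, y2 in ev:
                if {x1, y1} == set(pu) and {x2, y2} == set(pv):
                    continue  # original tree
                adj2 = _copy_adj(adj)
                # smooth u and v out of their original positions
                adj2[pu[0]][adj2[pu[0]].index(u)] = pu[1]
                adj2[pu[1]][adj2[pu[1]].index(u)] = pu[0]
                adj2[pv[0]][adj2[pv[0]].index(v)] = pv[1]
                adj2[pv[1]][adj2[pv[1]].index(v)] = pv[0]
                adj2[u] = [v, x1, y1]
                adj2[x1][adj2[x1].index(y1)] = u
                adj2[y1][adj2[y1].index(x1)] = u
                adj2[v] = [u, x2, y2]
                adj2[x2][adj2[x2].index(y2)] = v
                adj2[y2][adj2[y2].index(x2)] = v
                yield adj2
    yield from _spr_neighbors(adj)


# ----------------------------------------------------------------------
# search


def _stepwise_addition(enc: _Encoded, rng: np.random.Generator):
    n = enc.n_leaves
    order = [int(i) for i in rng.permutation(n)]
    a, b, c = order[:3]
    hub = n
    adj = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_id = n + 1
    for leaf in order[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        w = next_id
        best, best_F = [], -np.inf
        for u, v in edges:
            adj[u][adj[u].index(v)] = w
            adj[v][adj[v].index(u)] = w
            adj[w] = [u, v, leaf]
            adj[leaf] = [w]
            F = enc.score(adj)
            adj[u][adj[u].index(w)] = v
            adj[v][adj[v].index(w)] = u
            del adj[w], adj[leaf]
            if F > best_F + _TOL:
                best, best_F = [(u, v)], F
            elif F >= best_F - _TOL:
                best.append((u, v))
        u, v = best[rng.integers(len(best))]
        adj[u][adj[u].index(v)] = w
        adj[v][adj[v].index(u)] = w
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
        next_id += 1
    return adj


def _canon_key(adj, n_leaves):
    from .treeutils import _edge_masks

    masks = []
    full = (1 << n_leaves) - 1
    for m in _edge_masks(adj, n_leaves):
        if m & 1:
            m ^= full
        if 2 <= bin(m).count("1") <= n_leaves - 2:
            masks.append(m)
    return tuple(sorted(masks))


def _swap_to_optimum(enc, adj, rng, swap: str):
    neighbor_fn = _spr_neighbors if swap == "spr" else _tbr_neighbors
    cur_F = enc.score(adj)
    while True:
        neighbors = list(neighbor_fn(adj))
        idx = rng.permutation(len(neighbors))
        improved = False
        scores = {}
        for i in idx:
            F = enc.score(neighbors[i])
            scores[i] = F
            if F > cur_F + _TOL:
                adj, cur_F = neighbors[i], F
                improved = True
                break
        if not improved:
            ties = [
                neighbors[i] for i, F in scores.items() if abs(F - cur_F) <= _TOL
            ]
            return adj, cur_F, ties


def search(matrix: CharacterMatrix, config: SearchConfig | None = None) -> SearchResult:
    """Heuristic implied-weights parsimony search (seeded, deterministic)."""
    if config is None:
        config = SearchConfig()
    if matrix.n_taxa < 4:
        raise MatrixError("tree search needs at least 4 taxa")
    enc = _Encoded(matrix, config.k)
    rng = np.random.default_rng(config.seed)
    best_F = -np.inf
    pool: dict[tuple, dict] = {}
    overflowed = False
    for _ in range(config.n_addition_replicates):
        adj = _stepwise_addition(enc, rng)
        adj, F, ties = _swap_to_optimum(enc, adj, rng, config.swap)
        if F > best_F + _TOL:
            best_F = F
            pool = {}
        if F >= best_F - _TOL:
            for cand in [adj] + ties:
                key = _canon_key(cand, enc.n_leaves)
                if key not in pool:
                    if len(pool) >= config.max_trees_held:
                        overflowed = True
                        break
                    pool[key] = cand
    trees = [
        PhyloTree.from_adjacency(a, enc.taxa) for a in pool.values()
    ]
    return SearchResult(trees=trees, best_fit=best_F, overflowed=overflowed)


def tied_leaf_placements(
    matrix: CharacterMatrix, tree: PhyloTree, leaves, k: float = 1.0
) -> list:
    """All optimal-fit reattachment positions of each listed leaf.

    For each leaf in *leaves*, the leaf is pruned from *tree* and scored at
    every possible attachment edge; every position tying the best fit
    yields one tree.  This resolves the placement ambiguity of artificially
    fossilized subjects, whose position is often underdetermined while the
    rest of the topology is stable — the dominant source of equally
    optimal trees in these analyses.  The returned list includes *tree*.
    """
    enc = _Encoded(matrix, k)
    adj0 = tree.adjacency()
    out = {_canon_key(adj0, enc.n_leaves): tree}
    for lab in leaves:
        leaf = enc.taxa.index(lab)
        adj = _copy_adj(adj0)
        v = adj[leaf][0]
        a, b = (x for x in adj[v] if x != leaf)
        adj[a][adj[a].index(v)] = b
        adj[b][adj[b].index(v)] = a
        del adj[v]
        del adj[leaf]
        edges = [(x, y) for x in adj for y in adj[x] if x < y]
        best_F, ties = -np.inf, []
        for x, y in edges:
            adj[x][adj[x].index(y)] = v
            adj[y][adj[y].index(x)] = v
            adj[v] = [leaf, x, y]
            adj[leaf] = [v]
            F = enc.score(adj)
            adj[x][adj[x].index(v)] = y
            adj[y][adj[y].index(v)] = x
            del adj[v]
            del adj[leaf]
            if F > best_F + _TOL:
                best_F, ties = F, [(x, y)]
            elif F >= best_F - _TOL:
                ties.append((x, y))
        for x, y in ties:
            adj2 = _copy_adj(adj)
            adj2[x][adj2[x].index(y)] = v
            adj2[y][adj2[y].index(x)] = v
            adj2[v] = [leaf, x, y]
            adj2[leaf] = [v]
            key = _canon_key(adj2, enc.n_leaves)
            if key not in out:
                out[key] = PhyloTree.from_adjacency(adj2, enc.taxa)
    return list(out.values())


def exhaustive_search(matrix: CharacterMatrix, k: float = 1.0) -> SearchResult:
    """Score every unrooted binary topology (feasible for <= ~9 taxa)."""
    enc = _Encoded(matrix, k)
    n = enc.n_leaves
    if n < 4:
        raise MatrixError("need at least 4 taxa")
    best_F = -np.inf
    best: list = []
    for adj in _enumerate_adj(n):
        F = enc.score(adj)
        if F > best_F + _TOL:
            best_F, best = F, [adj]
        elif F >= best_F - _TOL:
            best.append(adj)
    trees = [PhyloTree.from_adjacency(a, enc.taxa) for a in best]
    return SearchResult(trees=trees, best_fit=best_F)


# ----------------------------------------------------------------------
# ancestral states


def ancestral_states(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char: int,
    root_taxon: str | None = None,
):
    """Most-parsimonious reconstruction (MPR) state sets for every node.

    The tree is rooted at *root_taxon* (outgroup); a node's MPR set holds
    every state it takes in at least one minimum-change labelling.  Returns
    a dict keyed by leaf label (for leaves) and by frozenset of descendant
    leaf labels (for internal nodes).
    """
    if root_taxon is None:
        raise TreeError("ancestral_states requires a root taxon (root hint)")
    if root_taxon not in tree.taxa:
        raise TreeError(f"root taxon {root_taxon!r} not in tree")
    rows = _leaf_rows(tree, matrix)
    cells = [matrix.cells[r][char] for r in rows]
    if all(c is None or c == GAP for c in cells):
        raise MatrixError("character has no observed states")
    smax = 0
    for c in cells:
        if c is not None and c != GAP:
            smax = max(smax, max(c) if isinstance(c, frozenset) else c)
    n_states = smax + 1
    states = np.arange(n_states)
    if matrix.ordered[char]:
        cost = np.abs(states[:, None] - states[None, :]).astype(np.int64)
    else:
        cost = (states[:, None] != states[None, :]).astype(np.int64)

    adj = tree.adjacency()
    root = tree.taxa.index(root_taxon)
    order, parent = postorder(adj, root=root)
    n_leaves = tree.n_taxa

    def tipcost(leaf):
        v = np.full(n_states, _INF, dtype=np.int64)
        v[[s for s in _tip_states(cells[leaf], smax) if s <= smax]] = 0
        return v

    down: dict[int, np.ndarray] = {}
    contrib: dict[int, np.ndarray] = {}  # child -> min_t(cost + down[child])
    below: dict[int, frozenset] = {}
    for node in order:
        kids = [nb for nb in adj[node] if nb != parent[node]]
        if node < n_leaves:
            d = tipcost(node)
            below[node] = frozenset((tree.taxa[node],))
        else:
            d = np.zeros(n_states, dtype=np.int64)
            below[node] = frozenset()
        for ch in kids:
            contrib[ch] = np.min(cost + down[ch][None, :], axis=1)
            d = d + contrib[ch]
            below[node] = below[node] | below[ch]
        down[node] = np.minimum(d, _INF)

    total = int(down[root].min())
    out: dict[int, np.ndarray] = {root: np.zeros(n_states, dtype=np.int64)}
    mpr: dict = {}
    for node in reversed(order):  # preorder
        if node == root:
            # include the root leaf's own tip cost in its outside view
            pass
        full = down[node] + out[node]
        mpr_key = tree.taxa[node] if node < n_leaves else below[node]
        mpr[mpr_key] = frozenset(int(s) for s in states[full == total])
        for ch in [nb for nb in adj[node] if nb != parent[node]]:
            rest = np.minimum(down[node] - contrib[ch], _INF) + out[node]
            out[ch] = np.min(cost + rest[:, None], axis=0)
            out[ch] = np.minimum(out[ch], _INF)
    return mpr
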