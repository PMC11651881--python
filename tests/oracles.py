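"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive quantities by different algorithms than the
package: generalized Sankoff dynamic programming with explicit cost
matrices, exhaustive enumeration of internal-node labelings, and direct
quartet extraction by leaf-set restriction.
"""

from __future__ import annotations

import itertools

import numpy as np

from artex.matrix import GAP
from artex.treeutils import PhyloTree, postorder

INF = 10**9


def _tip_states(cell, n_states):
    if cell is None or cell == GAP:
        return set(range(n_states))
    if isinstance(cell, frozenset):
        return set(cell)
    return {cell}


def sankoff_steps(tree: PhyloTree, matrix, char: int, cost_fn) -> int:
    """Minimum total cost of a character on a tree (general cost matrix DP)."""
    adj = tree.adjacency()
    n = tree.n_taxa
    rows = [matrix.taxa.index(t) for t in tree.taxa]
    cells = [matrix.cells[r][char] for r in rows]
    smax = 0
    for c in cells:
        if c is not None and c != GAP:
            smax = max(smax, max(c) if isinstance(c, frozenset) else c)
    S = smax + 1

    def tipcost(i):
        allowed = _tip_states(cells[i], S)
        return [0 if s in allowed else INF for s in range(S)]

    order, parent = postorder(adj, 0)
    dp = {}
    for node in order:
        if node < n and node != 0:
            dp[node] = tipcost(node)
            continue
        acc = list(tipcost(node)) if node < n else [0] * S
        for ch in adj[node]:
            if ch == parent.get(node, -1):
                continue
            if node == 0 and ch != adj[0][0]:
                continue
            acc = [
                a + min(dp[ch][t] + cost_fn(s, t) for t in range(S))
                for s, a in enumerate(acc)
            ]
        dp[node] = [min(x, INF) for x in acc]
    return min(dp[0])


def enumeration_steps(tree: PhyloTree, matrix, char: int, ordered: bool) -> int:
    """Minimum changes by exhaustive enumeration of internal labelings."""
    adj = tree.adjacency()
    n = tree.n_taxa
    rows = [matrix.taxa.index(t) for t in tree.taxa]
    cells = [matrix.cells[r][char] for r in rows]
    smax = 0
    for c in cells:
        if c is not None and c != GAP:
            smax = max(smax, max(c) if isinstance(c, frozenset) else c)
    states = range(smax + 1)
    internal = [v for v in adj if v >= n]
    edges = [(u, v) for u in adj for v in adj[u] if u < v]
    tipsets = {i: _tip_states(cells[i], smax + 1) for i in range(n)}
    best = INF
    for leaf_choice in itertools.product(
        *[sorted(tipsets[i]) for i in range(n)]
    ):
        for lab in itertools.product(states, repeat=len(internal)):
            assign = dict(zip(internal, lab))
            assign.update(dict(enumerate(leaf_choice)))
            cost = 0
            for u, v in edges:
                d = abs(assign[u] - assign[v]) if ordered else int(
                    assign[u] != assign[v]
                )
                cost += d
            best = min(best, cost)
    return best


def quartet_topology(tree: PhyloTree, four_labels) -> frozenset | None:
    """Resolution of one quartet via restriction; None when unresolved."""
    sub = tree.restrict(four_labels)
    if not sub.clades:
        return None
    (m,) = sub.clades
    side = sub.labels_of(m)
    return frozenset((side, frozenset(four_labels) - side))


def brute_shared_quartets(test: PhyloTree, ref: PhyloTree) -> float:
    common = sorted(set(test.taxa) & set(ref.taxa))
    num = den = 0
    for four in itertools.combinations(common, 4):
        rq = quartet_topology(ref, four)
        if rq is None:
            continue
        den += 1
        if quartet_topology(test, four) == rq:
            num += 1
    return num / den if den else 1.0


def ols_slope(x, y):
    """Closed-form simple-regression slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))
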