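"""Congruence of an inferred tree with a well-corroborated reference.

Two asymmetric, reference-normalized indices are provided: the fraction of
the reference's non-trivial splits present in the test tree, and the
fraction of reference-resolved leaf quartets resolved identically in the
test tree.  Both are computed on the common leaf set; the reference is
treated as the truth standard, optionally after collapsing weakly
supported nodes (posterior probability strictly below a threshold).

Per-subject placement accuracy for artificial-extinction analyses roots
both trees at a designated root (outgroup) taxon.  The clades containing
a subject form a nested chain describing its position; a subject is
accurately reconstructed when every consensus clade containing it is
compatible with every reference clade containing it — i.e. no grouping
the consensus asserts *about the subject* contradicts what the reference
asserts about the subject.  Conflicts between backbone taxa that do not
involve the subject's placement are charged to the congruence indices,
not to the subject.  In strict mode a subject whose placement is wholly
unresolved (it belongs to no non-trivial clade) counts as inaccurate; in
lenient mode it counts as accurate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .treeutils import PhyloTree, TreeError

__all__ = [
    "ReferenceTreeConfig",
    "CongruenceResult",
    "collapse_low_support",
    "shared_splits",
    "shared_quartets",
    "subject_accuracy",
    "compare_trees",
]


@dataclass
class ReferenceTreeConfig:
    """How to derive the truth standard from a supported tree."""

    support_threshold: float = 0.8
    conflict_collapse_list: list = field(default_factory=list)  # leaf-label sets

    def __post_init__(self):
        if not 0.0 <= self.support_threshold <= 1.0:
            raise ValueError("support threshold must lie in [0, 1]")


@dataclass
class CongruenceResult:
    shared_splits: float
    shared_quartets: float
    subject_accuracy: dict
    accuracy: float
    n_common_taxa: int


def collapse_low_support(
    tree: PhyloTree, config: ReferenceTreeConfig | None = None
) -> PhyloTree:
    """Contract internal edges with support strictly below the threshold.

    Splits without a recorded support value are retained.  Splits matching
    an entry of ``conflict_collapse_list`` (given as sets of leaf labels,
    either side) are contracted regardless of support.
    """
    if config is None:
        config = ReferenceTreeConfig()
    full = (1 << tree.n_taxa) - 1
    conflict_masks = set()
    for labels in config.conflict_collapse_list:
        m = tree.mask_of(labels)
        conflict_masks.add(m ^ full if m & 1 else m)
    keep = {}
    for m in tree.clades:
        sup = tree.support.get(m)
        if sup is not None and sup < config.support_threshold:
            continue
        if m in conflict_masks:
            continue
        keep[m] = sup
    return PhyloTree(
        tree.taxa, keep.keys(), {m: s for m, s in keep.items() if s is not None}
    )


def _common_restriction(test: PhyloTree, reference: PhyloTree):
    common = sorted(set(test.taxa) & set(reference.taxa))
    if len(common) < 4:
        raise TreeError(
            f"congruence undefined: only {len(common)} common taxa (need >= 4)"
        )
    return test.restrict(common), reference.restrict(common), len(common)


def shared_splits(test: PhyloTree, reference: PhyloTree) -> float:
    """Fraction of non-trivial reference splits present in the test tree."""
    t, r, _ = _common_restriction(test, reference)
    if not r.clades:
        return 1.0
    return len(r.clades & t.clades) / len(r.clades)


def _quartet_codes(tree: PhyloTree, quartets: np.ndarray) -> np.ndarray:
    """Resolution of each 4-leaf subset: 1=ab|cd, 2=ac|bd, 3=ad|bc, 0=star.

    Uses the four-point condition on unit-branch-length path distances,
    which is exact for trees (polytomies give ties, i.e. unresolved).
    """
    d = tree.topo_distances()
    a, b, c, e = quartets[:, 0], quartets[:, 1], quartets[:, 2], quartets[:, 3]
    s1 = d[a, b] + d[c, e]
    s2 = d[a, c] + d[b, e]
    s3 = d[a, e] + d[b, c]
    sums = np.stack([s1, s2, s3])
    lo = sums.min(axis=0)
    is_min = sums == lo
    code = np.where(is_min.sum(axis=0) == 1, is_min.argmax(axis=0) + 1, 0)
    return code


def shared_quartets(test: PhyloTree, reference: PhyloTree) -> float:
    """Fraction of reference-resolved quartets resolved identically in test.

    Quartets unresolved in the test tree count as unshared; quartets
    unresolved in the reference are excluded from the denominator.
    Exhaustive enumeration over all 4-subsets of the common leaf set.
    """
    t, r, n = _common_restriction(test, reference)
    quartets = np.array(
        list(itertools.combinations(range(n), 4)), dtype=np.int64
    )
    rc = _quartet_codes(r, quartets)
    tc = _quartet_codes(t, quartets)
    resolved = rc != 0
    if not resolved.any():
        return 1.0
    return float(np.mean(tc[resolved] == rc[resolved]))


# ----------------------------------------------------------------------
# per-subject placement accuracy


def _compatible(a: int, b: int, full: int) -> bool:
    """Rooted-clade compatibility: nested or disjoint."""
    i = a & b
    return i == 0 or i == a or i == b


def _conflicts(clade: int, ref_clades, full: int) -> bool:
    return any(not _compatible(clade, r, full) for r in ref_clades)


def subject_accuracy(
    consensus: PhyloTree,
    reference: PhyloTree,
    subjects,
    root_taxon: str,
    strictness: str = "strict",
) -> CongruenceResult:
    """Placement accuracy of each artificially fossilized subject.

    Returns a :class:`CongruenceResult` whose congruence indices are also
    populated (computed on the common leaf set).
    """
    if strictness not in ("strict", "lenient"):
        raise ValueError("strictness must be 'strict' or 'lenient'")
    subjects = list(subjects)
    for s in subjects:
        if s not in consensus._index or s not in reference._index:
            raise TreeError(f"subject {s!r} missing from a tree")
    t, r, n = _common_restriction(consensus, reference)
    if root_taxon not in t._index:
        raise TreeError(f"root taxon {root_taxon!r} not in the common leaf set")
    full = (1 << n) - 1
    t_clades = t.rooted_clades(root_taxon)
    r_clades = r.rooted_clades(root_taxon)

    per_subject = {}
    for s in subjects:
        sbit = 1 << t._index[s]
        containing = [c for c in t_clades if c & sbit]
        if not containing:
            # wholly unresolved placement (subject hangs off the root)
            per_subject[s] = strictness == "lenient"
            continue
        ref_chain = [r for r in r_clades if r & sbit]
        per_subject[s] = not any(
            _conflicts(c, ref_chain, full) for c in containing
        )

    return CongruenceResult(
        shared_splits=shared_splits(consensus, reference),
        shared_quartets=shared_quartets(consensus, reference),
        subject_accuracy=per_subject,
        accuracy=float(np.mean([per_subject[s] for s in subjects]))
        if subjects
        else float("nan"),
        n_common_taxa=n,
    )


def compare_trees(
    test: PhyloTree,
    reference: PhyloTree,
    subjects=(),
    root_taxon: str | None = None,
    strictness: str = "strict",
) -> CongruenceResult:
    """Full congruence record for one analysis (indices + subject accuracy)."""
    if subjects and root_taxon is None:
        raise TreeError("subject accuracy needs a root taxon")
    if subjects:
        return subject_accuracy(test, reference, subjects, root_taxon, strictness)
    _, _, n = _common_restriction(test, reference)
    return CongruenceResult(
        shared_splits=shared_splits(test, reference),
        shared_quartets=shared_quartets(test, reference),
        subject_accuracy={},
        accuracy=float("nan"),
        n_common_taxa=n,
    )
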