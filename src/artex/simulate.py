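"""Synthetic studies: birth-death trees, Mk characters, fossil templates.

The generator emulates the shape of a combined-evidence lipotyphlan
matrix — by default 44 extant taxa, 217 discrete morphological characters
(a minority ordered), a binary indel partition of 26 characters and an
18 762-column DNA alignment — evolved on an ultrametric birth-death tree
under symmetric Mk dynamics with per-character gamma rate multipliers.
Ordered characters evolve on a nearest-neighbour state chain.  Fossil
templates are boolean character masks at chosen completeness levels,
optionally drawn as a contiguous block to mimic the anatomical clustering
of real fossil preservation (jaws and teeth fossilize together).

The true generating tree doubles as the well-corroborated reference
(all supports 1.0), which isolates the artificial-extinction machinery
from inference noise on the reference side.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import dendropy
from dendropy.model import birthdeath
from scipy.linalg import expm

from .matrix import CharacterMatrix, MatrixError, Partition, Template
from .treeutils import PhyloTree

__all__ = ["SimConfig", "SyntheticStudy", "simulate_tree", "simulate_mk",
           "make_templates", "build_study", "DEFAULT_COMPLETENESS_LEVELS"]

# spans the observed fossil range: 26/217 (sparsest) .. 149/217 (most complete)
DEFAULT_COMPLETENESS_LEVELS = (26 / 217, 0.25, 0.40, 0.55, 149 / 217)


@dataclass
class SimConfig:
    """Parameters of one synthetic study (defaults emulate the real matrix)."""

    n_taxa: int = 44
    birth: float = 1.0
    death: float = 0.5
    n_morph: int = 217
    n_states: int = 3          # max states per character (drawn 2..n_states)
    prop_ordered: float = 21 / 217
    rate_gamma_shape: float = 0.8
    morph_rate: float = 1.5    # expected changes per character per unit depth;
                               # gives ensemble consistency indices near those
                               # of real morphological matrices (~0.4)
    n_dna: int = 18762
    dna_rate: float = 1.0
    n_indel: int = 26
    indel_rate: float = 0.2
    missing_fraction: float = 0.1
    completeness_levels: tuple = DEFAULT_COMPLETENESS_LEVELS
    template_block_prob: float = 0.5
    support_e0: float = 8.0    # expected-changes scale of reference supports
    seed: int = 0

    def __post_init__(self):
        if not self.birth > self.death >= 0:
            raise ValueError("need birth > death >= 0")
        for name in ("prop_ordered", "missing_fraction", "template_block_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 2 <= self.n_states <= 10:
            raise ValueError("n_states must lie in 2..10")


@dataclass
class SyntheticStudy:
    true_tree: dendropy.Tree
    reference: PhyloTree
    matrix: CharacterMatrix
    templates: list
    config: SimConfig

    @property
    def root_taxon(self) -> str:
        return sorted(self.matrix.taxa)[0]

    @property
    def subject_pool(self) -> list:
        return [t for t in self.matrix.taxa if t != self.root_taxon]


# ----------------------------------------------------------------------


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None):
    """Ultrametric birth-death tree conditioned on ``n_taxa`` extant tips.

    Tip labels are ``t01..tNN``; depth is rescaled to 1 time unit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pyrng = _pyrandom.Random(int(rng.integers(2**31)))
    try:
        # GSA conditioning avoids the zero-length terminal cherry that
        # stopping at the n-th speciation event would leave
        tree = birthdeath.birth_death_tree(
            birth_rate=config.birth,
            death_rate=config.death,
            num_extant_tips=config.n_taxa,
            gsa_ntax=max(config.n_taxa + 2, int(config.n_taxa * 1.25)),
            rng=pyrng,
            repeat_until_success=True,
        )
    except (TypeError, ValueError):  # dendropy GSA edge case on tiny trees
        tree = birthdeath.birth_death_tree(
            birth_rate=config.birth,
            death_rate=config.death,
            num_extant_tips=config.n_taxa,
            rng=pyrng,
            repeat_until_success=True,
        )
    width = len(str(config.n_taxa))
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    for i, leaf in enumerate(leaves):
        leaf.taxon.label = f"t{i + 1:0{width}d}"
    depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    return tree


# ----------------------------------------------------------------------


def _evolve_unordered(tree, n_char, k_states, rates, rng):
    """Symmetric Mk walk down the tree; vectorized across characters.

    ``k_states``: per-character state count array; ``rates``: per-character
    total substitution rates.
    """
    k = k_states.astype(np.float64)
    states = {}
    root = tree.seed_node
    states[root] = (rng.random(n_char) * k_states).astype(np.int64)
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is root:
            continue
        parent = states[edge.tail_node]
        b = edge.length or 0.0
        p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k / (k - 1.0) * rates * b)
        change = rng.random(n_char) >= p_same
        offset = (rng.random(n_char) * (k_states - 1)).astype(np.int64)
        proposal = np.where(offset >= parent, offset + 1, offset)
        states[node] = np.where(change, proposal, parent)
    return {
        l.taxon.label: states[l] for l in tree.leaf_node_iter()
    }


def _evolve_ordered(tree, n_char, k_states, rates, rng):
    """Nearest-neighbour stepwise Mk chain (exact CTMC via matrix exponentials)."""
    out = {}
    root = tree.seed_node
    states = {root: (rng.random(n_char) * k_states).astype(np.int64)}
    # per-(edge, character) transition: group characters by (k, rate) cheaply
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is root:
            continue
        parent = states[edge.tail_node]
        b = edge.length or 0.0
        new = parent.copy()
        for j in range(n_char):
            k = int(k_states[j])
            if k < 2:
                continue
            q = np.zeros((k, k))
            for s in range(k - 1):
                q[s, s + 1] = rates[j] / 2
                q[s + 1, s] = rates[j] / 2
            np.fill_diagonal(q, -q.sum(axis=1))
            p = expm(q * b)
            new[j] = rng.choice(k, p=np.maximum(p[parent[j]], 0) / p[parent[j]].sum())
        states[node] = new
    return {l.taxon.label: states[l] for l in tree.leaf_node_iter()}


def simulate_mk(tree, config: SimConfig, rng: np.random.Generator | None = None):
    """Character matrix (morphology + indel + DNA partitions) on *tree*."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    n_taxa = len(taxa)
    shape = config.rate_gamma_shape

    def gamma_rates(n, base):
        return base * rng.gamma(shape, 1.0 / shape, size=n)

    n_ord = int(round(config.prop_ordered * config.n_morph))
    ordered_idx = np.sort(rng.choice(config.n_morph, size=n_ord, replace=False))
    is_ord = np.zeros(config.n_morph, dtype=bool)
    is_ord[ordered_idx] = True

    # morphology: per-character state counts 2..n_states (ordered chars >= 3
    # where possible, so ordering has something to order)
    k_morph = rng.integers(2, config.n_states + 1, size=config.n_morph)
    if config.n_states >= 3:
        k_morph[is_ord] = np.maximum(k_morph[is_ord], 3)
    m_un = _evolve_unordered(
        tree,
        int((~is_ord).sum()),
        k_morph[~is_ord],
        gamma_rates((~is_ord).sum(), config.morph_rate),
        rng,
    )
    m_or = _evolve_ordered(
        tree, n_ord, k_morph[is_ord], gamma_rates(n_ord, config.morph_rate), rng
    )
    d_states = (
        _evolve_unordered(
            tree,
            config.n_dna,
            np.full(config.n_dna, 4),
            gamma_rates(config.n_dna, config.dna_rate),
            rng,
        )
        if config.n_dna
        else {t: np.zeros(0, dtype=np.int64) for t in taxa}
    )
    i_states = (
        _evolve_unordered(
            tree,
            config.n_indel,
            np.full(config.n_indel, 2),
            gamma_rates(config.n_indel, config.indel_rate),
            rng,
        )
        if config.n_indel
        else {t: np.zeros(0, dtype=np.int64) for t in taxa}
    )

    cells = []
    un_pos = np.flatnonzero(~is_ord)
    or_pos = np.flatnonzero(is_ord)
    for t in taxa:
        morph = np.zeros(config.n_morph, dtype=np.int64)
        morph[un_pos] = m_un[t]
        morph[or_pos] = m_or[t]
        row = np.concatenate([morph, i_states[t], d_states[t]])
        miss = rng.random(row.size) < config.missing_fraction
        cells.append([None if miss[j] else int(row[j]) for j in range(row.size)])

    parts = [Partition("morphology", "morphology", 0, config.n_morph)]
    pos = config.n_morph
    if config.n_indel:
        parts.append(Partition("indels", "indel", pos, pos + config.n_indel))
        pos += config.n_indel
    if config.n_dna:
        parts.append(Partition("dna", "dna", pos, pos + config.n_dna))
        pos += config.n_dna
    ordered = np.concatenate(
        [is_ord, np.zeros(pos - config.n_morph, dtype=bool)]
    )
    return CharacterMatrix(taxa, cells, parts, ordered)


# ----------------------------------------------------------------------


def make_templates(
    n_morph: int,
    completeness_levels,
    seed: int = 0,
    block_prob: float = 0.5,
) -> list:
    """Boolean character masks at the requested completeness levels.

    With probability ``block_prob`` a template is a contiguous character
    block (anatomically clustered preservation); otherwise characters are
    sampled uniformly.  Realized completeness is within one character of
    ``round(level * n_morph)`` by construction.
    """
    rng = np.random.default_rng(seed)
    templates = []
    for i, level in enumerate(completeness_levels):
        if not 0 < level <= 1:
            raise MatrixError(f"completeness level {level} outside (0, 1]")
        size = int(round(level * n_morph))
        if size < 1:
            raise MatrixError(f"completeness level {level} selects no characters")
        mask = np.zeros(n_morph, dtype=bool)
        if rng.random() < block_prob:
            start = int(rng.integers(0, n_morph - size + 1))
            mask[start : start + size] = True
        else:
            mask[rng.choice(n_morph, size=size, replace=False)] = True
        templates.append(Template(name=f"tpl{i + 1:02d}_c{level:.2f}", mask=mask))
    return templates


def build_study(config: SimConfig | None = None, out_dir=None) -> SyntheticStudy:
    """Compose tree, matrix, templates and reference into one study."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    matrix = simulate_mk(tree, config, rng)
    templates = make_templates(
        config.n_morph,
        config.completeness_levels,
        seed=int(rng.integers(2**31)),
        block_prob=config.template_block_prob,
    )
    reference = _reference_with_supports(tree, config)
    study = SyntheticStudy(
        true_tree=tree,
        reference=reference,
        matrix=matrix,
        templates=templates,
        config=config,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _reference_with_supports(tree, config: SimConfig) -> PhyloTree:
    """True tree as reference, with posterior-like supports per split.

    An internal edge is only recoverable when enough character changes are
    expected along it; we model support as ``1 - exp(-E / e0)`` where E is
    the expected number of changes over all characters (edge length times
    the summed per-partition rates).  With the 0.8 collapse threshold this
    removes edges the data cannot resolve, mirroring how a well-corroborated
    reference drops weakly supported nodes.
    """
    total_rate = (
        config.n_morph * config.morph_rate
        + config.n_dna * config.dna_rate
        + config.n_indel * config.indel_rate
    )
    ref = PhyloTree.from_dendropy(tree)
    idx = {t: i for i, t in enumerate(ref.taxa)}
    full = (1 << ref.n_taxa) - 1
    support = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._mask = 1 << idx[node.taxon.label]
            continue
        m = 0
        for ch in node.child_nodes():
            m |= ch._mask
        node._mask = m
        norm = m ^ full if m & 1 else m
        if norm in ref.clades and node.edge.length is not None:
            expected = node.edge.length * total_rate
            sup = 1.0 - float(np.exp(-expected / config.support_e0))
            support[norm] = round(min(max(support.get(norm, 0.0), sup), 1.0), 4)
    return PhyloTree(ref.taxa, ref.clades, support)


def _write_study(study: SyntheticStudy, out: Path) -> None:
    import yaml

    from .nexus import write_nexus, write_tree

    out.mkdir(parents=True, exist_ok=True)
    write_nexus(study.matrix, out / "matrix.nex")
    write_tree(study.reference, out / "true_tree.nwk")
    with open(out / "templates.tsv", "w") as fh:
        fh.write("template\tn_scored\tn_morph\tcompleteness\tmask\n")
        for t in study.templates:
            bits = "".join("1" if b else "0" for b in t.mask)
            fh.write(
                f"{t.name}\t{t.n_scored}\t{t.mask.size}\t{t.completeness:.4f}\t{bits}\n"
            )
    with open(out / "config.yaml", "w") as fh:
        cfg = asdict(study.config)
        cfg["completeness_levels"] = list(cfg["completeness_levels"])
        yaml.safe_dump(cfg, fh)
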