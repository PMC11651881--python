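"""Discrete character matrices with partitions, orderings and fossil templates.

Cell encoding
-------------
Each cell is one of:

* ``int`` in ``0..9`` (DNA mapped A,C,G,T -> 0..3) — a single observed state,
* ``frozenset`` of such ints — a polymorphic/ambiguous observation,
* :data:`GAP` — an alignment gap (kept distinct so indels can be coded),
* ``None`` — missing / undetermined.

For parsimony, gaps and missing data are both treated as "could be any
state"; the distinction only matters for gap (indel) coding of DNA
partitions.  Ordered characters (states forming a linear morphocline)
are flagged per character and are only permitted in morphology partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GAP", "Cell", "Partition", "CharacterMatrix", "Template",
           "template_from_fossil", "MatrixError"]

GAP = -1

Cell = "int | frozenset | None"

_KINDS = ("morphology", "indel", "dna")


class MatrixError(ValueError):
    """Raised for structurally invalid matrices or templates."""


@dataclass(frozen=True)
class Partition:
    """A named, contiguous block of character indices (0-based, end-exclusive)."""

    name: str
    kind: str
    start: int
    stop: int

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise MatrixError(f"unknown partition kind {self.kind!r}")
        if not 0 <= self.start < self.stop:
            raise MatrixError(f"bad partition range {self.start}:{self.stop}")

    @property
    def indices(self) -> range:
        return range(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


def cell_states(cell, max_state: int = 9) -> frozenset:
    """The state set a cell contributes to parsimony (full set when unknown)."""
    if cell is None or cell == GAP:
        return frozenset(range(max_state + 1))
    if isinstance(cell, frozenset):
        return cell
    return frozenset((cell,))


class CharacterMatrix:
    """Taxa × discrete characters, partitioned and with per-character orderings."""

    def __init__(
        self,
        taxa: Sequence[str],
        cells: Sequence[Sequence],
        partitions: Sequence[Partition],
        ordered: Sequence[bool] | None = None,
    ):
        self.taxa = list(taxa)
        self.cells = [list(row) for row in cells]
        self.partitions = list(partitions)
        n_char = len(self.cells[0]) if self.cells else 0
        if ordered is None:
            ordered = np.zeros(n_char, dtype=bool)
        self.ordered = np.asarray(ordered, dtype=bool)
        self.validate()

    # ------------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def validate(self) -> None:
        if not self.taxa:
            raise MatrixError("empty taxon set")
        if len(set(self.taxa)) != len(self.taxa):
            raise MatrixError("duplicate taxon labels")
        if len(self.cells) != len(self.taxa):
            raise MatrixError("row count does not match taxon count")
        n_char = self.n_char
        for t, row in zip(self.taxa, self.cells):
            if len(row) != n_char:
                raise MatrixError(f"ragged row for taxon {t!r}")
        covered = np.zeros(n_char, dtype=bool)
        for p in self.partitions:
            if p.stop > n_char:
                raise MatrixError(f"partition {p.name!r} exceeds matrix width")
            if covered[p.start : p.stop].any():
                raise MatrixError(f"partition {p.name!r} overlaps another")
            covered[p.start : p.stop] = True
        if not covered.all():
            raise MatrixError("partitions do not cover all characters")
        if len(self.ordered) != n_char:
            raise MatrixError("ordered flag length mismatch")
        morph = np.zeros(n_char, dtype=bool)
        for p in self.partitions:
            if p.kind == "morphology":
                morph[p.start : p.stop] = True
        if (self.ordered & ~morph).any():
            raise MatrixError("ordered flags set outside morphology partitions")
        for row, t in zip(self.cells, self.taxa):
            for j, c in enumerate(row):
                if isinstance(c, frozenset):
                    if not c or any(not isinstance(s, int) or s < 0 for s in c):
                        raise MatrixError(
                            f"invalid polymorphic set at {t!r} char {j + 1}"
                        )

    # ------------------------------------------------------------------
    # access helpers

    def partition(self, name: str) -> Partition:
        for p in self.partitions:
            if p.name == name:
                return p
        raise KeyError(name)

    def partitions_of_kind(self, kind: str) -> list[Partition]:
        return [p for p in self.partitions if p.kind == kind]

    def indices_of_kind(self, kind: str) -> list[int]:
        out: list[int] = []
        for p in self.partitions_of_kind(kind):
            out.extend(p.indices)
        return out

    def row(self, taxon: str) -> list:
        return self.cells[self.taxa.index(taxon)]

    def column(self, j: int) -> list:
        return [row[j] for row in self.cells]

    def observed_states(self, j: int) -> frozenset:
        """Distinct states observed in character *j* (polymorphs expanded)."""
        out: set[int] = set()
        for row in self.cells:
            c = row[j]
            if c is None or c == GAP:
                continue
            out.update(c if isinstance(c, frozenset) else (c,))
        return frozenset(out)

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            list(self.taxa),
            [list(r) for r in self.cells],
            list(self.partitions),
            self.ordered.copy(),
        )

    def subset_taxa(self, keep: Iterable[str]) -> "CharacterMatrix":
        keep = list(keep)
        missing = set(keep) - set(self.taxa)
        if missing:
            raise MatrixError(f"taxa not in matrix: {sorted(missing)}")
        idx = [self.taxa.index(t) for t in keep]
        return CharacterMatrix(
            keep,
            [self.cells[i] for i in idx],
            list(self.partitions),
            self.ordered.copy(),
        )


# ----------------------------------------------------------------------
# fossil templates


@dataclass
class Template:
    """Which morphology characters a fossil is scored for.

    ``mask`` is a boolean vector over the morphology characters (in matrix
    order); completeness is the scored fraction.
    """

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1 or self.mask.size == 0:
            raise MatrixError("template mask must be a nonempty vector")
        if not self.mask.any():
            raise MatrixError(f"template {self.name!r} scores no characters")

    @property
    def completeness(self) -> float:
        return float(self.mask.mean())

    @property
    def n_scored(self) -> int:
        return int(self.mask.sum())


def template_from_fossil(matrix: CharacterMatrix, fossil: str) -> Template:
    """Extract a template from a fossil row: scored = non-missing morphology cell."""
    if fossil not in matrix.taxa:
        raise MatrixError(f"fossil {fossil!r} not in matrix")
    row = matrix.row(fossil)
    morph = matrix.indices_of_kind("morphology")
    if not morph:
        raise MatrixError("matrix has no morphology partition")
    mask = np.array([row[j] is not None and row[j] != GAP for j in morph])
    if not mask.any():
        raise MatrixError(f"fossil {fossil!r} is scored for no morphology characters")
    return Template(name=fossil, mask=mask)
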