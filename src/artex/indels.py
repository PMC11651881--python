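"""Simple indel coding: triplet gaps in codon alignments as binary characters.

A maximal run of gap columns in one taxon becomes a candidate indel event.
Runs whose length is a positive multiple of three (codon-preserving
deletions) and that are shared with identical start and end columns by at
least ``min_sharers`` taxa are coded as one binary character: 1 = gap
present, 0 = gap absent, missing (?) where the region is undetermined or
overlapped by a non-identical gap.  Runs seen in a single taxon
(autapomorphies) are never coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .matrix import GAP, CharacterMatrix, MatrixError, Partition

__all__ = ["IndelCharacter", "code_gaps", "with_indel_partition"]


@dataclass(frozen=True)
class IndelCharacter:
    """One coded gap: 1-based columns [start, end] within the DNA partition."""

    name: str
    start: int
    end: int
    states: tuple  # per-taxon 1 / 0 / None, in matrix taxon order


def _gap_runs(row, lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal (start, stop) gap runs of one row within columns [lo, hi)."""
    runs = []
    j = lo
    while j < hi:
        if row[j] == GAP:
            k = j
            while k < hi and row[k] == GAP:
                k += 1
            runs.append((j, k))
            j = k
        else:
            j += 1
    return runs


def code_gaps(
    matrix: CharacterMatrix, dna_partition: str, min_sharers: int = 2
) -> list[IndelCharacter]:
    """Code shared triplet gaps of one DNA partition as binary characters."""
    if min_sharers < 2:
        raise MatrixError("min_sharers must be >= 2 (non-autapomorphic coding)")
    part = matrix.partition(dna_partition)
    if part.kind != "dna":
        raise MatrixError(f"partition {dna_partition!r} is not DNA")
    if len(part) % 3 != 0:
        warnings.warn(
            f"partition {dna_partition!r} length {len(part)} is not a codon "
            "multiple; proceeding",
            stacklevel=2,
        )

    runs_by_taxon = {
        t: _gap_runs(row, part.start, part.stop)
        for t, row in zip(matrix.taxa, matrix.cells)
    }
    sharers: dict[tuple[int, int], list[str]] = {}
    for t, runs in runs_by_taxon.items():
        for run in runs:
            if (run[1] - run[0]) % 3 == 0:
                sharers.setdefault(run, []).append(t)

    chars = []
    for (start, stop), taxa in sorted(sharers.items()):
        if len(taxa) < min_sharers:
            continue
        states = []
        for t, row in zip(matrix.taxa, matrix.cells):
            if t in taxa:
                states.append(1)
                continue
            region = row[start:stop]
            if any(c is None for c in region) or any(c == GAP for c in region):
                states.append(None)  # undetermined or conflicting gap boundaries
            else:
                states.append(0)
        rel = start - part.start + 1
        chars.append(
            IndelCharacter(
                name=f"{dna_partition}_gap_{rel}",
                start=rel,
                end=stop - part.start,
                states=tuple(states),
            )
        )
    return chars


def with_indel_partition(
    matrix: CharacterMatrix,
    dna_partitions: list[str] | None = None,
    min_sharers: int = 2,
    partition_name: str = "indels",
) -> CharacterMatrix:
    """Append one binary indel partition coded from the given DNA partitions."""
    if dna_partitions is None:
        dna_partitions = [p.name for p in matrix.partitions_of_kind("dna")]
    chars: list[IndelCharacter] = []
    for name in dna_partitions:
        chars.extend(code_gaps(matrix, name, min_sharers))
    if not chars:
        return matrix.copy()
    n = matrix.n_char
    cells = [
        list(row) + [ch.states[i] for ch in chars]
        for i, row in enumerate(matrix.cells)
    ]
    parts = list(matrix.partitions) + [
        Partition(partition_name, "indel", n, n + len(chars))
    ]
    ordered = list(matrix.ordered) + [False] * len(chars)
    return CharacterMatrix(matrix.taxa, cells, parts, ordered)
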