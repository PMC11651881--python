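"""NEXUS matrix and newick tree input/output.

Matrices are written as one CHARACTERS block per partition (``TITLE`` gives
the partition name; DNA partitions use ``DATATYPE=DNA``, morphology and
indel partitions ``DATATYPE=STANDARD``), which round-trips losslessly
through dendropy.  Character orderings are emitted as a standard
``ASSUMPTIONS``/``TYPESET`` line with global 1-based indices; dendropy
skips ASSUMPTIONS blocks, so that one line is recovered with a regex on
the raw text.  Single-block files (a plain DATA/CHARACTERS block) are also
readable and become a one-partition matrix.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy

from .matrix import GAP, CharacterMatrix, MatrixError, Partition
from .treeutils import PhyloTree, TreeError

__all__ = ["read_nexus", "write_nexus", "read_tree", "write_tree", "NexusError"]


class NexusError(MatrixError):
    """Raised when a NEXUS file cannot be parsed into a CharacterMatrix."""


_DNA_MAP = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_DNA_SYM = "ACGT"
_STD_SYMBOLS = "0123456789"


# ----------------------------------------------------------------------
# reading


def _cell_from_state(cell, kind: str):
    """Map a dendropy StateIdentity to the internal cell encoding."""
    sym = cell.symbol
    if sym == "?":
        return None
    if sym == "-":
        # morphology '-' means inapplicable -> missing; DNA '-' is a gap
        return GAP if kind == "dna" else None
    if cell.state_denomination == 0:  # fundamental single state
        if kind == "dna":
            try:
                return _DNA_MAP[sym.upper()]
            except KeyError as exc:
                raise NexusError(f"unknown DNA symbol {sym!r}") from exc
        if sym not in _STD_SYMBOLS:
            raise NexusError(f"unknown state symbol {sym!r}")
        return int(sym)
    # polymorphic / uncertain: expand to fundamental non-gap states
    states = set()
    for fs in cell.fundamental_states:
        s = fs.symbol
        if s == "-":
            continue
        states.add(_DNA_MAP[s.upper()] if kind == "dna" else int(s))
    if not states:
        return None
    n_alphabet = 4 if kind == "dna" else 10
    if len(states) >= n_alphabet:
        return None  # covers the whole alphabet: effectively missing
    if len(states) == 1:
        return next(iter(states))
    return frozenset(states)


def _block_kind(cm) -> str:
    if isinstance(cm, dendropy.DnaCharacterMatrix):
        return "dna"
    label = (cm.label or "").lower()
    return "indel" if "indel" in label or "gap" in label else "morphology"


_TYPESET_RE = re.compile(
    r"TYPESET[^=;]*=\s*([^;]*);", re.IGNORECASE | re.DOTALL
)


def _parse_typeset(text: str, n_char: int):
    """Ordered-character flags from a ``TYPESET * x = ord: 1 3-5, unord: ...;`` line."""
    import numpy as np

    flags = np.zeros(n_char, dtype=bool)
    m = _TYPESET_RE.search(text)
    if not m:
        return flags
    for clause in m.group(1).split(","):
        clause = clause.strip()
        if ":" not in clause:
            continue
        typ, idxs = clause.split(":", 1)
        if typ.strip().lower() not in ("ord", "ordered"):
            continue
        for tok in idxs.split():
            if "-" in tok:
                a, b = tok.split("-")
                flags[int(a) - 1 : int(b)] = True
            else:
                flags[int(tok) - 1] = True
    return flags


def read_nexus(path) -> CharacterMatrix:
    """Read a (possibly multi-block) NEXUS file into a CharacterMatrix."""
    path = Path(path)
    text = path.read_text()
    try:
        ds = dendropy.DataSet.get(data=text, schema="nexus")
    except Exception as exc:
        raise NexusError(f"{path.name}: NEXUS parse error: {exc}") from exc
    if not ds.char_matrices:
        raise NexusError(f"{path.name}: no CHARACTERS/DATA block found")

    taxa = [t.label for t in ds.char_matrices[0].taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise NexusError(f"{path.name}: duplicate taxon labels")
    rows: dict[str, list] = {t: [] for t in taxa}
    partitions: list[Partition] = []
    offset = 0
    used_names = set()
    for bi, cm in enumerate(ds.char_matrices):
        kind = _block_kind(cm)
        name = cm.label or f"{kind}{bi + 1}"
        if name in used_names:
            name = f"{name}_{bi + 1}"
        used_names.add(name)
        width = None
        for t in taxa:
            taxon_obj = next(
                (x for x in cm.taxon_namespace if x.label == t), None
            )
            seq = cm[taxon_obj] if taxon_obj is not None and taxon_obj in cm else None
            if seq is None:
                # taxon absent from this block: all-missing
                if width is None:
                    width = cm.max_sequence_size
                rows[t].extend([None] * width)
                continue
            vals = [_cell_from_state(c, kind) for c in seq]
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise NexusError(
                    f"{path.name}: ragged row for taxon {t!r} in block {name!r}"
                )
            rows[t].extend(vals)
        partitions.append(Partition(name, kind, offset, offset + width))
        offset += width

    ordered = _parse_typeset(text, offset)
    return CharacterMatrix(
        taxa, [rows[t] for t in taxa], partitions, ordered
    )


# ----------------------------------------------------------------------
# writing


def _format_cell(cell, kind: str) -> str:
    if cell is None:
        return "?"
    if cell == GAP:
        return "-" if kind == "dna" else "?"
    if isinstance(cell, frozenset):
        syms = sorted(cell)
        if kind == "dna":
            return "{" + "".join(_DNA_SYM[s] for s in syms) + "}"
        return "{" + "".join(str(s) for s in syms) + "}"
    return _DNA_SYM[cell] if kind == "dna" else str(cell)


def _ranges(idx: list[int]) -> str:
    """Compress sorted 1-based indices to NEXUS range notation."""
    out, i = [], 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and idx[j + 1] == idx[j] + 1:
            j += 1
        out.append(str(idx[i]) if i == j else f"{idx[i]}-{idx[j]}")
        i = j + 1
    return " ".join(out)


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Write a CharacterMatrix as a multi-block NEXUS file (see module docs)."""
    matrix.validate()
    path = Path(path)
    pad = max(len(t) for t in matrix.taxa) + 2
    lines = ["#NEXUS", ""]
    lines.append("BEGIN TAXA;")
    lines.append(f"    DIMENSIONS NTAX={matrix.n_taxa};")
    labels = " ".join(_quote(t) for t in matrix.taxa)
    lines.append(f"    TAXLABELS {labels};")
    lines.append("END;")
    for p in matrix.partitions:
        lines.append("")
        lines.append("BEGIN CHARACTERS;")
        lines.append(f"    TITLE {_quote(p.name)};")
        lines.append(f"    DIMENSIONS NCHAR={len(p)};")
        if p.kind == "dna":
            fmt = "DATATYPE=DNA MISSING=? GAP=-"
        else:
            syms = "01" if p.kind == "indel" else _STD_SYMBOLS
            fmt = f'DATATYPE=STANDARD SYMBOLS="{syms}" MISSING=? GAP=-'
        lines.append(f"    FORMAT {fmt};")
        lines.append("    MATRIX")
        for t, row in zip(matrix.taxa, matrix.cells):
            seq = "".join(_format_cell(row[j], p.kind) for j in p.indices)
            lines.append(f"    {_quote(t):<{pad}} {seq}")
        lines.append("    ;")
        lines.append("END;")
    # global charset table as a comment: partitions round-trip via the block
    # structure; a real SETS block would need per-matrix LINK statements.
    lines.append("")
    lines.append("[charsets (global 1-based columns):")
    for p in matrix.partitions:
        lines.append(f"    charset {p.name} = {p.start + 1}-{p.stop};")
    lines.append("]")
    ord_idx = [j + 1 for j in range(matrix.n_char) if matrix.ordered[j]]
    if ord_idx:
        unord = [j + 1 for j in range(matrix.n_char) if not matrix.ordered[j]]
        lines.append("")
        lines.append("BEGIN ASSUMPTIONS;")
        clause = f"ord: {_ranges(ord_idx)}"
        if unord:
            clause += f", unord: {_ranges(unord)}"
        lines.append(f"    TYPESET * default = {clause};")
        lines.append("END;")
    path.write_text("\n".join(lines) + "\n")


def _quote(label: str) -> str:
    if re.search(r"[\s(){}\[\]/\\,;:=*'\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# trees


def read_tree(path) -> PhyloTree:
    """Read a newick tree; internal node labels become split supports."""
    text = Path(path).read_text()
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick(include_support=True) + "\n")
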