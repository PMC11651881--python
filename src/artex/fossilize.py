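"""Artificial extinction: masking extant taxa down to a fossil's characters.

A *subject* (extant taxon) is artificially fossilized against a *template*
(a real fossil's morphology-character coverage): all its molecular and
indel cells become missing, and its morphology cells are kept only where
the template scores the character.  In ``random`` mode the retained cells
are replaced by seeded uniform binary states, giving a noise control with
the same completeness as the real-state analysis.  The full experimental
design enumerates subject-template combinations exhaustively for single
subjects and with seeded draws for multi-subject groups.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict

import numpy as np

from .matrix import CharacterMatrix, MatrixError, Template

__all__ = ["JobSpec", "ExperimentPlan", "fossilize_matrix", "enumerate_plan"]

_MODES = ("real", "random")


@dataclass(frozen=True)
class JobSpec:
    """One artificial-extinction analysis."""

    subjects: tuple
    template: str
    mode: str
    group_size: int
    replicate_index: int
    seed: int

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if len(self.subjects) != self.group_size:
            raise ValueError("subject count must equal group_size")
        if len(set(self.subjects)) != self.group_size:
            raise ValueError("duplicate subjects in one job")

    @property
    def job_id(self) -> str:
        return f"{self.template}|g{self.group_size}|r{self.replicate_index}|{self.mode}"


@dataclass
class ExperimentPlan:
    jobs: list
    n_subject_pool: int
    n_templates: int

    def __len__(self):
        return len(self.jobs)

    def __iter__(self):
        return iter(self.jobs)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for j in self.jobs:
                fh.write(json.dumps(asdict(j)) + "\n")

    @classmethod
    def from_jsonl(cls, path, n_subject_pool=0, n_templates=0) -> "ExperimentPlan":
        jobs = []
        with open(path) as fh:
            for line in fh:
                d = json.loads(line)
                d["subjects"] = tuple(d["subjects"])
                jobs.append(JobSpec(**d))
        return cls(jobs, n_subject_pool, n_templates)


def _derive_seed(*parts) -> int:
    """Stable 31-bit stream seed from heterogeneous key parts."""
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def enumerate_plan(
    subject_pool,
    templates,
    group_sizes=(1, 2, 4, 8, 16, 32),
    modes=("real", "random"),
    master_seed: int = 0,
    replicates_per_template: int | None = None,
    root_taxon: str | None = None,
) -> ExperimentPlan:
    """Enumerate the artificial-extinction design.

    Single-subject sets are exhaustive over the pool (one job per
    subject-template pair); multi-subject sets draw ``replicates_per_template``
    (default: pool size, matching the single-subject count) seeded random
    subject groups without replacement.  Subject draws are blocked on the
    replicate index — every template sees the same subject groups — and
    each job is duplicated per state mode with the same subject set, so
    template and mode comparisons are within-subject.
    """
    pool = [t for t in subject_pool if t != root_taxon]
    if not pool:
        raise ValueError("empty subject pool")
    names = [t.name if isinstance(t, Template) else str(t) for t in templates]
    if not names:
        raise ValueError("no templates")
    for g in group_sizes:
        if not 1 <= g <= len(pool):
            raise ValueError(f"group size {g} exceeds subject pool ({len(pool)})")
    for m in modes:
        if m not in _MODES:
            raise ValueError(f"unknown mode {m!r}")
    n_rep = replicates_per_template or len(pool)

    jobs = []
    for g in group_sizes:
        for name in names:
            for r in range(n_rep):
                if g == 1 and n_rep == len(pool):
                    subjects = (pool[r],)
                else:
                    rng = np.random.default_rng(
                        _derive_seed(master_seed, g, r, "subjects")
                    )
                    subjects = tuple(
                        sorted(rng.choice(pool, size=g, replace=False).tolist())
                    )
                for mode in modes:
                    jobs.append(
                        JobSpec(
                            subjects=subjects,
                            template=name,
                            mode=mode,
                            group_size=g,
                            replicate_index=r,
                            seed=_derive_seed(master_seed, name, g, r, mode),
                        )
                    )
    return ExperimentPlan(jobs, n_subject_pool=len(pool), n_templates=len(names))


def fossilize_matrix(
    matrix: CharacterMatrix, job: JobSpec, templates: dict
) -> CharacterMatrix:
    """Apply one artificial-extinction job to a matrix of extant taxa.

    Idempotent for a fixed job: random-state draws are seeded from the job.
    """
    if job.template not in templates:
        raise MatrixError(f"unknown template {job.template!r}")
    template: Template = templates[job.template]
    morph = matrix.indices_of_kind("morphology")
    if len(template.mask) != len(morph):
        raise MatrixError(
            f"template {template.name!r} mask length {len(template.mask)} != "
            f"{len(morph)} morphology characters"
        )
    for s in job.subjects:
        if s not in matrix.taxa:
            raise MatrixError(f"subject {s!r} is not an extant taxon in the matrix")

    out = matrix.copy()
    nonmorph = set(matrix.indices_of_kind("dna")) | set(
        matrix.indices_of_kind("indel")
    )
    for s in job.subjects:
        row = out.cells[out.taxa.index(s)]
        for j in nonmorph:
            row[j] = None
        if job.mode == "random":
            rng = np.random.default_rng(_derive_seed(job.seed, s, "states"))
            draws = rng.integers(0, 2, size=len(morph))
        for pos, j in enumerate(morph):
            if not template.mask[pos]:
                row[j] = None
            elif job.mode == "random":
                row[j] = int(draws[pos])
    return out
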