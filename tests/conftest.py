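from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from artex.matrix import CharacterMatrix, Partition


def make_matrix(taxa, columns, ordered=None, kind="morphology"):
    """Matrix from a list of columns (each a per-taxon state list)."""
    cells = [list(r) for r in zip(*columns)]
    parts = [Partition("m", kind, 0, len(columns))]
    return CharacterMatrix(taxa, cells, parts, ordered or [False] * len(columns))


@pytest.fixture(scope="session")
def small_study():
    """A 10-taxon study shared by congruence/experiment tests (cheap)."""
    from artex.simulate import SimConfig, build_study

    cfg = SimConfig(
        n_taxa=10,
        n_morph=80,
        n_dna=120,
        n_indel=6,
        n_states=3,
        completeness_levels=(0.15, 0.4, 0.7),
        template_block_prob=0.0,
        seed=5,
    )
    return build_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
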