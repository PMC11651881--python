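# artex — artificial-extinction experiments for combined-evidence phylogenetics

Fossils preserve a small fraction of the characters available from living
species — mostly teeth, jaws, and scattered cranial or postcranial bones,
and never DNA.  Do such small packets of fossilizable data still carry
enough signal to place a taxon correctly in a phylogeny?  `artex`
implements the *artificial extinction* protocol for answering that
question on any combined morphological–molecular matrix: treat a living
species (a **subject**, whose true affinities are well corroborated) as
though it were a fossil by deleting its molecular data and every
morphological character a chosen real fossil (the **template**) lacks,
re-infer the tree, and score how well the subject is recovered.

The package is aimed at systematists and palaeontologists who want to
quantify the phylogenetic value of fossilizable data for their own
matrices, and it ships a synthetic-study generator so the entire pipeline
is testable end to end without any external data.

## What it computes

For each analysis in a factorial design (subjects × templates × group
sizes × real-vs-randomized states):

1. **Masking** — the subjects' DNA and indel cells become missing; their
   morphology survives only where the template fossil is scored
   (`artex.fossilize`).
2. **Inference** — implied-weights parsimony: each character's fit is
   `f = k/(k + e)` with `e` its extra (homoplastic) steps and concavity
   `k = 1`; the search maximizes `F = Σ f` by seeded random-addition +
   SPR/TBR swapping, holding all equally optimal trees
   (`artex.parsimony`).
3. **Scoring** — the strict consensus of the optimal trees is compared
   with a well-corroborated reference (weakly supported nodes collapsed
   at posterior probability < 0.8): shared splits, shared quartets, and
   per-subject placement accuracy (`artex.congruence`).
4. **Trends** — per-template means and OLS slopes of congruence on
   template completeness, per group size and state mode
   (`artex.experiment`, surfaced through the model interface below).

## Worked example

```python
from artex import SimConfig, build_study, ArtificialExtinction, SearchConfig

config = SimConfig(
    n_taxa=20, n_morph=200, n_dna=300, n_indel=10, n_states=3,
    completeness_levels=(0.12, 0.25, 0.40, 0.55, 0.687),
    template_block_prob=0.0, seed=7,
)
study = build_study(config)          # tree + matrix + templates + reference

model = ArtificialExtinction.from_study(
    study, group_sizes=(1, 4, 8), modes=("real", "random"),
    replicates_per_template=4,
)
results = model.fit(
    seed=7,
    search_config=SearchConfig(n_addition_replicates=1, swap="spr"),
)
print(results.summary())
```

which prints (≈2 minutes on one core):

```
========================================================================
                Artificial-Extinction Experiment Results
========================================================================
Taxa: 20     Characters: 510      Templates: 5
Jobs: 120    completed: 120    group sizes: [1, 4, 8] modes: ['real', 'random']
------------------------------------------------------------------------
Mean congruence by group size and state mode
 size    mode   splits  quartets  acc(strict)  acc(lenient)
    1  random    0.773     0.917        0.100         0.100
    1    real    0.980     0.993        0.950         0.950
    4  random    0.393     0.735        0.000         0.000
    4    real    0.940     0.984        0.925         0.938
    8  random    0.263     0.557        0.031         0.031
    8    real    0.830     0.902        0.738         0.756
...
```

Reading the table: with real states, a single artificially fossilized
subject is placed compatibly with the reference 95% of the time, and even
eight simultaneous "fossils" are mostly recovered (74%); replacing the
retained characters with random binary states destroys accuracy (≤10%)
while leaving the rest of the tree standing at small group sizes.  The
slope block below it (not shown in full) reports how mean congruence
rises with template completeness in each stratum, with standard errors.
`results.table` holds the per-job rows, `results.group_stats` the
per-template means, and `results.plot_congruence()` draws the
congruence-versus-completeness trends.

The same machinery is scriptable from the shell (`artex simulate`,
`artex plan`, `artex run`, `artex aggregate`, `artex search`,
`artex congruence`, `artex gapcode`, `artex template`, `artex convert`).

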