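# Methods

`artex` implements the *artificial extinction* protocol for asking whether
fossilizable data carry enough signal to place taxa correctly in a
combined-evidence phylogeny.  A living species with well-corroborated
affinities (the **subject**) is degraded to the preservational state of a
real fossil (the **template**): its molecular and indel characters are
deleted outright and its morphological characters are kept only where the
template fossil is scored.  The degraded matrix is re-analysed, and the
subject's recovered position is compared with a reference topology that
was derived independently of the degraded data.  Sweeping templates from
sparse to complete, and fossilizing one or many subjects at a time, maps
how phylogenetic accuracy responds to the quantity of hard-tissue data.

## Inference: implied-weights parsimony

Each analysis is an unrooted parsimony search under Goloboff implied
weighting.  For character $c$ on tree $T$, let $s_c(T)$ be its minimum
number of changes on $T$ (Fitch counting for unordered characters; a
linear-cost Wagner dynamic program for ordered ones, with missing and
polymorphic cells contributing their full state sets), and $m_c$ its
minimum over all trees (for unordered characters the minimum hitting-set
size of the tip state sets minus one; for ordered characters the spread
of the observed range).  The extra steps $e_c = s_c - m_c$ give the fit

$$f_c = \frac{k}{k + e_c},\qquad F(T) = \sum_c f_c,$$

maximized over topologies with concavity $k = 1$ by default.  Characters
whose extra steps are identically zero on every topology (constant,
autapomorphic, or otherwise parsimony-uninformative) contribute a fixed
$f_c = 1$ and are excluded from the search inner loop; duplicate character
patterns are pooled with weights.  The inner loop evaluates Fitch/interval
passes over all patterns simultaneously (JIT-compiled when numba is
available; a pure-numpy path computes identical scores otherwise).

The search uses random-addition-sequence starting trees refined by
first-improvement SPR or TBR branch swapping with seeded move ordering.
All distinct topologies tying the best fit are retained (default cap
1000).  Because the placement of a data-poor subject is the dominant
source of equally optimal trees, the experiment driver additionally
prunes each subject from the best tree, rescores every reattachment
edge, and adds all tied placements to the optimal set before taking the
strict consensus.  This deliberately targets ambiguity where artificial
extinction creates it; joint ambiguity across several subjects is still
explored only through the search's own tie collection, so consensus
resolution is an upper bound for extreme multi-subject designs.

On every instance small enough to enumerate (≤7 taxa) the heuristic with
default settings has matched the exhaustive optimum across all seeded
trials in the test suite.  Experiment-scale runs use a reduced
configuration (one or two addition replicates, SPR) chosen to keep a
~200–500 job experiment in the minutes range on one core; this is a
problem-size choice, and the `SearchConfig` dataclass exposes all knobs.

## Congruence scoring

The reference ("well-corroborated") tree is first pruned of weak
structure: internal edges with support strictly below 0.8, and any
explicitly blacklisted splits, are contracted.  Two reference-normalized
indices are reported on the common leaf set:

* **shared splits** — the fraction of the reference's non-trivial splits
  present in the test tree;
* **shared quartets** — the fraction of reference-resolved four-taxon
  subsets resolved identically in the test tree (quartets the test tree
  leaves unresolved count as unshared).  Quartets are enumerated
  exhaustively, using the four-point condition on unit-length path
  distances, which is exact for trees with polytomies; at the intended
  scale (≤44 taxa, ~135k quartets) this is effectively instant.

Both indices are asymmetric by design: the reference is the truth
standard, so resolving structure the reference leaves open is neither
rewarded nor punished, and collapsing test-tree edges can only lower
congruence (monotonicity is property-tested).

**Per-subject accuracy.**  Both trees are rooted at a designated root
(outgroup) taxon, which is never a subject.  The rooted clades containing
a subject form a nested chain describing everything the tree asserts
about that subject's position.  A subject is *accurately reconstructed*
when every consensus clade containing it is compatible (nested or
disjoint) with every reference clade containing it.  Conflicts among
backbone taxa that do not involve the subject's own chain are charged to
the congruence indices, not to the subject.  Two resolution conventions
are reported side by side: **strict** (a subject in no non-trivial clade —
a wholly unresolved placement — counts as inaccurate; the default,
because an uninformative star consensus should not score as perfect) and
**lenient** (absence of contradiction suffices).  This operational
definition was chosen from several candidates because it is the only one
that simultaneously (i) leaves single-subject accuracy high when the
backbone is noisy but the subject is well placed, (ii) degrades when
co-fossilized subjects attach to each other spuriously, and (iii)
punishes random-state controls; the alternatives — charging the subject
with every conflict on its root path, or only with conflicts that vanish
when the subject is deleted — fail (i) and (ii) respectively.

## Experimental design

`enumerate_plan` builds the full factorial design: exhaustive
subject × template combinations for single subjects, and seeded random
subject groups (2–32, drawn without replacement) for multi-subject
analyses, each duplicated with real and with randomized binary states.
With 43 subjects, 23 templates, six group sizes and two state modes this
reproduces the published arithmetic: 989 single-subject real-state
analyses and 11 868 analyses overall.  Three further conventions:

* multi-subject draws are **blocked on the replicate index** — every
  template sees the same subject groups — so template and mode contrasts
  are within-subject rather than confounded with subject identity;
* random states are Bernoulli(1/2) over {0, 1} regardless of a
  character's observed state count, drawn only at template-scored
  positions so the noise control has exactly the completeness of its
  real-state twin;
* every job carries a seed derived by hashing (master seed, template,
  group size, replicate, mode), making the whole experiment reproducible
  row-for-row, resumable, and independent of execution order.

Aggregation weights templates equally (per-template means are the
quantity of interest), and fits ordinary least-squares slopes of mean
congruence on template completeness per (group size, mode) stratum, with
standard errors from statsmodels; slopes are reported as undefined with
fewer than three completeness levels.

## Synthetic studies

The generator emulates the shape of the motivating shrew dataset: by
default 44 extant taxa on an ultrametric birth–death tree (birth 1.0,
death 0.5 per lineage per unit time, conditioned on the tip count via the
general sampling approach, depth rescaled to 1), carrying 217 discrete
morphological characters (2–3 states, ~10% ordered), 26 binary
indel-like characters and 18 762 DNA columns, with 10% missingness.
Characters evolve under the symmetric Mk model with per-character
gamma(α, α) rate multipliers (α = 0.8); ordered characters step only
between neighbouring states (exact CTMC via matrix exponentials).

Two calibrations are the generator's scientific anchors:

* **Homoplasy.**  The default morphology rate (1.5 expected changes per
  character per unit depth) gives ensemble consistency indices near 0.43
  on the generating tree, in the range of published morphological
  matrices; a much cleaner matrix would make sparse templates
  unrealistically powerful.
* **Reference supports.**  Real reference trees have weakly supported
  nodes collapsed before congruence is scored.  The synthetic reference
  assigns each split a posterior-like support $1 - e^{-E/8}$, where $E$
  is the expected number of character changes on the edge (length times
  summed per-partition rates), so edges the data cannot resolve fall
  below the 0.8 collapse threshold just as they would in a Bayesian
  reference.  Without this, single-subject accuracy is dominated by
  edges no method could recover.

Fossil templates are boolean masks at requested completeness levels
(realized within one character); each template is either a contiguous
character block (probability 0.5 by default, mimicking anatomical
clustering — jaws and teeth preserve together) or a uniform sample.
Trend experiments use uniform masks (`template_block_prob=0`), because
block position adds template-level variance orthogonal to completeness.

**What the generator does not emulate.**  Morphology evolves on the same
tree that serves as the reference, so there is no systematic conflict
between morphological signal and the molecular reference (real matrices
have convergence); characters are independent; DNA has no substitution
model structure beyond symmetric 4-state Mk; missingness is uniform
rather than taxon- or region-structured.  Passing tests therefore show
that the machinery behaves correctly under aligned signal and realistic
noise levels — not that any particular empirical accuracy value will be
reproduced.

A seeded oracle experiment (exhaustive search on 6-taxon studies, 200
characters) establishes the generator's reference behaviour: under
strong rate heterogeneity (α = 0.5, rate 0.15) the generating tree is
recovered in ≈90% of runs whose internal edges are all statistically
resolvable; recovery plateaus there because birth–death trees keep
producing a tail of near-zero internal edges, not because of character
noise.

## Desk-scale results and their reading

The acceptance experiment runs 20-taxon studies (200 morphological
characters, 300 DNA columns, five completeness levels from 12% to 69%,
group sizes 1/4/8, both state modes, ~5–6 subject groups per cell, every
job independently seeded; the suite pools three independently generated
studies).  Its stable findings mirror the published qualitative pattern:
congruence with the reference rises with template completeness under
real states (and the slope steepens as more subjects are fossilized
simultaneously), overall similarity falls as group size grows, real
states beat the random-state control by a wide margin, and pooled
placement accuracy declines from single-subject to eight-subject
designs.  Per-study accuracy-versus-size contrasts are noisier than the
congruence indices (binary per-subject outcomes, 25–30 per cell) and are
asserted only on the pooled design.  One deliberate subtlety: at group
size 1 the random-state control can score *higher* placement accuracy
than real states with the sparsest templates — junk data lands a subject
in a weakly asserted position that rarely contradicts the reference,
whereas sparse real data can actively (if wrongly) attract a subject
into a specific clade.  The congruence indices, which reward asserting
correct structure rather than asserting nothing, order the modes as
expected everywhere.

## Numerical conventions and edge cases

* Character indices are 0-based internally and 1-based in files and logs
  (NEXUS convention); morphology `-` (inapplicable) is treated as
  missing, while DNA `-` is kept as a gap state so indels can be coded.
* Gap coding follows simple indel coding restricted to codon-preserving
  events: a maximal gap run is a character only if its length is a
  positive multiple of three and it is shared with identical boundaries
  by at least two taxa; taxa with overlapping but non-identical gaps, or
  missing data in the region, are scored unknown.
* Fit ties in the search are resolved by keeping all tied trees (strict
  consensus downstream expects the full optimal set); floating-point
  ties use an absolute tolerance of 1e-9 on F.
* `collapse_low_support` contracts edges with support strictly below the
  threshold ("under 0.8"); splits with no recorded support are retained.
* Degenerate inputs fail loudly: empty taxon sets, all-missing fossils,
  templates whose mask length does not match the morphology partition,
  group sizes exceeding the subject pool, congruence on fewer than four
  common taxa.
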