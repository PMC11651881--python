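"""Congruence indices, reference collapsing, and subject placement accuracy."""

import itertools

import numpy as np
import pytest

from artex.congruence import (
    ReferenceTreeConfig,
    collapse_low_support,
    compare_trees,
    shared_quartets,
    shared_splits,
    subject_accuracy,
)
from artex.treeutils import PhyloTree, TreeError, random_resolved_tree
from oracles import brute_shared_quartets


class TestCollapseLowSupport:
    def test_support_just_below_threshold_collapsed(self):
        t = PhyloTree.from_newick("(((A,B)0.79,C),(D,E));")
        c = collapse_low_support(t, ReferenceTreeConfig())
        assert t.mask_of("AB") not in {m if not m & 1 else m for m in c.clades}
        assert len(c.clades) == len(t.clades) - 1

    def test_support_at_threshold_retained(self):
        t = PhyloTree.from_newick("(((A,B)0.80,C),(D,E));")
        c = collapse_low_support(t, ReferenceTreeConfig())
        assert len(c.clades) == len(t.clades)

    def test_full_support_identity(self):
        t = PhyloTree.from_newick("(((A,B)1.0,C)1.0,(D,E)1.0);")
        assert collapse_low_support(t, ReferenceTreeConfig()) == t

    def test_explicit_conflict_list_collapsed(self):
        t = PhyloTree.from_newick("(((A,B)1.0,C)1.0,(D,E)1.0);")
        cfg = ReferenceTreeConfig(conflict_collapse_list=[{"D", "E"}])
        c = collapse_low_support(t, cfg)
        assert len(c.clades) == len(t.clades) - 1

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ReferenceTreeConfig(support_threshold=1.5)


class TestSharedSplits:
    def test_identity_is_one(self):
        t = PhyloTree.from_newick("(((A,B),(C,D)),(E,F));")
        assert shared_splits(t, t) == 1.0

    def test_star_against_resolved_is_zero(self):
        ref = PhyloTree.from_newick("(((A,B),(C,D)),(E,F));")
        star = PhyloTree(ref.taxa)
        assert shared_splits(star, ref) == 0.0

    def test_half_shared(self):
        # 5-taxon reference with 2 non-trivial splits, test sharing exactly 1
        ref = PhyloTree.from_newick("(((A,B),C),(D,E));")
        test = PhyloTree.from_newick("(((A,B),D),(C,E));")
        assert ref.clades & test.clades  # AB is common
        assert shared_splits(test, ref) == 0.5

    def test_unresolved_reference_returns_one(self):
        ref = PhyloTree(("A", "B", "C", "D"))
        test = PhyloTree.from_newick("((A,B),(C,D));")
        assert shared_splits(test, ref) == 1.0

    def test_too_few_common_taxa_rejected(self):
        a = PhyloTree.from_newick("((A,B),(C,X));")
        b = PhyloTree.from_newick("((A,B),(Y,Z));")
        with pytest.raises(TreeError):
            shared_splits(a, b)

    def test_computed_on_common_leaf_subset(self):
        ref = PhyloTree.from_newick("(((A,B),(C,D)),(E,F));")
        test = PhyloTree.from_newick("((A,B),(C,D),G);")
        # common leaves A-D: reference restricted has one split, shared
        assert shared_splits(test, ref) == 1.0


class TestSharedQuartets:
    def test_identity_and_star(self):
        ref = PhyloTree.from_newick("(((A,B),(C,D)),(E,F));")
        assert shared_quartets(ref, ref) == 1.0
        assert shared_quartets(PhyloTree(ref.taxa), ref) == 0.0

    def test_nni_neighbor_value_matches_enumeration(self):
        # 5 taxa, one NNI apart; value derived by listing all 5 quartets
        ref = PhyloTree.from_newick("(((A,B),C),(D,E));")
        test = PhyloTree.from_newick("(((A,C),B),(D,E));")
        expect = brute_shared_quartets(test, ref)
        assert shared_quartets(test, ref) == pytest.approx(expect)
        # the three quartets not separating A from B/C survive the NNI
        assert expect == pytest.approx(3 / 5)

    def test_matches_brute_force_on_random_pairs(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(10):
            a = random_resolved_tree(taxa, rng)
            b = random_resolved_tree(taxa, rng)
            # partially collapse both
            ap = PhyloTree(taxa, [c for c in a.clades if rng.random() < 0.7])
            bp = PhyloTree(taxa, [c for c in b.clades if rng.random() < 0.7])
            assert shared_quartets(ap, bp) == pytest.approx(
                brute_shared_quartets(ap, bp)
            )

    def test_rerooting_invariance(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        a = random_resolved_tree(taxa, rng)
        b = random_resolved_tree(taxa, rng)
        # rewriting from a different rooting must not change either index
        a2 = PhyloTree.from_newick(a.to_newick())
        assert shared_quartets(a2, b) == shared_quartets(a, b)
        assert shared_splits(a2, b) == shared_splits(a, b)


class TestMonotonicityUnderCollapse:
    def test_collapsing_test_edges_never_increases_congruence(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(8):
            ref = random_resolved_tree(taxa, rng)
            test = random_resolved_tree(taxa, rng)
            clades = sorted(test.clades)
            ss, sq = shared_splits(test, ref), shared_quartets(test, ref)
            while clades:
                clades.pop(int(rng.integers(len(clades))))
                coarser = PhyloTree(taxa, clades)
                ss2 = shared_splits(coarser, ref)
                sq2 = shared_quartets(coarser, ref)
                assert ss2 <= ss + 1e-12 and sq2 <= sq + 1e-12
                ss, sq = ss2, sq2


class TestSubjectAccuracy:
    def setup_method(self):
        self.ref = PhyloTree.from_newick("((((A,B),C),(D,E)),(F,G));")

    def test_correct_sister_recovery_accurate(self):
        cons = PhyloTree.from_newick("((((A,B),C),(D,E)),(F,G));")
        r = subject_accuracy(cons, self.ref, ["B"], root_taxon="G")
        assert r.subject_accuracy["B"] and r.accuracy == 1.0

    def test_subject_inside_wrong_clade_inaccurate(self):
        cons = PhyloTree.from_newick("(((A,C),(D,(B,E))),(F,G));")
        for mode in ("strict", "lenient"):
            r = subject_accuracy(cons, self.ref, ["B"], "G", mode)
            assert not r.subject_accuracy["B"]

    def test_star_consensus_lenient_vs_strict(self):
        star = PhyloTree(self.ref.taxa)
        assert subject_accuracy(star, self.ref, ["B"], "G", "lenient").accuracy == 1.0
        assert subject_accuracy(star, self.ref, ["B"], "G", "strict").accuracy == 0.0

    def test_backbone_error_elsewhere_not_charged_to_subject(self):
        # the D/E/F subclade is misresolved, but every clade containing B
        # keeps the same composition: B itself is still accurately placed
        ref = PhyloTree.from_newick("((((A,B),C),((D,E),F)),(G,H));")
        cons = PhyloTree.from_newick("((((A,B),C),((D,F),E)),(G,H));")
        r = subject_accuracy(cons, ref, ["B"], "H")
        assert r.subject_accuracy["B"]
        assert r.shared_splits < 1.0  # the error is charged to congruence

    def test_subject_missing_from_tree_rejected(self):
        with pytest.raises(TreeError):
            subject_accuracy(self.ref, self.ref, ["ZZ"], "G")

    def test_aggregate_is_mean_of_booleans(self):
        cons = PhyloTree.from_newick("(((A,C),(D,(B,E))),(F,G));")
        r = subject_accuracy(cons, self.ref, ["B", "C"], "G")
        vals = [r.subject_accuracy["B"], r.subject_accuracy["C"]]
        assert r.accuracy == pytest.approx(np.mean(vals))


class TestRealVersusRandomStates:
    def test_real_states_beat_random_states(self, small_study):
        """Placement accuracy with real states must exceed the random-state
        noise control when pooled over a matched design (>= 200 jobs)."""
        from artex.model import ArtificialExtinction
        from artex.parsimony import SearchConfig

        model = ArtificialExtinction.from_study(
            small_study,
            group_sizes=(1, 2, 4),
            modes=("real", "random"),
            replicates_per_template=12,
        )
        res = model.fit(
            seed=2,
            search_config=SearchConfig(
                n_addition_replicates=1, swap="spr", max_trees_held=64
            ),
        )
        t = res.table
        assert len(t) >= 200 and (t["error"] == "").all()
        real = t[t["mode"] == "real"]["accuracy_strict"].astype(float)
        rand = t[t["mode"] == "random"]["accuracy_strict"].astype(float)
        assert real.mean() > rand.mean()
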