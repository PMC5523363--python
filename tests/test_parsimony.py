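import numpy as np
import pytest
from _oracles import enumerate_optimal_labelings, random_case

from gmycdelim import CharacterMatrix, fitch_length, optimize_characters
from gmycdelim.parsimony import (
    PNode,
    collapse_unsupported,
    heuristic_search,
    reroot_on_outgroup,
)
from gmycdelim.seqio import AlignedSeq, Alignment


def topology(nwk_like):
    """Tiny helper: build a PNode tree from nested tuples."""

    def rec(x):
        if isinstance(x, str):
            return PNode(x)
        n = PNode()
        for c in x:
            n.add(rec(c))
        return n

    return rec(nwk_like)


def matrix(rows):
    return CharacterMatrix.from_alignment(
        Alignment([AlignedSeq(k, v) for k, v in rows.items()])
    )


class TestFitchLength:
    def test_single_informative_site(self):
        t = topology((("a", "b"), ("c", "d")))
        m = matrix({"a": "A", "b": "A", "c": "G", "d": "G"})
        assert fitch_length(t, m) == 1

    def test_constant_site_zero(self):
        t = topology((("a", "b"), ("c", "d")))
        m = matrix({k: "T" for k in "abcd"})
        assert fitch_length(t, m) == 0

    def test_missing_states_are_wildcards(self):
        t = topology((("a", "b"), ("c", "d")))
        m = matrix({"a": "A", "b": "N", "c": "G", "d": "-"})
        assert fitch_length(t, m) == 1

    def test_tip_mismatch_rejected(self):
        t = topology((("a", "b"), ("c", "x")))
        m = matrix({"a": "A", "b": "A", "c": "G", "d": "G"})
        with pytest.raises(ValueError, match="match"):
            fitch_length(t, m)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            root, masks = random_case(rng, 6, 4)
            ids = [f"t{i}" for i in range(6)]
            cm = CharacterMatrix(ids, masks)
            base = fitch_length(root, cm)
            for og in ids:
                assert fitch_length(reroot_on_outgroup(root, og), cm) == base

    def test_matches_exhaustive_minimum(self):
        # brute force over all ancestral assignments on small random cases
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 7))
            root, masks = random_case(rng, n, int(rng.integers(1, 4)))
            cm = CharacterMatrix([f"t{i}" for i in range(n)], masks)
            total = 0
            for j in range(masks.shape[1]):
                tm = {f"t{i}": int(masks[i, j]) for i in range(n)}
                best, _, _ = enumerate_optimal_labelings(root, tm)
                total += best
            assert fitch_length(root, cm) == total


class TestOptimizeCharacters:
    def test_clean_synapomorphy_unambiguous_nonhomoplasious(self):
        t = topology((("a", "b"), ("c", "d")))
        m = matrix({"a": "A", "b": "A", "c": "G", "d": "G"})
        opt = optimize_characters(t, m)
        un = opt.unambiguous_changes()
        assert len(un) == 1
        assert un[0].homoplasious is False
        assert un[0].clade in (frozenset("ab"), frozenset("cd"))

    def test_convergent_site_never_clean_synapomorphy(self):
        # ((a,c1),(a2,c2)) with states A,G,A,G: two changes (homoplasy)
        # or one change ambiguously placed; never unambiguous AND
        # non-homoplasious
        t = topology((("a1", "c1"), ("a2", "c2")))
        m = matrix({"a1": "A", "c1": "G", "a2": "A", "c2": "G"})
        opt = optimize_characters(t, m)
        assert not opt.unambiguous_changes(homoplasious=False)

    def test_site_minimum_at_least_theoretical(self):
        rng = np.random.default_rng(7)
        root, masks = random_case(rng, 6, 5)
        cm = CharacterMatrix([f"t{i}" for i in range(6)], masks)
        opt = optimize_characters(root, cm)
        assert (opt.site_min_changes >= opt.site_theoretical_min).all()

    def test_matches_exhaustive_classification(self):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            root, masks = random_case(rng, n, 2)
            cm = CharacterMatrix([f"t{i}" for i in range(n)], masks)
            opt = optimize_characters(root, cm)
            for j in range(2):
                tm = {f"t{i}": int(masks[i, j]) for i in range(n)}
                best, always, _ = enumerate_optimal_labelings(root, tm)
                got = {
                    c.clade for c in opt.changes
                    if c.site == j and c.unambiguous
                }
                want = {
                    clade for clade, flag in always.items() if flag and best > 0
                }
                assert got == want

    def test_branch_changes_bounded_by_tree_length(self):
        rng = np.random.default_rng(5)
        root, masks = random_case(rng, 6, 5)
        cm = CharacterMatrix([f"t{i}" for i in range(6)], masks)
        opt = optimize_characters(root, cm)
        n_unamb = len(opt.unambiguous_changes())
        assert n_unamb <= opt.tree_length == fitch_length(root, cm)


@pytest.fixture(scope="module")
def small_fixture():
    from gmycdelim.synthetic import (
        ScenarioConfig,
        fixture_species_tree,
        simulate_gene_tree,
        simulate_sequences,
    )

    cfg = ScenarioConfig(
        n_species=4, tips_per_species=(2, 1, 3, 2),
        coalescent_size=0.5, substitution_rate=0.003, sites=825, seed=3,
    )
    sp = fixture_species_tree(include_outgroup=True)
    gt, labels = simulate_gene_tree(sp, cfg)
    aln = simulate_sequences(gt, cfg, labels=labels)
    return gt, CharacterMatrix.from_alignment(aln)


class TestHeuristicSearch:
    def test_finds_generating_topology_length(self, small_fixture):
        gene_tree, cm = small_fixture
        truth_len = fitch_length(gene_tree, cm)
        res = heuristic_search(cm, outgroup="aubei_1", reps=5, seed=0)
        assert res.best_length == truth_len

    def test_more_reps_never_worse(self, small_fixture):
        _, cm = small_fixture
        l1 = heuristic_search(cm, reps=1, seed=9).best_length
        l5 = heuristic_search(cm, reps=5, seed=9).best_length
        assert l5 <= l1

    def test_tip_order_permutation_invariant(self, small_fixture):
        _, cm = small_fixture
        perm = np.random.default_rng(2).permutation(len(cm.ids))
        cm2 = CharacterMatrix(
            [cm.ids[i] for i in perm], cm.masks[perm]
        )
        a = heuristic_search(cm, reps=3, seed=4).best_length
        b = heuristic_search(cm2, reps=3, seed=4).best_length
        assert a == b

    def test_outgroup_rooting(self, small_fixture):
        _, cm = small_fixture
        res = heuristic_search(cm, outgroup="aubei_1", reps=2, seed=0)
        for t in res.trees:
            assert "aubei_1" in [c.label for c in t.children]

    def test_collapse_unsupported_reduces_or_keeps_nodes(self, small_fixture):
        _, cm = small_fixture
        res = heuristic_search(cm, outgroup="aubei_1", reps=2, seed=0)
        t = res.trees[0]
        collapsed = collapse_unsupported(t, cm)
        n_before = sum(1 for n in t.postorder() if not n.is_leaf)
        n_after = sum(1 for n in collapsed.postorder() if not n.is_leaf)
        assert n_after <= n_before
        assert sorted(n.label for n in collapsed.leaves()) == sorted(cm.ids)
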