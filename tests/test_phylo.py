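"""Distances, neighbour joining, bootstrap supports and clade PD."""

import math

import numpy as np
import pytest

from rieskeq import phylo, simulate
from rieskeq.phylo import (
    DistanceMatrix,
    Tree,
    TreeNode,
    clade_pd,
    distance_matrix,
    neighbor_joining,
    pairwise_distance,
    read_newick,
    tree_to_distance_matrix,
    write_newick,
)
from rieskeq.seqcore import Alignment, SequenceRecord

# 60-bp pair with 8 differences; expected distances frozen from an
# independent computation with ape::dist.dna (models TN93 / JC69 / raw).
_S1 = "ACGTACGTGGCCAATTACGTACGTGGCCAATTACGTACGTGGCCAATTACGGTTCCAAGG"
_S2 = "ACATACGTGACCAATCACGTACATGGCCTATTACGAACGTGGCCAGTTACGGCTCCAAGG"


def _aln(seqs, prefix="s"):
    return Alignment(
        [SequenceRecord(id=f"{prefix}{i}", seq=s) for i, s in enumerate(seqs, 1)]
    )


class TestPairwiseDistance:
    @pytest.mark.parametrize("model", ["p", "jc69", "tn93"])
    def test_identical_sequences_are_zero(self, model):
        assert pairwise_distance(_S1, _S1, model=model) == pytest.approx(0.0)

    def test_p_distance_simple(self):
        assert pairwise_distance("AAAA", "AAAT", model="p") == pytest.approx(0.25)

    def test_jc69_closed_form(self):
        # p = 0.25 -> -(3/4) ln(1 - 1/3)
        d = pairwise_distance("AAAA", "AAAT", model="jc69")
        assert d == pytest.approx(-(0.75) * math.log(1 - 4 * 0.25 / 3), abs=1e-12)
        assert d == pytest.approx(0.3041, abs=1e-4)

    @pytest.mark.parametrize(
        "model,expected",
        [("tn93", 0.1516252939), ("jc69", 0.1468084328), ("p", 0.1333333333)],
    )
    def test_against_independent_reference(self, model, expected):
        assert pairwise_distance(_S1, _S2, model=model) == pytest.approx(
            expected, abs=1e-9
        )

    def test_gap_sites_excluded_pairwise(self):
        # gap column is dropped, leaving 3 comparable sites with 1 diff
        assert pairwise_distance("A-CT", "AGCA", model="p") == pytest.approx(1 / 3)

    def test_zero_comparable_sites_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("--", "AA", model="p")

    def test_saturated_pair_flagged_nan(self):
        assert math.isnan(pairwise_distance("AAAA", "TTTT", model="jc69"))


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        root = rng.choice(list("ACGT"), 100)
        seqs = []
        for _ in range(5):
            s = root.copy()
            for i in rng.choice(100, size=15, replace=False):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            seqs.append("".join(s))
        dm = distance_matrix(_aln(seqs), model="jc69")
        assert not dm.undefined_pairs
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)

    def test_saturation_ceiling_applied(self):
        aln = _aln(["AAAAAAAA", "TTTTTTTT"])
        with pytest.warns(phylo.SaturationWarning):
            dm = distance_matrix(aln, model="jc69", saturation_ceiling=5.0)
        assert dm.d[0, 1] == 5.0
        assert dm.undefined_pairs == [("s1", "s2")]

    def test_tsv_round_trip(self, tmp_path, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        dm = distance_matrix(_aln(seqs), model="p")
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == dm.labels
        assert np.allclose(back.d, dm.d)


class TestNeighborJoining:
    def test_four_taxon_exact_recovery(self):
        # ((A:0.1, B:0.2):0.05, C:0.3, D:0.4)
        truth = Tree(
            TreeNode(
                children=[
                    TreeNode(
                        length=0.05,
                        children=[
                            TreeNode(name="A", length=0.1),
                            TreeNode(name="B", length=0.2),
                        ],
                    ),
                    TreeNode(name="C", length=0.3),
                    TreeNode(name="D", length=0.4),
                ]
            )
        )
        dm = tree_to_distance_matrix(truth)
        nj = neighbor_joining(dm)
        em_t, em_n = truth.edge_map(), nj.edge_map()
        assert set(em_t) == set(em_n)
        for key in em_t:
            assert em_n[key][0] == pytest.approx(em_t[key][0], abs=1e-12)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            d=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.4)

    def test_additive_oracle_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            truth = simulate.random_tree(n, rng)
            nj = neighbor_joining(tree_to_distance_matrix(truth))
            em_t, em_n = truth.edge_map(), nj.edge_map()
            assert set(em_t) == set(em_n)
            for key in em_t:
                assert em_n[key][0] == pytest.approx(em_t[key][0], abs=1e-9)

    def test_robust_to_tiny_perturbation(self, rng):
        truth = simulate.random_tree(6, rng)
        dm = tree_to_distance_matrix(truth)
        noise = rng.uniform(-1e-6, 1e-6, dm.d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        nj = neighbor_joining(DistanceMatrix(dm.labels, np.abs(dm.d + noise)))
        assert nj.bipartitions() == truth.bipartitions()

    def test_matches_independent_nj_topology(self, rng):
        skbio = pytest.importorskip("skbio")
        # related sequences (common ancestor, moderate divergence) so no
        # pairwise distance saturates
        root = rng.choice(list("ACGT"), 300)
        seqs = []
        for _ in range(6):
            s = root.copy()
            for i in rng.choice(300, size=60, replace=False):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            seqs.append("".join(s))
        dm = distance_matrix(_aln(seqs), model="jc69")
        assert not dm.undefined_pairs
        ours = neighbor_joining(dm)
        ref = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
        ref_biparts = set()
        all_leaves = frozenset(dm.labels)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                ref_biparts.add(frozenset({side, all_leaves - side}))
        assert ours.bipartitions() == ref_biparts

    def test_too_few_taxa(self):
        dm = DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)


class TestNewick:
    def test_three_leaf_string_form(self):
        tree = Tree(
            TreeNode(
                children=[
                    TreeNode(name="A", length=0.1),
                    TreeNode(name="B", length=0.2),
                    TreeNode(name="C", length=0.3),
                ]
            )
        )
        assert tree.to_newick() == "(A:0.1,B:0.2,C:0.3);"

    def test_round_trip_with_supports(self, tmp_path, rng):
        truth = simulate.random_tree(7, rng)

        def tag(node, s=[80]):
            for ch in node.children:
                if not ch.is_leaf:
                    ch.support = float(s[0])
                    s[0] += 5
                    tag(ch, s)

        tag(truth.root)
        write_newick(truth, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        em_t, em_b = truth.edge_map(), back.edge_map()
        assert set(em_t) == set(em_b)
        for key, (length, support) in em_t.items():
            assert em_b[key][0] == pytest.approx(length, abs=1e-9)
            assert em_b[key][1] == support

    def test_support_appears_as_internal_label(self):
        inner = TreeNode(
            length=0.05,
            support=87.0,
            children=[TreeNode(name="A", length=0.1), TreeNode(name="B", length=0.2)],
        )
        tree = Tree(TreeNode(children=[inner, TreeNode(name="C", length=0.3)]))
        assert ")87:" in tree.to_newick()


@pytest.fixture(scope="module")
def two_clade_alignment():
    rng = np.random.default_rng(42)
    core = "".join(rng.choice(list("ACGT"), 200))
    other = list(core)
    for i in rng.choice(200, size=40, replace=False):  # 20% divergence
        other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
    return _aln([core, core, core, "".join(other), "".join(other), "".join(other)], prefix="x")


class TestBootstrap:
    def test_clear_split_gets_high_support(self, two_clade_alignment):
        tree = phylo.bootstrap_supports(
            two_clade_alignment, model="jc69", n_replicates=100, seed=3
        )
        split = frozenset(
            {frozenset({"x1", "x2", "x3"}), frozenset({"x4", "x5", "x6"})}
        )
        supports = {k: v[1] for k, v in tree.edge_map().items() if isinstance(k, frozenset)}
        assert supports[split] >= 95

    def test_single_replicate_gives_binary_supports(self, two_clade_alignment):
        tree = phylo.bootstrap_supports(
            two_clade_alignment, model="jc69", n_replicates=1, seed=5
        )
        vals = [v[1] for k, v in tree.edge_map().items() if isinstance(k, frozenset)]
        assert set(vals) <= {0.0, 100.0}

    def test_column_duplication_preserves_signal(self, two_clade_alignment):
        doubled = Alignment(
            [
                SequenceRecord(id=r.id, seq=r.seq + r.seq)
                for r in two_clade_alignment.records
            ]
        )
        t1 = phylo.bootstrap_supports(two_clade_alignment, "jc69", 100, seed=3)
        t2 = phylo.bootstrap_supports(doubled, "jc69", 100, seed=3)
        assert t1.bipartitions() == t2.bipartitions()
        split = frozenset(
            {frozenset({"x1", "x2", "x3"}), frozenset({"x4", "x5", "x6"})}
        )
        assert t2.edge_map()[split][1] >= 95

    def test_effective_replicates_reported(self, two_clade_alignment):
        tree = phylo.bootstrap_supports(
            two_clade_alignment, model="jc69", n_replicates=10, seed=1
        )
        assert tree.meta["n_effective_replicates"] == 10


class TestCladePd:
    def _dm(self):
        labels = ["a", "b", "c"]
        d = np.array([[0, 0.5, 0.6], [0.5, 0, 0.7], [0.6, 0.7, 0]])
        return DistanceMatrix(labels=labels, d=d)

    def test_sister_pair_eligible(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.16], [0.16, 0]]))
        rep = clade_pd(dm, ["a", "b"])
        assert rep.pd_mean == pytest.approx(0.16)
        assert rep.eligible

    def test_singleton_is_zero_and_eligible(self):
        rep = clade_pd(self._dm(), ["a"])
        assert rep.pd_mean == rep.pd_max == 0.0
        assert rep.eligible

    def test_divergent_triple_not_eligible(self):
        rep = clade_pd(self._dm(), ["a", "b", "c"])
        assert rep.pd_mean == pytest.approx(0.6)
        assert rep.pd_max == pytest.approx(0.7)
        assert not rep.eligible

    def test_order_invariance(self):
        r1 = clade_pd(self._dm(), ["a", "b", "c"])
        r2 = clade_pd(self._dm(), ["c", "a", "b"])
        assert r1.pd_mean == r2.pd_mean and r1.pd_max == r2.pd_max

    def test_duplicate_member_cannot_increase_pd_max(self):
        labels = ["a", "b", "a2"]
        d = np.array([[0, 0.4, 0.0], [0.4, 0, 0.4], [0.0, 0.4, 0]])
        dm = DistanceMatrix(labels=labels, d=d)
        base = clade_pd(dm, ["a", "b"])
        extended = clade_pd(dm, ["a", "b", "a2"])
        assert extended.pd_max <= base.pd_max

    def test_unknown_member_rejected(self):
        with pytest.raises(KeyError, match="zz"):
            clade_pd(self._dm(), ["a", "zz"])
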