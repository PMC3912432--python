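"""Distances, neighbor joining, Newick round-trips and bootstrap supports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snadlab import (
    Alignment,
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    dayhoff_distance,
    distance_matrix,
    jc_distance,
    nj_tree,
    p_distance,
    poisson_distance,
    read_fasta,
)
from snadlab.errors import (
    DomainError,
    InvalidMatrixError,
    NoOverlapError,
    SaturationError,
)
from snadlab.phylo import AA_ALPHABET

from conftest import random_additive_tree


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.0),      # pairwise deletion drops the gapped column
            ("ACNT", "ACGT", 0.0),      # ambiguity treated like a gap
            ("A--T", "AC-T", 0.0),
        ],
    )
    def test_pairwise_deletion(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            p_distance("AC--", "--GT")

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            p_distance("ACGT", "ACG")

    def test_amino_acid_alphabet(self):
        assert p_distance("MKV", "MRV", AA_ALPHABET) == pytest.approx(1 / 3)
        # X is an ambiguity for proteins
        assert p_distance("MXV", "MRV", AA_ALPHABET) == pytest.approx(0.0)


class TestCorrections:
    @pytest.mark.parametrize(
        "fn, p, expected",
        [
            (jc_distance, 0.0, 0.0),
            (jc_distance, 0.3, 0.3831),
            (poisson_distance, 0.0, 0.0),
            (poisson_distance, 0.5, math.log(2)),
            (dayhoff_distance, 0.0, 0.0),
        ],
    )
    def test_closed_forms(self, fn, p, expected):
        assert fn(p) == pytest.approx(expected, abs=5e-5)

    def test_poisson_finite_near_saturation(self):
        assert poisson_distance(1 - 1e-9) == pytest.approx(-math.log(1e-9), rel=1e-6)

    @pytest.mark.parametrize(
        "fn, bad_p",
        [(jc_distance, 0.75), (jc_distance, 0.9), (poisson_distance, 1.0),
         (dayhoff_distance, 0.95), (jc_distance, -0.01)],
    )
    def test_saturation_errors(self, fn, bad_p):
        with pytest.raises(SaturationError):
            fn(bad_p)

    @given(p=st.floats(0.0, 0.74))
    @settings(derandomize=True, max_examples=100)
    def test_corrections_monotone_and_dominate_p(self, p):
        d = jc_distance(p)
        assert d >= p - 1e-15
        assert jc_distance(min(p + 0.005, 0.7499)) >= d
        dp = poisson_distance(p)
        assert dp >= p - 1e-15

    def test_dayhoff_short_time_limit(self):
        """For small p the Dayhoff distance is close to p itself."""
        for p in (0.005, 0.02, 0.05):
            assert dayhoff_distance(p) == pytest.approx(p, rel=0.05)

    def test_dayhoff_exceeds_poisson(self):
        for p in np.linspace(0.1, 0.7, 13):
            assert dayhoff_distance(p) > poisson_distance(p)

    def test_dayhoff_inverts_matrix_exponential_oracle(self):
        """d(p) must invert the expected-difference curve computed
        independently with scipy's expm of the embedded rate matrix."""
        from scipy.linalg import expm

        from snadlab._dayhoff import equilibrium_frequencies, rate_matrix

        pi, q = equilibrium_frequencies(), rate_matrix()
        for d_true in (0.05, 0.2, 0.5, 1.0, 2.0):
            p = 1.0 - float(pi @ np.diag(expm(q * d_true)))
            assert dayhoff_distance(p) == pytest.approx(d_true, abs=2e-5)


class TestDistanceMatrix:
    def test_from_alignment_jc(self):
        aln = Alignment(("a", "b", "c"), ("ACGTACGT", "ACGTACGA", "ACGTTTTT"), "nt")
        dm = distance_matrix(aln, "jc")
        assert dm.values[0, 1] == pytest.approx(jc_distance(1 / 8))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_model_kind_mismatch(self):
        aln = Alignment(("a", "b", "c"), ("ACGT", "ACGA", "AAAA"), "nt")
        with pytest.raises(DomainError):
            distance_matrix(aln, "poisson")

    def test_saturation_names_pair(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "CCCC", "AAAC"), "nt")
        with pytest.raises(SaturationError, match="a.*b"):
            distance_matrix(aln, "jc")

    def test_invalid_matrices_rejected(self):
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(InvalidMatrixError):
            DistanceMatrix(("a", "b"), np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # path lengths of the tree ((A:1,B:2):1,(C:3,D:4))
        ids = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(ids, d))
        pl = tree.path_lengths()
        assert pl.ids == ids
        np.testing.assert_allclose(pl.values, d, atol=1e-12)
        # the AB|CD split is an internal edge of the recovered topology
        assert frozenset(["C", "D"]) in tree.bipartitions()

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0})

    def test_equal_distances_deterministic_tie_break(self):
        d = np.ones((5, 5)) - np.eye(5)
        ids = tuple("ABCDE")
        t1 = nj_tree(DistanceMatrix(ids, d))
        t2 = nj_tree(DistanceMatrix(ids, d))
        assert t1.to_newick() == t2.to_newick()
        # lowest-index pair (A, B) joined first
        assert "(A:0.500000,B:0.500000)" in t1.to_newick()

    def test_random_additive_matrices_reproduced(self, rng):
        """NJ is exact on additive matrices: path lengths match the
        independently agglomerated generating matrix to 1e-9."""
        for n_leaves in (4, 5, 6, 7, 8):
            for _ in range(4):
                names, d = random_additive_tree(rng, n_leaves)
                tree = nj_tree(DistanceMatrix(tuple(names), d))
                pl = tree.path_lengths()
                assert pl.ids == tuple(names)  # L0..Ln sort lexically for n<=9
                np.testing.assert_allclose(pl.values, d, atol=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        """Cross-check against the independent scikit-bio NJ."""
        skbio = pytest.importorskip("skbio")
        names, d = random_additive_tree(rng, 6)
        tree = nj_tree(DistanceMatrix(tuple(names), d))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
        ours = tree.path_lengths()
        for i, a in enumerate(ours.ids):
            for j, b in enumerate(ours.ids):
                if i < j:
                    assert sk_tree.find(a).distance(sk_tree.find(b)) == pytest.approx(
                        ours.values[i, j], abs=1e-6
                    )

    def test_negative_branch_clamping_recorded(self):
        # deliberately non-additive matrix that forces a negative NJ length
        d = np.array(
            [
                [0.0, 0.655, 0.306, 0.089],
                [0.655, 0.0, 0.066, 0.823],
                [0.306, 0.066, 0.0, 0.917],
                [0.089, 0.823, 0.917, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(tuple("ABCD"), d))
        assert tree.clamp_deficit > 0
        assert all(leaf.length >= 0 for leaf in tree.root.leaves())

    def test_too_few_taxa(self):
        with pytest.raises(DomainError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestNewick:
    def test_round_trip_topology_lengths_supports(self, rng):
        names, d = random_additive_tree(rng, 6)
        tree = nj_tree(DistanceMatrix(tuple(names), d))
        for node in tree.bipartitions().values():
            node.support = 87.0
        back = PhyloTree.from_newick(tree.to_newick())
        np.testing.assert_allclose(
            back.path_lengths().values, tree.path_lengths().values, atol=1e-5
        )
        assert set(back.bipartitions()) == set(tree.bipartitions())
        assert all(n.support == 87.0 for n in back.bipartitions().values())

    def test_min_support_display_threshold(self):
        tree = nj_tree(
            DistanceMatrix(tuple("ABCD"), np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float))
        )
        node = next(iter(tree.bipartitions().values()))
        node.support = 43.0
        assert "43" in tree.to_newick()
        assert "43" not in tree.to_newick(min_support=50.0)

    def test_file_round_trip(self, tmp_path, rng):
        names, d = random_additive_tree(rng, 5)
        tree = nj_tree(DistanceMatrix(tuple(names), d))
        p = tmp_path / "tree.nwk"
        tree.write(p)
        back = PhyloTree.read(p)
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)


class TestBootstrap:
    def _two_group_alignment(self, n_sites=120):
        left = "A" * (n_sites // 2) + "C" * (n_sites - n_sites // 2)
        right = "G" * (n_sites // 2) + "C" * (n_sites - n_sites // 2)

        def perturb(s, k):
            # a couple of private substitutions so distances are positive
            chars = list(s)
            chars[k] = "T"
            return "".join(chars)

        return Alignment(
            ("a1", "a2", "b1", "b2"),
            (perturb(left, 0), perturb(left, 1), perturb(right, 2), perturb(right, 3)),
            "nt",
        )

    def test_clear_split_gets_full_support(self):
        aln = self._two_group_alignment()
        tree = bootstrap_support(aln, model="jc", n_reps=50, seed=1)
        (key, node), = tree.bipartitions().items()
        assert node.support == pytest.approx(100.0)

    def test_deterministic_for_fixed_seed(self, rng):
        gen = PhyloTree.from_newick("((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.02,E:0.1);")
        from snadlab import evolve_sequences

        aln = evolve_sequences(gen, 200, "nt", seed=9)
        t1 = bootstrap_support(aln, "jc", n_reps=10, seed=77)
        t2 = bootstrap_support(aln, "jc", n_reps=10, seed=77)
        assert t1.to_newick() == t2.to_newick()
        t3 = bootstrap_support(aln, "jc", n_reps=10, seed=78)
        assert sorted(t3.leaf_names) == sorted(t1.leaf_names)

    def test_support_stability_with_replicate_count(self):
        """Support estimates stabilize: 500 vs 2000 replicates agree
        within 5 percentage points per branch."""
        gen = PhyloTree.from_newick(
            "((A:0.08,B:0.08):0.04,(C:0.08,D:0.08):0.04,E:0.12);"
        )
        from snadlab import evolve_sequences

        aln = evolve_sequences(gen, 300, "nt", seed=5)
        t500 = bootstrap_support(aln, "jc", n_reps=500, seed=11)
        t2000 = bootstrap_support(aln, "jc", n_reps=2000, seed=12)
        s500 = {k: n.support for k, n in t500.bipartitions().items()}
        s2000 = {k: n.support for k, n in t2000.bipartitions().items()}
        assert set(s500) == set(s2000)
        for k in s500:
            assert abs(s500[k] - s2000[k]) < 5.0

    def test_saturated_replicates_dropped_and_counted(self):
        # maximally divergent pair saturates JC in every replicate
        aln = Alignment(("a", "b", "c"), ("AAAA", "CCCC", "AACC"), "nt")
        with pytest.raises(SaturationError):
            bootstrap_support(aln, "jc", n_reps=5, seed=0)


class TestFastaIO:
    def test_read_wrapped_fasta_with_gaps(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">s1 first\nACGT\nAC-T\n>s2\nACGA\nACGT\n>s3\nACGT\nAAAA\n")
        aln = read_fasta(p)
        assert aln.kind == "nt"
        assert aln.ids == ("s1", "s2", "s3")
        assert aln.rows[0] == "ACGTAC-T"

    def test_kind_inference_amino_acid(self, tmp_path):
        p = tmp_path / "aa.fasta"
        p.write_text(">p1\nMKVLW\n>p2\nMKVLF\n>p3\nMRVLW\n")
        assert read_fasta(p).kind == "aa"
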