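"""p-distances, neighbor-joining, bootstrap, subgroups, similarity."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from prxfam import (
    AlignedProteinSet,
    assign_subgroups,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    pairwise_similarity,
)
from prxfam.phylo import read_newick, tree_splits, write_newick

from .conftest import random_additive_tree_distances


class TestPDistance:
    def test_simple_mismatch_fraction(self):
        a = AlignedProteinSet(
            ids=["x", "y", "z"], rows=["ACDEF", "ACDFF", "ACDEF"]
        )
        d = p_distance_matrix(a)
        assert d.loc["x", "y"] == pytest.approx(0.2)
        assert d.loc["x", "z"] == 0.0

    def test_identical_rows_zero_matrix(self):
        a = AlignedProteinSet(ids=list("abc"), rows=["MKV"] * 3)
        assert (p_distance_matrix(a).to_numpy() == 0).all()

    def test_gap_column_excluded_for_all_pairs(self):
        # column 2 gapped only in row z, but complete deletion removes it
        # from EVERY pairwise comparison, including (x, y)
        a = AlignedProteinSet(
            ids=["x", "y", "z"],
            rows=["ACDEFG", "AVDEFG", "AC-EFG"],
        )
        d = p_distance_matrix(a)
        # retained columns: 0,1,3,4,5 -> x vs y differ at column 1 only
        assert d.loc["x", "y"] == pytest.approx(1 / 5)
        assert d.loc["x", "z"] == pytest.approx(0.0)

    def test_all_columns_gapped_raises(self):
        a = AlignedProteinSet(ids=list("abc"), rows=["A-C-", "-BC-", "AB--"])
        with pytest.raises(ValueError, match="no columns"):
            p_distance_matrix(a)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = nj_tree(d)
        lengths = {c.name: c.branch_length for c in tree.root.clades}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_matrices_reproduced_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(10):
            d = random_additive_tree_distances(rng, n_taxa)
            tree = nj_tree(d)
            for a, b in product(d.index, d.index):
                assert tree.distance(a, b) == pytest.approx(
                    d.loc[a, b], abs=1e-9
                )

    def test_internal_nodes_have_degree_three(self):
        rng = np.random.default_rng(5)
        d = random_additive_tree_distances(rng, 7)
        tree = nj_tree(d)
        assert len(tree.root.clades) == 3
        for clade in tree.get_nonterminals():
            if clade is tree.root:
                continue
            assert len(clade.clades) == 2  # + parent edge = degree 3

    def test_agrees_with_biopython_nj_topology(self):
        """Independent cross-check: Biopython's NJ on the same matrix
        must produce the same unrooted split set."""
        from Bio.Phylo.TreeConstruction import DistanceMatrix as BDM
        from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

        rng = np.random.default_rng(17)
        for rep in range(5):
            d = random_additive_tree_distances(rng, 6)
            names = list(d.index)
            lower = [
                [float(d.iloc[i, j]) for j in range(i + 1)] for i in range(6)
            ]
            btree = DistanceTreeConstructor().nj(BDM(names, lower))
            btree.rooted = False
            assert tree_splits(nj_tree(d)) == tree_splits(btree)

    def test_degenerate_equal_distances_deterministic(self):
        d = pd.DataFrame(
            1.0 - np.eye(4), index=list("abcd"), columns=list("abcd")
        )
        t1, t2 = nj_tree(d), nj_tree(d)
        assert write_newick(t1) == write_newick(t2)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            # noisy (non-additive) distances provoke negative limb estimates
            d = random_additive_tree_distances(rng, 6)
            noise = rng.uniform(0, 0.8, size=d.shape)
            noisy = d + (noise + noise.T) * (1 - np.eye(6))
            tree = nj_tree(pd.DataFrame(noisy, index=d.index, columns=d.columns))
            for clade in tree.find_clades():
                if clade.branch_length is not None:
                    assert clade.branch_length >= 0


@pytest.fixture(scope="module")
def separated_alignment():
    # two 3-taxon clades separated by 200 diagnostic columns
    block_a, block_b = "A" * 200, "C" * 200
    rng = np.random.default_rng(0)
    noise = ["".join(rng.choice(list("DEFG"), size=50)) for _ in range(6)]
    rows = [block_a + n for n in noise[:3]] + [block_b + n for n in noise[3:]]
    return AlignedProteinSet(
        ids=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
        rows=rows,
    )


class TestBootstrap:
    def test_central_split_fully_supported(self, separated_alignment):
        tree = bootstrap_support(separated_alignment, replicates=100, seed=1)
        from prxfam.phylo import split_support

        assert split_support(tree, {"a0", "a1", "a2"}) == pytest.approx(1.0)

    def test_single_replicate_supports_binary(self, separated_alignment):
        tree = bootstrap_support(separated_alignment, replicates=1, seed=3)
        sups = [
            c.confidence
            for c in tree.get_nonterminals()
            if c.confidence is not None
        ]
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_same_seed_reproducible(self, separated_alignment):
        t1 = bootstrap_support(separated_alignment, replicates=25, seed=9)
        t2 = bootstrap_support(separated_alignment, replicates=25, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_under_relabeling(self, separated_alignment):
        relabeled = AlignedProteinSet(
            ids=[f"x_{i}" for i in separated_alignment.ids],
            rows=list(separated_alignment.rows),
        )
        from prxfam.phylo import split_support

        t1 = bootstrap_support(separated_alignment, replicates=50, seed=2)
        t2 = bootstrap_support(relabeled, replicates=50, seed=2)
        s1 = split_support(t1, {"a0", "a1", "a2"})
        s2 = split_support(t2, {"x_a0", "x_a1", "x_a2"})
        assert s1 == s2


class TestSubgroups:
    def test_all_taxa_exemplars_is_identity(self):
        a = AlignedProteinSet(
            ids=list("wxyz"), rows=["MKVA", "MKVC", "MDVA", "MDVC"]
        )
        tree = nj_tree(p_distance_matrix(a))
        exemplars = {t: f"lab_{t}" for t in "wxyz"}
        asg = assign_subgroups(tree, exemplars)
        assert asg.labels == exemplars

    def test_missing_exemplar_raises(self):
        a = AlignedProteinSet(ids=list("abc"), rows=["MK", "MD", "ID"])
        tree = nj_tree(p_distance_matrix(a))
        with pytest.raises(KeyError):
            assign_subgroups(tree, {"nope": "L"})


class TestSimilarity:
    def test_identical_sequences_100(self):
        assert pairwise_similarity("MKVLAW", "MKVLAW") == pytest.approx(100.0)

    def test_toy_matrix_mismatch(self):
        from Bio.Align import substitution_matrices

        toy = substitution_matrices.Array(alphabet="AT", dims=2)
        toy["A", "A"] = toy["T", "T"] = 1
        toy["A", "T"] = toy["T", "A"] = -1
        sim = pairwise_similarity("AAAA", "AAAT", matrix=toy)
        assert sim == pytest.approx(75.0)

    def test_optimal_score_matches_exhaustive_enumeration(self):
        """Brute-force oracle: enumerate every global alignment of two
        short peptides and compare the best score with the aligner's."""
        from Bio.Align import PairwiseAligner, substitution_matrices

        sub = substitution_matrices.load("BLOSUM62")
        gap = -4.0

        def best_score(a, b):
            # exhaustive recursion over all alignment paths
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def rec(i, j):
                if i == len(a) and j == len(b):
                    return 0.0
                options = []
                if i < len(a) and j < len(b):
                    options.append(float(sub[a[i], b[j]]) + rec(i + 1, j + 1))
                if i < len(a):
                    options.append(gap + rec(i + 1, j))
                if j < len(b):
                    options.append(gap + rec(i, j + 1))
                return max(options)

            return rec(0, 0)

        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = sub
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=int(rng.integers(3, 8))))
            b = "".join(rng.choice(aas, size=int(rng.integers(3, 8))))
            assert aligner.score(a, b) == pytest.approx(best_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "MKV")


class TestNewick:
    def test_round_trip_idempotent(self):
        rng = np.random.default_rng(8)
        d = random_additive_tree_distances(rng, 6)
        tree = nj_tree(d)
        once = write_newick(tree)
        again = write_newick(read_newick(once))
        assert once == again
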