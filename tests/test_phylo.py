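"""Pairwise-deletion distances, neighbor joining, bootstrap, Newick."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import bisect

from conftest import additive_matrix_from_random_tree

from bsptools.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloError,
    annotate_supports,
    bipartitions,
    bootstrap,
    dayhoff_model,
    distance_matrix,
    nj_tree,
    pairwise_distance,
    read_newick,
    write_newick,
)


class TestPairwiseDistance:
    @pytest.mark.parametrize("model", ["p", "poisson", "dayhoff"])
    def test_identical_rows_are_zero(self, model):
        d, n = pairwise_distance("ACDEFGHIKL", "ACDEFGHIKL", model)
        assert d == 0.0 and n == 10

    def test_p_distance_definition(self):
        d, n = pairwise_distance("AADEFGHIKL", "ACDEFGHIKW", "p")
        assert (d, n) == (0.2, 10)

    def test_pairwise_deletion_excludes_gapped_columns(self):
        d, n = pairwise_distance("A-CDEFGHIK", "AAC-EFGHIW", "p")
        assert n == 8 and d == pytest.approx(1 / 8)

    def test_no_comparable_columns_is_undefined(self):
        d, n = pairwise_distance("--AA", "AA--", "p")
        assert math.isnan(d) and n == 0

    def test_dayhoff_against_dense_matrix_exponential_oracle(self):
        """The spectral inversion must agree with a brute-force root find
        on the dense matrix exponential of the same generator."""
        m = dayhoff_model()
        for p in (0.05, 0.2, 0.5, 0.7):
            def identity_gap(t):
                return float(np.sum(m.pi * np.diag(expm(m.Q * t)))) - (1.0 - p)

            oracle = bisect(identity_gap, 0.0, 50.0, xtol=1e-10)
            assert m.distance(p) == pytest.approx(oracle, abs=1e-6)

    def test_model_ordering_dayhoff_ge_poisson_ge_p(self):
        m = dayhoff_model()
        for p in np.linspace(0.01, 0.69, 20):
            poisson = -math.log(1 - p)
            day = m.distance(float(p))
            assert day >= poisson >= p
            assert day <= 2 * poisson  # sane correction magnitude

    def test_saturation_flag(self):
        m = dayhoff_model()
        assert math.isinf(m.distance(0.97))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d, np.full((3, 3), 10)))
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives this additive matrix
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d, np.full((4, 4), 14)))
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_all_equal_distances_give_valid_tree(self):
        d = np.ones((5, 5)) - np.eye(5)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(5)], d, np.full((5, 5), 9)))
        assert sorted(tree.leaf_names) == [f"t{i}" for i in range(5)]
        for node in tree.root.traverse(include_self=False):
            assert node.length >= 0

    def test_fewer_than_three_taxa_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["A", "B"], d, np.zeros((2, 2), int)))

    @pytest.mark.parametrize("seed", range(12))
    def test_recovers_topology_on_additive_matrices(self, seed):
        """NJ is consistent: exact additive input -> generating topology."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d, truth = additive_matrix_from_random_tree(n, rng)
        ids = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(ids, d, np.full((n, n), 100)))
        assert bipartitions(tree) == truth

    def test_agrees_with_scikit_bio_on_additive_input(self):
        """Independent oracle: scikit-bio's own NJ on the same matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(99)
        d, truth = additive_matrix_from_random_tree(8, rng)
        ids = [f"t{i}" for i in range(8)]
        ours = bipartitions(nj_tree(DistanceMatrix(ids, d, np.full((8, 8), 50))))
        theirs_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        all_leaves = frozenset(ids)
        theirs = set()
        for node in theirs_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if "t0" in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(ids) - 2:
                theirs.add(side)
        assert ours == theirs == truth


@pytest.fixture(scope="module")
def clade_alignment():
    return Alignment(
        ["a1", "a2", "b1", "b2"],
        [
            "AAAAAAAAAAAAAAAACCCC",
            "AAAAAAAAAAAAAAAACCCA",
            "TTTTTTTTTTTTTTTTCCCC",
            "TTTTTTTTTTTTTTTTCCCG",
        ],
    )


class TestBootstrap:
    def test_clean_split_gets_full_support(self, clade_alignment):
        supports = bootstrap(clade_alignment, "p", replicates=100, seed=3)
        assert supports[frozenset({"b1", "b2"})] == 100.0

    def test_single_replicate_supports_are_binary(self, clade_alignment):
        supports = bootstrap(clade_alignment, "p", replicates=1, seed=8)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces(self, clade_alignment):
        a = bootstrap(clade_alignment, "p", replicates=40, seed=13)
        b = bootstrap(clade_alignment, "p", replicates=40, seed=13)
        assert a == b


class TestNewick:
    def test_three_leaf_form(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d, np.full((3, 3), 5)))
        assert write_newick(tree) == "(A:1,B:1,C:1);\n"

    def test_supports_appear_as_internal_labels(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), d, np.full((4, 4), 14)))
        annotate_supports(tree, {frozenset({"C", "D"}): 87.0})
        assert ")87:" in write_newick(tree)

    def test_metacharacter_labels_are_quoted(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(["A B", "C(1)", "D"], d, np.full((3, 3), 5)))
        text = write_newick(tree)
        assert "'A B'" in text and "'C(1)'" in text

    def test_write_read_write_is_byte_stable(self):
        rng = np.random.default_rng(4)
        d, _ = additive_matrix_from_random_tree(7, rng)
        ids = [f"t{i}" for i in range(7)]
        tree = nj_tree(DistanceMatrix(ids, d, np.full((7, 7), 30)))
        tree.supports = {next(iter(bipartitions(tree))): 91.0}
        once = write_newick(tree)
        twice = write_newick(read_newick(once))
        assert once == twice


def test_distance_matrix_is_symmetric_with_zero_diagonal(small_panel):
    recs, _ = small_panel
    from bsptools.architecture import assemble
    from bsptools.blocks import scan_blocks

    cores = []
    for sid, seq in recs[:6]:
        arch = assemble(scan_blocks(seq, 1), seq, seq_id=sid)
        cores.append((sid, seq[arch.fn2_1_span[0] - 1 : arch.fn2_2_span[1]]))
    aln = Alignment([c[0] for c in cores], [c[1] for c in cores])
    dm = distance_matrix(aln, "dayhoff")
    assert np.allclose(dm.d, dm.d.T)
    assert np.all(np.diag(dm.d) == 0)
    assert dm.well_defined
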