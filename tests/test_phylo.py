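"""Alignment (vs. a brute-force affine-gap DP oracle), p-distances,
neighbor joining (closed forms and additive-matrix recovery), bootstrap and
FReD-based paralog assignment."""
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tenascope import phylo
from tenascope.records import (
    AnnotationMethod,
    Architecture,
    DomainAnnotation,
    DomainKind,
)
from tenascope.synthetic_data import (
    GeneratorConfig,
    evolve_family,
    make_tenascin,
    reference_freds,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")
NEG = -10**9


def gotoh_oracle_score(a: str, b: str, gap_open=11, gap_extend=1) -> float:
    """Independent quadratic-space affine-gap DP (gap of length k costs
    gap_open + gap_extend*k, end gaps penalized)."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first gapped position
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue over gap)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first)
    return float(max(M[n][m], X[n][m], Y[n][m]))


def rand_seq(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, n))


class TestGlobalAlign:
    def test_identical_sequences_100_identity(self, rng):
        s = rand_seq(rng, 50)
        res = phylo.global_align(s, s)
        assert res.percent_identity == pytest.approx(100.0)

    def test_hand_computed_single_mismatch(self):
        res = phylo.global_align("ACDEFG", "ACDEFH")
        assert res.percent_identity == pytest.approx(100 * 5 / 6)
        assert (res.aligned_a, res.aligned_b) == ("ACDEFG", "ACDEFH")

    def test_score_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = rand_seq(rng, int(rng.integers(1, 61)))
            b = rand_seq(rng, int(rng.integers(1, 61)))
            res = phylo.global_align(a, b)
            assert res.score == pytest.approx(gotoh_oracle_score(a, b))
            # returned alignment is internally consistent
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b
            ident = sum(1 for p, q in zip(res.aligned_a, res.aligned_b)
                        if p == q and p != "-")
            assert res.percent_identity == pytest.approx(
                100 * ident / len(res.aligned_a))

    def test_identity_symmetric(self, rng):
        for _ in range(20):
            a, b = rand_seq(rng, 40), rand_seq(rng, 35)
            assert phylo.global_align(a, b).percent_identity == \
                pytest.approx(phylo.global_align(b, a).percent_identity)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            phylo.global_align("", "ACD")


class TestExtractFred:
    def _arch(self, n, fred_span):
        doms = [DomainAnnotation(protein_id="p", kind=DomainKind.FRED,
                                 start=fred_span[0], end=fred_span[1],
                                 method=AnnotationMethod.EXTERNAL)]
        arch = Architecture(protein_id="p", seq_length=n, domains=doms)
        arch.has_terminal_fred = n - fred_span[1] <= 30
        return arch

    def test_planted_interval_extracted(self):
        seq = "A" * 499 + "W" * 221 + "GS"
        assert phylo.extract_fred(self._arch(722, (500, 720)), seq) == "W" * 221

    def test_without_terminal_fred_errors(self):
        with pytest.raises(ValueError):
            phylo.extract_fred(self._arch(900, (100, 330)), "A" * 900)


class TestPDistance:
    def test_identical_zero_and_hand_value(self):
        dm = phylo.p_distance_matrix([("a", "AAAA"), ("b", "AAAT"),
                                      ("c", "AAAA")])
        assert dm.value("a", "c") == 0.0
        assert dm.value("a", "b") == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        dm = phylo.p_distance_matrix([("a", "A-CT"), ("b", "AGCT"),
                                      ("c", "AGGT")])
        assert dm.value("a", "b") == 0.0          # 3 comparable, 0 mismatches
        assert dm.value("a", "c") == pytest.approx(1 / 3)

    def test_zero_comparable_columns_error(self):
        with pytest.raises(ValueError, match="comparable"):
            phylo.p_distance_matrix([("a", "A-"), ("b", "-A"), ("c", "AA")])

    def test_random_matrix_symmetric_zero_diagonal(self, rng):
        seqs = [(f"s{i}", rand_seq(rng, 30)) for i in range(6)]
        dm = phylo.p_distance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T) and np.allclose(np.diag(dm.d), 0)


def random_additive_tree(rng, n_leaves):
    """Random binary rooted tree (newick) with branch lengths in [0.1, 1]."""
    def build(labels):
        if len(labels) == 1:
            return labels[0]
        k = int(rng.integers(1, len(labels)))
        l = build(labels[:k])
        r = build(labels[k:])
        return f"({l}:{0.1 + 0.9 * rng.random():.6f},{r}:{0.1 + 0.9 * rng.random():.6f})"
    labels = [f"t{i}" for i in range(n_leaves)]
    order = rng.permutation(n_leaves)
    return build([labels[i] for i in order]) + ";"


def tree_distances(newick):
    tree = phylo.PhyloTree.from_newick(newick)
    import dendropy
    pdm = tree._tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree._tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    taxa = {t.label: t for t in tree._tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return tree, phylo.DistanceMatrix(labels=labels, d=d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = phylo.neighbor_joining(
            phylo.DistanceMatrix(labels=["A", "B", "C"], d=d))
        lengths = tree.edge_lengths()
        assert lengths[frozenset({"A"})] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths[frozenset({"B"})] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths[frozenset({"C"})] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_recovery(self):
        # tree: (A,B)|(C,D) with internal edge 1.0
        newick = "((A:1.0,B:2.0):1.0,(C:1.5,D:0.5):0.0);"
        true_tree, dm = tree_distances(newick)
        nj = phylo.neighbor_joining(dm)
        assert nj.bipartitions() == {frozenset({"A", "B"})}
        got = nj.edge_lengths()
        for key, val in true_tree.edge_lengths().items():
            assert got[key] == pytest.approx(val, abs=1e-9)

    def test_additive_random_trees_recovered(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            newick = random_additive_tree(rng, n)
            true_tree, dm = tree_distances(newick)
            nj = phylo.neighbor_joining(dm)
            assert nj.bipartitions() == true_tree.bipartitions()
            got = nj.edge_lengths()
            for key, val in true_tree.edge_lengths().items():
                assert got[key] == pytest.approx(val, abs=1e-8)

    def test_all_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        labels = ["a", "b", "c", "d", "e"]
        t1 = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, d=d))
        t2 = phylo.neighbor_joining(phylo.DistanceMatrix(labels=labels, d=d))
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_three_labels_error(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(
                phylo.DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2))))

    def test_agrees_with_skbio_on_additive_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix as SkDM
        newick = random_additive_tree(rng, 7)
        _, dm = tree_distances(newick)
        ours = phylo.neighbor_joining(dm).bipartitions()
        sk_tree = skbio_nj(SkDM(dm.d, ids=dm.labels))
        sk = phylo.PhyloTree.from_newick(str(sk_tree)).bipartitions()
        assert ours == sk


class TestBootstrap:
    def test_fixed_seed_bit_reproducible(self, rng):
        seqs = [(f"s{i}", rand_seq(rng, 60)) for i in range(5)]
        t1 = phylo.bootstrap_support(seqs, n_reps=25, seed=7)
        t2 = phylo.bootstrap_support(seqs, n_reps=25, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_identical_columns_give_full_support(self):
        # every column identical -> every replicate equals the original
        seqs = [("a", "AAAA"), ("b", "CCCC"), ("c", "GGGG"), ("d", "TTTT"),
                ("e", "WWWW")]
        tree = phylo.bootstrap_support(seqs, n_reps=1, seed=0)
        assert set(tree.supports().values()) == {100.0}

    def test_supports_within_range(self, rng):
        seqs = [(f"s{i}", rand_seq(rng, 40)) for i in range(6)]
        tree = phylo.bootstrap_support(seqs, n_reps=20, seed=3)
        assert all(0.0 <= v <= 100.0 for v in tree.supports().values())

    def test_deep_split_high_support(self, rng):
        newick = ("((A:0.1,(B:0.1,C:0.1):0.1):0.6,"
                  "(D:0.1,(E:0.1,F:0.1):0.1):0.6);")
        leaves = evolve_family(rand_seq(rng, 400), newick, 1.0, rng)
        tree = phylo.bootstrap_support(sorted(leaves.items()), n_reps=100, seed=5)
        deep = frozenset({"A", "B", "C"})
        assert tree.supports()[deep] >= 90.0


class TestParalogAssignment:
    def test_identical_query_wins_with_margin(self):
        refs = reference_freds()
        tnr = next(seq for lab, _, seq in refs if lab == "TNR")
        label, margin = phylo.assign_paralog_by_fred(tnr, refs)
        assert label == "TNR" and margin > 0

    def test_equidistant_query_unclassified(self):
        refs = [("L1", "r1", "AAAAAAAAAA"), ("L2", "r2", "AAAAAAAAAA")]
        label, margin = phylo.assign_paralog_by_fred("AAAAAAAAAA", refs)
        assert label == "UNCLASSIFIED" and margin == pytest.approx(0.0)

    def test_low_identity_unclassified(self, rng):
        refs = reference_freds()
        label, _ = phylo.assign_paralog_by_fred(rand_seq(rng, 230), refs)
        assert label == "UNCLASSIFIED"

    def test_evolved_tnc_clade_assignment(self, rng):
        """FReDs at 20% substitution from the TNC template are assigned TNC."""
        cfg = GeneratorConfig(seed=1, substitution_rate=0.2)
        refs = reference_freds()
        correct = 0
        for i in range(20):
            rec, truth = make_tenascin(cfg, "TNC", rng, species=f"s{i}")
            fred_dom = [d for d in truth["domains"]
                        if d.kind == DomainKind.FRED][0]
            fred = rec.seq[fred_dom.start - 1:fred_dom.end]
            label, _ = phylo.assign_paralog_by_fred(fred, refs)
            correct += label == "TNC"
        assert correct >= 19  # >= 95%
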