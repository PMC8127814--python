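import itertools
import math

import numpy as np
import pytest

from cneloss.formats import read_gff3, read_maf
from cneloss.phylo import (BASES, FOURFOLD_PREFIXES, PhyloTree, SiteColumnSet,
                           SubstitutionModel, column_log_likelihood,
                           column_log_likelihoods, distance_to_outgroup,
                           extract_4d_columns, fit_neutral_model,
                           relative_rate_test, total_log_likelihood)


def brute_force_column_ll(tree, model, leaf_states):
    """Independent oracle: sum over all internal-state assignments."""
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        states = dict(zip((id(n) for n in internal), assign))
        for leaf in tree.leaves():
            states[id(leaf)] = leaf_states[leaf.name]
        prob = model.pi[states[id(tree.root)]]
        for node in nodes:
            if node.parent is None:
                continue
            obs = states[id(node)]
            if obs is None:  # missing leaf: marginalize
                continue
            P = model.transition_matrix(node.length)
            prob *= P[states[id(node.parent)], obs]
        total += prob
    return math.log(total)


class TestSubstitutionModel:
    def test_rows_sum_to_zero(self, gtr_model):
        assert np.allclose(gtr_model.Q.sum(axis=1), 0.0, atol=1e-12)

    def test_rate_normalization(self, gtr_model):
        assert np.isclose(-(gtr_model.pi * np.diag(gtr_model.Q)).sum(), 1.0)

    def test_detailed_balance(self, gtr_model):
        Q, pi = gtr_model.Q, gtr_model.pi
        for i in range(4):
            for j in range(4):
                assert pi[i] * Q[i, j] == pytest.approx(pi[j] * Q[j, i])

    def test_identity_at_zero(self, gtr_model):
        assert np.allclose(gtr_model.transition_matrix(0.0), np.eye(4),
                           atol=1e-12)

    @pytest.mark.parametrize("s,t", [(0.1, 0.2), (0.5, 1.0), (0.01, 2.0)])
    def test_chapman_kolmogorov(self, gtr_model, s, t):
        P = gtr_model.transition_matrix
        assert np.allclose(P(s) @ P(t), P(s + t), atol=1e-10)

    def test_rows_stochastic(self, gtr_model):
        for t in (0.01, 0.3, 5.0):
            assert np.allclose(gtr_model.transition_matrix(t).sum(axis=1),
                               1.0, atol=1e-10)

    def test_jc_closed_form(self, jc_model):
        for t in (0.01, 0.1, 0.5, 1.0, 2.0):
            P = jc_model.transition_matrix(t)
            expected = 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)
            assert P[0, 0] == pytest.approx(expected, abs=1e-10)


class TestColumnLikelihood:
    def test_single_leaf(self, jc_model):
        tree = PhyloTree.from_newick("(A:0.0);")
        ll = column_log_likelihood(tree, jc_model, "A", ["A"])
        # root partials propagate through zero-length branch
        assert ll == pytest.approx(math.log(0.25), abs=1e-10)

    def test_two_leaf_jc_closed_form(self, jc_model):
        # P(same pair) = 1/4 * (1/4 + 3/4 exp(-4t/3)), t = branch sum
        for t1, t2 in [(0.1, 0.2), (0.4, 0.6), (1.0, 1.0)]:
            tree = PhyloTree.from_newick(f"(A:{t1},B:{t2});")
            ll = column_log_likelihood(tree, jc_model, "AA", ["A", "B"])
            t = t1 + t2
            expected = 0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3))
            assert ll == pytest.approx(math.log(expected), abs=1e-10)

    def test_missing_data_is_flat(self, gtr_model):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        # all-missing column integrates to 1
        ll = column_log_likelihood(tree, gtr_model, "NN", ["A", "B"])
        assert ll == pytest.approx(0.0, abs=1e-10)

    def test_four_leaf_enumeration_oracle(self, gtr_model):
        tree = PhyloTree.from_newick(
            "((A:0.12,B:0.34):0.05,(C:0.21,D:0.08):0.09);")
        for column in ("ACGT", "AAAA", "AGAG"):
            states = {n: BASES.index(c)
                      for n, c in zip("ABCD", column)}
            expected = brute_force_column_ll(tree, gtr_model, states)
            got = column_log_likelihood(tree, gtr_model, column, list("ABCD"))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_unknown_leaf_error(self, gtr_model):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        with pytest.raises(KeyError):
            column_log_likelihood(tree, gtr_model, "AC", ["A", "X"])

    def test_reroot_invariance(self, gtr_model):
        # reversibility: likelihood identical for different rootings of the
        # same unrooted tree
        t1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        t2 = PhyloTree.from_newick("((A:0.1,B:0.2):0.0,C:0.35);")
        for col in ("AAC", "ACG", "CCC"):
            l1 = column_log_likelihood(t1, gtr_model, col, list("ABC"))
            l2 = column_log_likelihood(t2, gtr_model, col, list("ABC"))
            assert l1 == pytest.approx(l2, abs=1e-10)


class TestDistances:
    def test_toy_path_sums(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,O:0.3);")
        d = distance_to_outgroup(tree, "O")
        assert d == {"A": pytest.approx(0.45), "B": pytest.approx(0.55)}

    def test_cophenetic_symmetric(self, six_taxon_tree):
        names, mat = six_taxon_tree.cophenetic_matrix()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_random_tree_matches_path_oracle(self):
        rng = np.random.default_rng(11)

        def rand_newick(names):
            if len(names) == 1:
                return f"{names[0]}:{rng.uniform(0.01, 0.5):.4f}"
            k = rng.integers(1, len(names))
            left, right = names[:k], names[k:]
            return (f"({rand_newick(left)},{rand_newick(right)})"
                    f":{rng.uniform(0.01, 0.5):.4f}")

        names = [f"L{i}" for i in range(8)]
        tree = PhyloTree.from_newick(f"({rand_newick(names[:4])},"
                                     f"{rand_newick(names[4:])});")

        # oracle: distance via explicit root paths
        def path(leafname):
            node = next(n for n in tree.leaves() if n.name == leafname)
            out = []
            while node is not None:
                out.append(node)
                node = node.parent
            return out

        for a in names:
            for b in names:
                if a >= b:
                    continue
                pa, pb = path(a), path(b)
                shared = {id(n) for n in pa} & {id(n) for n in pb}
                expect = sum(n.length for n in pa if id(n) not in shared) + \
                    sum(n.length for n in pb if id(n) not in shared)
                assert tree.leaf_distance(a, b) == pytest.approx(expect)

    def test_unknown_leaf(self, six_taxon_tree):
        with pytest.raises(KeyError):
            distance_to_outgroup(six_taxon_tree, "nope")


class TestExtract4D:
    def test_fourfold_families(self):
        # Ala (GC*) is fourfold; Met (ATG) is not
        assert "GC" in FOURFOLD_PREFIXES
        assert "AT" not in FOURFOLD_PREFIXES
        assert len(FOURFOLD_PREFIXES) == 8

    def test_simple_gene(self, tmp_path):
        # reference codons: ATG GCA CGT TAA -> one 4D codon (GCA) plus CGT
        maf = tmp_path / "a.maf"
        maf.write_text(
            "a score=0\n"
            "s ref.chr1 0 12 + 12 ATGGCACGTTAA\n"
            "s sp2.c 0 12 + 12 ATGGCGCGATAA\n\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "chr1\tx\tgene\t1\t12\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t12\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\tx\tCDS\t1\t12\t.\t+\t0\tID=c1;Parent=m1\n")
        cols = extract_4d_columns(read_maf(maf), read_gff3(gff),
                                  ["ref", "sp2"], "ref")
        # GCA (Ala, 4D) and CGT (Arg, 4D) -> third-position columns AG, TA
        got = {"".join(BASES[c] if c < 4 else "N" for c in row)
               for row in cols.codes}
        assert got == {"AG", "TA"}

    def test_minus_strand_gene_matches_hand_walk(self, tmp_path):
        # forward genome: TTAACGTGCCAT = revcomp(ATGGCACGTTAA)
        # so the minus-strand gene has codons ATG GCA CGT TAA
        maf = tmp_path / "a.maf"
        maf.write_text(
            "a score=0\n"
            "s ref.chr1 0 12 + 12 TTAACGTGCCAT\n"
            "s sp2.c 0 12 + 12 TTATCGCGCCAT\n\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "chr1\tx\tgene\t1\t12\t.\t-\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t12\t.\t-\t.\tID=m1;Parent=g1\n"
            "chr1\tx\tCDS\t1\t12\t.\t-\t0\tID=c1;Parent=m1\n")
        cols = extract_4d_columns(read_maf(maf), read_gff3(gff),
                                  ["ref", "sp2"], "ref")
        # hand walk: coding positions 11..0; 4D codons GCA (third base at
        # genome offset 5) and CGT (third base at genome offset 2);
        # emitted columns are the forward-strand alignment columns there.
        got = {"".join(BASES[c] if c < 4 else "N" for c in row)
               for row in cols.codes}
        assert got == {"TC", "AT"}

    def test_met_codon_excluded(self, tmp_path):
        maf = tmp_path / "a.maf"
        maf.write_text("a score=0\ns ref.chr1 0 6 + 6 ATGTAA\n\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "chr1\tx\tgene\t1\t6\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t1\t6\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\tx\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=m1\n")
        cols = extract_4d_columns(read_maf(maf), read_gff3(gff), ["ref"],
                                  "ref")
        assert len(cols) == 0


class TestFitNeutralModel:
    def test_identical_columns_hit_lower_bound(self, six_taxon_tree):
        cols = SiteColumnSet.from_strings(
            six_taxon_tree.leaf_names(), ["AAAAAA"] * 200)
        fit = fit_neutral_model(cols, six_taxon_tree)
        for node in fit.tree.branches():
            assert node.length <= 1e-6 + 1e-12

    def test_ml_beats_generating_parameters(self, six_taxon_tree, gtr_model,
                                            small_result):
        from cneloss.phylo import extract_4d_columns
        cols = extract_4d_columns(
            small_result.blocks, small_result.annotations,
            six_taxon_tree.leaf_names(), "Zv9")
        fit = fit_neutral_model(cols, six_taxon_tree)
        at_truth = total_log_likelihood(six_taxon_tree, gtr_model,
                                        cols.collapsed())
        assert fit.log_likelihood >= at_truth - 1e-6

    def test_no_columns_error(self, six_taxon_tree):
        cols = SiteColumnSet.from_strings(six_taxon_tree.leaf_names(),
                                          ["NNNNNN"] * 5)
        with pytest.raises(ValueError):
            fit_neutral_model(cols, six_taxon_tree)


class TestRelativeRateTest:
    def test_equal_counts(self):
        a = "A" * 10 + "C" * 10 + "G" * 40
        b = "A" * 10 + "G" * 10 + "C" * 10 + "G" * 30
        o = "A" * 10 + "G" * 50
        r = relative_rate_test(a, b, o)
        assert r.m1 == r.m2 == 10
        assert r.chi2 == 0.0
        assert r.p_value == 1.0

    def test_worked_example(self):
        # m1=15, m2=5 -> chi2 = (15-5)^2/20 = 5.0, p ~ 0.02535
        a = "C" * 15 + "A" * 5 + "A" * 40
        b = "A" * 15 + "C" * 5 + "A" * 40
        o = "A" * 60
        r = relative_rate_test(a, b, o)
        assert (r.m1, r.m2) == (15, 5)
        assert r.chi2 == pytest.approx(5.0)
        assert r.p_value == pytest.approx(0.025347, abs=1e-5)

    def test_hand_counted_fixture(self):
        seq_a = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        seq_b = "ACGAACGTACCTACGTAGGTACGTACGTTCGTACGTACGAACGTACGTACGTACGGACGT"
        seq_o = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACTTACGTACGTACGT"
        m1 = sum(1 for a, b, o in zip(seq_a, seq_b, seq_o)
                 if a != o and b == o)
        m2 = sum(1 for a, b, o in zip(seq_a, seq_b, seq_o)
                 if b != o and a == o)
        r = relative_rate_test(seq_a, seq_b, seq_o)
        assert (r.m1, r.m2) == (m1, m2) == (0, 6)

    def test_ambiguous_columns_excluded(self):
        r = relative_rate_test("ANC", "AAC", "AAT")
        assert r.n_excluded == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            relative_rate_test("AC", "ACG", "ACG")


class TestTreeIO:
    def test_newick_round_trip(self, six_taxon_tree, tmp_path):
        six_taxon_tree.write(tmp_path / "t.nwk")
        back = PhyloTree.read(tmp_path / "t.nwk")
        assert back.to_newick() == six_taxon_tree.to_newick()
        assert back.leaf_names() == six_taxon_tree.leaf_names()

    def test_scaled(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.4):0.1,O:0.3);")
        half = tree.scaled(0.5)
        assert half.leaf_distance("A", "O") == pytest.approx(0.3)
        assert half.total_length() == pytest.approx(tree.total_length() / 2)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("(A:-0.1,B:0.2);")
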