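import itertools

import numpy as np
import pytest

import barcode_eval as be
from barcode_eval.distances import AlignmentError, AlignmentParams

from conftest import library_from_specs, random_seq


def gotoh_score(a, b, match=1.0, mismatch=-1.0, open_=-2.0, extend=-0.5, free_ends=True):
    """Independent affine-gap global alignment score (Gotoh DP).

    Gap of length L costs open_ + (L-1)*extend; terminal gaps free when
    free_ends.  Used as an oracle on short sequences only.
    """
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_ends else open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_ends else open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend, X[i, j - 1] + open_)
    if not free_ends:
        return max(M[n, m], X[n, m], Y[n, m])
    # free terminal gaps: best over last row/column, remainder unpenalised
    best = max(M[n, m], X[n, m], Y[n, m])
    for i in range(n + 1):
        best = max(best, M[i, m], X[i, m], Y[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], X[n, j], Y[n, j])
    return best


class TestPairwiseAlign:
    def test_identity(self):
        aln = be.pairwise_align("ACGT", "ACGT")
        assert aln.aligned_a == aln.aligned_b == "ACGT"
        assert aln.score == 4.0

    def test_terminal_gap(self):
        aln = be.pairwise_align("ACGT", "ACG")
        assert aln.aligned_a == "ACGT"
        assert aln.aligned_b == "ACG-"

    def test_degap_recovers_inputs(self, rng):
        a, b = random_seq(rng, 40), random_seq(rng, 35)
        aln = be.pairwise_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_empty_sequence_raises(self):
        with pytest.raises(AlignmentError):
            be.pairwise_align("", "ACGT")

    def test_score_matches_dp_oracle_on_stated_instance(self):
        score = be.pairwise_align("AACCGG", "AAGG").score
        assert score == pytest.approx(gotoh_score("AACCGG", "AAGG"))

    def test_score_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            a = random_seq(rng, int(rng.integers(1, 13)))
            b = random_seq(rng, int(rng.integers(1, 13)))
            assert be.pairwise_align(a, b).score == pytest.approx(
                gotoh_score(a, b)
            ), (a, b)

    def test_custom_scoring_parameters(self, rng):
        params = AlignmentParams(match=2.0, mismatch=-3.0, gap_open=-4.0, gap_extend=-1.0)
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(2, 11)))
            b = random_seq(rng, int(rng.integers(2, 11)))
            got = be.pairwise_align(a, b, params).score
            assert got == pytest.approx(
                gotoh_score(a, b, match=2.0, mismatch=-3.0, open_=-4.0, extend=-1.0)
            ), (a, b)


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGA", 0.25),
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGN", 0.0),  # ambiguity never counts as a difference
            ("AC-T", "ACGT", 0.0),  # gap column counts only in the denominator
            ("AAAA", "TTTT", 1.0),
        ],
    )
    def test_definition_cases(self, a, b, expected):
        aln = be.PairwiseAlignment(aligned_a=a, aligned_b=b, score=0.0)
        assert be.p_distance(aln) == pytest.approx(expected)

    def test_gap_columns_enlarge_denominator(self):
        aln = be.PairwiseAlignment("ACGTT", "AC-TA", 0.0)
        assert be.p_distance(aln) == pytest.approx(1 / 5)

    def test_pseudo_metric_on_equal_length_sequences(self, rng):
        # symmetry, identity, triangle inequality for similar gap-free
        # same-length sequences (the barcode regime: alignments are identity)
        base = random_seq(rng, 60)
        seqs = []
        for _ in range(5):
            s = list(base)
            for pos in rng.choice(range(5, 55), size=4, replace=False):
                s[pos] = "ACGT"[int(rng.integers(4))]
            seqs.append("".join(s))
        al = be.Aligner()
        d = {(i, j): al.p_distance(seqs[i], seqs[j]) for i in range(5) for j in range(5)}
        for i, j, k in itertools.permutations(range(5), 3):
            assert d[i, j] == pytest.approx(d[j, i])
            assert d[i, i] == 0.0
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        lib = library_from_specs(
            [(f"s{i}", "Genus alpha", {"m1": "ACGT" * 10}) for i in range(3)]
        )
        dm = be.distance_matrix(lib, "m1")
        assert np.allclose(dm.matrix, 0.0)

    def test_single_substitution_distance(self):
        a = "A" * 50 + "C" + "G" * 49
        b = "A" * 50 + "T" + "G" * 49
        lib = library_from_specs(
            [("s1", "Genus alpha", {"m1": a}), ("s2", "Genus beta", {"m1": b})]
        )
        dm = be.distance_matrix(lib, "m1")
        assert dm.matrix[0, 1] == pytest.approx(0.01)

    def test_matches_hamming_oracle_on_indel_free_library(self, rng):
        # equal-length gap-free sequences: p-distance must equal Hamming/L
        L = 80
        base = random_seq(rng, L)
        seqs = {}
        for i in range(6):
            s = list(base)
            for pos in rng.choice(L, size=rng.integers(0, 5), replace=False):
                s[pos] = "ACGT"[int(rng.integers(4))]
            seqs[f"s{i}"] = "".join(s)
        lib = library_from_specs(
            [(sid, f"Genus sp{i}", {"m1": seq}) for i, (sid, seq) in enumerate(seqs.items())]
        )
        dm = be.distance_matrix(lib, "m1")
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                hamming = sum(x != y for x, y in zip(seqs[a], seqs[b])) / L
                assert dm.matrix[i, j] == pytest.approx(hamming)

    def test_symmetry_zero_diagonal(self, two_marker_library):
        dm = be.distance_matrix(two_marker_library, "m1")
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)

    def test_missing_marker_raises(self):
        lib = library_from_specs(
            [("s1", "Genus alpha", {"m1": "ACGT", "m2": "ACGT"}),
             ("s2", "Genus beta", {"m2": "ACGT"})]
        )
        with pytest.raises(AlignmentError, match="s2"):
            be.distance_matrix(lib, "m1")


class TestMultilocusDistance:
    def test_pooled_counts(self):
        # per-marker (diffs/cols): 1/100, 0/100, 1/100 -> pooled 2/300
        # (the substitution sits mid-sequence so free end gaps cannot absorb it)
        base = "A" * 50 + "C" + "A" * 49
        one_diff = "A" * 50 + "G" + "A" * 49
        lib = library_from_specs(
            [
                ("s1", "Genus alpha", {"m1": base, "m2": base, "m3": base}),
                ("s2", "Genus beta", {"m1": one_diff, "m2": base, "m3": one_diff}),
            ]
        )
        d = be.multilocus_distance(lib, ["m1", "m2", "m3"], "s1", "s2")
        assert d == pytest.approx(2 / 300)

    def test_equals_single_marker_distance_for_one_marker(self, two_marker_library):
        lib = two_marker_library
        d_multi = be.multilocus_distance(lib, ["m1"], "s1", "s3")
        dm = be.distance_matrix(lib, "m1")
        assert d_multi == pytest.approx(dm.value("s1", "s3"))

    def test_identical_at_all_markers(self, two_marker_library):
        assert be.multilocus_distance(two_marker_library, ["m1", "m2"], "s1", "s2") == 0.0

    def test_missing_marker_names_specimen(self):
        lib = library_from_specs(
            [("s1", "Genus alpha", {"m1": "ACGT", "m2": "ACGT"}),
             ("s2", "Genus beta", {"m1": "ACGT"})]
        )
        with pytest.raises(AlignmentError, match="s2.*m2"):
            be.multilocus_distance(lib, ["m1", "m2"], "s1", "s2")


class TestSimpleIndelCoding:
    def test_shared_gap_becomes_one_character(self):
        msa = {
            "s1": "ACG---TACGT",
            "s2": "ACG---TACGT",
            "s3": "ACGTTTTACGT",
            "s4": "ACGCCCTACGT",
        }
        m = be.simple_indel_coding(msa)
        assert m.events == ((4, 7),)
        assert m.states == ["1", "1", "0", "0"]

    def test_gapless_alignment_has_no_characters(self):
        m = be.simple_indel_coding({"s1": "ACGT", "s2": "ACGT"})
        assert m.events == ()

    def test_nested_gap_scored_inapplicable(self):
        msa = {
            "s1": "AC--TTTTGT",   # span (3,5)
            "s2": "AC------GT",   # span (3,9) strictly contains (3,5)
            "s3": "ACGGTTTTGT",
        }
        m = be.simple_indel_coding(msa)
        assert m.events == ((3, 5), (3, 9))
        states = dict(zip(m.ids, m.states))
        assert states["s1"] == "10"
        assert states["s2"] == "-1"
        assert states["s3"] == "00"

    def test_terminal_gaps_are_missing_not_characters(self):
        msa = {
            "s1": "----AC",      # leading gap: missing, not an event
            "s2": "AC--AC",      # internal event (3,5)
            "s3": "ACGTAC",
        }
        m = be.simple_indel_coding(msa)
        assert m.events == ((3, 5),)
        states = dict(zip(m.ids, m.states))
        assert states["s2"] == "1"
        assert states["s3"] == "0"
        assert states["s1"] == "-"  # span under the terminal missing region

    def test_ragged_alignment_raises(self):
        with pytest.raises(AlignmentError, match="ragged"):
            be.simple_indel_coding({"s1": "ACGT", "s2": "ACG"})


class TestNJTree:
    @staticmethod
    def splits(tree):
        out = set()
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.is_internal():
                out.add(frozenset(l.taxon.label for l in nd.leaf_iter()))
        return out

    def test_recovers_additive_topology(self):
        ids = ["a", "b", "c", "d"]
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        d = {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        tree = be.nj_tree(be.DistanceMatrix(ids=tuple(ids), matrix=mat))
        assert any(s in ({"a", "b"}, {"c", "d"}) for s in map(set, self.splits(tree)))

    def test_too_few_specimens_raises(self):
        dm = be.DistanceMatrix(ids=("a", "b"), matrix=np.zeros((2, 2)))
        with pytest.raises(AlignmentError):
            be.nj_tree(dm)

    def test_input_order_invariance(self, rng):
        ids = ["w", "x", "y", "z", "v"]
        mat = rng.random((5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        t1 = be.nj_tree(be.DistanceMatrix(ids=tuple(ids), matrix=mat))
        perm = [3, 1, 4, 0, 2]
        t2 = be.nj_tree(
            be.DistanceMatrix(
                ids=tuple(ids[i] for i in perm), matrix=mat[np.ix_(perm, perm)]
            )
        )
        assert self.splits(t1) == self.splits(t2)
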