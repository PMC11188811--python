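"""Alignment scores vs a brute-force oracle, and liftover properties."""

import itertools
import random

import pytest
from Bio.Align import substitution_matrices

from editrecode.alignment import (
    ProteinAlignment,
    align_genes,
    backtranslate,
    global_protein_align,
    make_aligner,
    pick_ortholog,
)
from editrecode.datamodel import Gene

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a, b, sub, gap_open, gap_extend):
    """Enumerate every global alignment (as edit paths) and score it with
    affine gaps: a gap run of length L costs open + extend*(L-1)."""
    best = [float("-inf")]

    def recurse(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + sub[a[i]][b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            recurse(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            recurse(i, j + 1, score - cost, "b")

    recurse(0, 0, 0.0, None)
    return best[0]


def _as_dict(matrix):
    alpha = matrix.alphabet
    return {x: {y: matrix[x, y] for y in alpha} for x in alpha}


class TestScoreAgainstBruteForce:
    def test_blosum62_pairs_up_to_length_five(self):
        """Optimal affine-gap score equals exhaustive enumeration on a
        reduced amino-acid alphabet."""
        sub = _as_dict(BLOSUM62)
        aligner = make_aligner("BLOSUM62", 10.0, 1.0)
        rng = random.Random(42)
        alphabet = "ARN"
        cases = [
            ("".join(rng.choices(alphabet, k=rng.randint(1, 5))),
             "".join(rng.choices(alphabet, k=rng.randint(1, 5))))
            for _ in range(40)
        ]
        cases += [(a, b) for a in ("A", "AR", "ARN") for b in ("N", "RA", "NRA")]
        for a, b in cases:
            expected = brute_force_best_score(a, b, sub, 10.0, 1.0)
            got = global_protein_align(a, b, aligner=aligner).score
            assert got == pytest.approx(expected), (a, b)

    def test_toy_scoring_example(self):
        """Unit match/mismatch/gap toy scheme, checked against enumeration."""
        alpha = "MKT"
        sub = {x: {y: (1.0 if x == y else -1.0) for y in alpha} for x in alpha}
        aligner = make_aligner()
        aligner.substitution_matrix = None
        aligner.match_score, aligner.mismatch_score = 1.0, -1.0
        aligner.open_gap_score = aligner.extend_gap_score = -1.0
        expected = brute_force_best_score("MKT", "MT", sub, 1.0, 1.0)
        got = global_protein_align("MKT", "MT", aligner=aligner)
        assert got.score == pytest.approx(expected) == 1.0

    def test_identical_sequences_align_ungapped_with_diagonal_score(self):
        seq = "MKTWQ"
        pa = global_protein_align(seq, seq)
        assert pa.aligned_a == pa.aligned_b == seq
        assert pa.score == sum(BLOSUM62[c, c] for c in seq)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            global_protein_align("", "MK")
        with pytest.raises(ValueError):
            global_protein_align("M*K", "MK")


class TestPickOrtholog:
    CANDIDATES = {"b": "MKTW", "a": "MATTW", "c": "WWWW"}

    def test_identical_candidate_wins(self):
        best, _ = pick_ortholog("MKTW", self.CANDIDATES)
        assert best == "b"

    def test_tie_breaks_lexicographically(self, caplog):
        best, _ = pick_ortholog("MKTW", {"z": "MKTW", "y": "MKTW"})
        assert best == "y"

    def test_single_candidate_returned_regardless_of_score(self):
        best, _ = pick_ortholog("MKTW", {"only": "CCCC"})
        assert best == "only"

    def test_empty_candidate_set_errors(self):
        with pytest.raises(ValueError):
            pick_ortholog("MK", {})


class TestBacktranslateAndLiftover:
    def test_ungapped_alignment_maps_identically(self):
        pa = global_protein_align("MK", "MK")
        ca = backtranslate(pa, "ATGAAA", "ATGAAA")
        for p in range(6):
            assert ca.map_cds_position(p) == p

    def test_gap_column_expands_to_codon_gap(self):
        # hand-constructed alignment M-K / MQK
        pa = ProteinAlignment(aligned_a="M-K", aligned_b="MQK", score=0.0)
        ca = backtranslate(pa, "ATGAAA", "ATGCAAAAA")
        assert [ca.map_cds_position(p) for p in range(3)] == [0, 1, 2]
        assert [ca.map_cds_position(p) for p in range(3, 6)] == [6, 7, 8]
        assert ca.map_cds_position(4) == 7
        # B's inserted codon has no counterpart in A
        assert ca.map_b_to_a(3) is None
        row_a, row_b = ca.aligned_codon_rows()
        assert row_a == "ATG---AAA" and row_b == "ATGCAAAAA"

    def test_gap_in_b_makes_a_codon_unmapped(self):
        pa = ProteinAlignment(aligned_a="MQK", aligned_b="M-K", score=0.0)
        ca = backtranslate(pa, "ATGCAAAAA", "ATGAAA")
        assert ca.map_cds_position(3) is None
        assert ca.map_cds_position(4) is None

    def test_translation_mismatch_raises_naming_residue(self):
        pa = ProteinAlignment(aligned_a="MK", aligned_b="MK", score=0.0)
        with pytest.raises(ValueError, match="residue 1"):
            backtranslate(pa, "ATGACT", "ATGAAA")  # MT vs row MK

    def test_out_of_range_position_errors(self):
        pa = global_protein_align("MK", "MK")
        ca = backtranslate(pa, "ATGAAA", "ATGAAA")
        with pytest.raises(ValueError):
            ca.map_cds_position(6)

    def test_codon_pos_preserved_monotone_and_round_trip(self, small_pair):
        """Liftover invariants on realistic diverged gene pairs."""
        ds_a, ds_b, _ = small_pair
        for gid in itertools.islice(sorted(ds_a.genes), 3):
            ca = align_genes(ds_a.genes[gid], ds_b.genes[gid])
            mapped = []
            for p in range(len(ca.cds_a)):
                q = ca.map_cds_position(p)
                if q is None:
                    continue
                assert p % 3 == q % 3  # within-codon offset preserved
                assert ca.map_b_to_a(q) == p  # round trip
                mapped.append((p, q))
            # strict monotonicity over mapped positions
            assert all(q1 < q2 for (_, q1), (_, q2) in zip(mapped, mapped[1:]))


def test_align_genes_on_genes_with_terminal_stop():
    a = Gene("g", "x", "ATGAAAACTTAA")
    b = Gene("g", "y", "ATGAAAATTTAA")
    ca = align_genes(a, b)
    assert ca.map_cds_position(6) == 6
    pairs = list(ca.codon_pairs())
    assert pairs[-1][2:] == ("ACT", "ATT")
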