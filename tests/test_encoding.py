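"""Peptide I/O, length normalisation and numeric encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepfunc.encoding import (AMINO_ACIDS, FastaParseError, FunctionVocabulary,
                              LabelTableError, PSSMParseError, Peptide,
                              PSSMProfile, encode_sample, one_hot_encode,
                              pad_or_truncate, parse_pssm, read_fasta,
                              read_label_table, write_label_table)

EXAMPLE = "GVAKFGKAAAHFGKGWIKEMLNS"  # a 23-residue antimicrobial peptide


# -- FASTA ---------------------------------------------------------------

class TestReadFasta:
    def test_single_record(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(f">p1\n{EXAMPLE}\n")
        peps = read_fasta(f)
        assert len(peps) == 1
        assert peps[0].id == "p1"
        assert len(peps[0].sequence) == 23
        assert peps[0].labels == set()

    def test_empty_file(self, tmp_path):
        f = tmp_path / "e.fasta"
        f.write_text("")
        assert read_fasta(f) == []

    def test_multiline_sequence(self, tmp_path):
        f = tmp_path / "m.fasta"
        f.write_text(">p1\nGVAKFGKAAAH\nFGKGWIKEMLNS\n")
        assert read_fasta(f)[0].sequence == EXAMPLE

    def test_nonstandard_residue_strict_names_position(self, tmp_path):
        f = tmp_path / "b.fasta"
        f.write_text(">bad\nACDBACDEFGHIKL\n")
        with pytest.raises(FastaParseError, match="position 4"):
            read_fasta(f, strict=True)

    def test_nonstandard_residue_lenient_warns(self, tmp_path):
        f = tmp_path / "b.fasta"
        f.write_text(">bad\nACDBACDEFGHIKL\n")
        with pytest.warns(UserWarning, match="non-standard"):
            peps = read_fasta(f)
        assert len(peps) == 1

    def test_short_sequence_warns_then_rejects_in_strict(self, tmp_path):
        f = tmp_path / "s.fasta"
        f.write_text(">short\nACDEF\n")
        with pytest.warns(UserWarning, match="below the recommended minimum"):
            assert len(read_fasta(f)) == 1
        with pytest.raises(FastaParseError):
            read_fasta(f, strict=True)

    def test_duplicate_ids_suffixed(self, tmp_path):
        f = tmp_path / "d.fasta"
        f.write_text(">p\nGVAKFGKAAAHF\n>p\nGVAKFGKAAAHF\n")
        assert [p.id for p in read_fasta(f)] == ["p", "p.2"]


# -- label table ---------------------------------------------------------

class TestLabelTable:
    def test_round_trip_bit_exact(self, tmp_path):
        vocab = FunctionVocabulary()
        rng = np.random.default_rng(0)
        Y = rng.integers(0, 2, size=(6, 15))
        ids = [f"s{i}" for i in range(6)]
        path = tmp_path / "labels.tsv"
        write_label_table(ids, Y, vocab, path)
        ids2, Y2 = read_label_table(path, vocab)
        assert ids2 == ids
        assert np.array_equal(Y, Y2)

    def test_shuffled_columns_reordered(self, tmp_path, vocab4):
        ids = ["a", "b", "c"]
        Y = np.zeros((3, 4), dtype=int)
        Y[1, 2] = 1
        path = tmp_path / "l.csv"
        names = list(vocab4)
        shuffled = [names[i] for i in (2, 0, 3, 1)]
        with open(path, "w") as fh:
            fh.write("id," + ",".join(shuffled) + "\n")
            for i, s in enumerate(ids):
                fh.write(s + "," + ",".join(
                    str(Y[i, names.index(n)]) for n in shuffled) + "\n")
        _, Y2 = read_label_table(path, vocab4)
        assert np.array_equal(Y, Y2)
        assert Y2.sum() == 1

    def test_missing_function_column_errors(self, tmp_path):
        vocab = FunctionVocabulary()
        path = tmp_path / "l.csv"
        names = list(vocab)[:-1]   # 14 of 15
        path.write_text("id," + ",".join(names) + "\n"
                        + "a," + ",".join("0" for _ in names) + "\n")
        with pytest.raises(LabelTableError, match="missing"):
            read_label_table(path, vocab)

    def test_non_binary_cell_names_row_and_column(self, tmp_path, vocab4):
        path = tmp_path / "l.csv"
        path.write_text("id," + ",".join(vocab4) + "\na,0,2,0,0\n")
        with pytest.raises(LabelTableError, match="'a'"):
            read_label_table(path, vocab4)

    def test_id_mismatch_lists_missing(self, tmp_path, vocab4):
        path = tmp_path / "l.csv"
        path.write_text("id," + ",".join(vocab4) + "\na,0,1,0,0\n")
        with pytest.raises(LabelTableError, match="b"):
            read_label_table(path, vocab4, ids=["a", "b"])


# -- pad / truncate ------------------------------------------------------

class TestPadOrTruncate:
    def test_short_sequence_padded_at_end(self):
        s, mask = pad_or_truncate(EXAMPLE, 50)
        assert len(s) == 50
        assert s[:23] == EXAMPLE
        assert mask[:23].all() and not mask[23:].any()
        assert int(mask.sum()) == 23

    def test_exact_length_unchanged(self):
        seq = (AMINO_ACIDS * 3)[:50]
        s, mask = pad_or_truncate(seq, 50)
        assert s == seq and mask.all()

    def test_long_sequence_splices_termini(self):
        seq = "".join(AMINO_ACIDS[i % 20] for i in range(60))
        s, mask = pad_or_truncate(seq, 50)
        assert s == seq[:25] + seq[-25:]
        assert mask.all()

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError, match="even"):
            pad_or_truncate("ACDEF", 49)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=80))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_no_new_residues(self, seq):
        s, mask = pad_or_truncate(seq, 50)
        s2, _ = pad_or_truncate(s, 50)   # fixed point once at length L
        assert s2 == s
        real = {ch for ch, m in zip(s, mask) if m}
        assert real <= set(seq)


# -- one-hot -------------------------------------------------------------

class TestOneHot:
    def test_homopolymer(self):
        mat = one_hot_encode("A" * 50, np.ones(50, bool))
        assert mat.shape == (50, 20)
        assert (mat[:, 0] == 1).all() and mat.sum() == 50

    def test_padded_rows_zero(self):
        s, mask = pad_or_truncate(EXAMPLE, 50)
        mat = one_hot_encode(s, mask)
        assert (mat.sum(axis=1) == mask).all()
        assert np.count_nonzero(mat.sum(axis=1)) == 23

    def test_alphabet_is_permutation(self):
        s, mask = pad_or_truncate(AMINO_ACIDS, 50)
        mat = one_hot_encode(s, mask)
        assert (mat[:20].sum(axis=0) == 1).all()

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError, match="position 2"):
            one_hot_encode("A*A", np.ones(3, bool))


# -- PSSM ----------------------------------------------------------------

PSSM_TEXT = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts

            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 G    -1  -3  -2  -2  -3  -3  -3   6  -3  -5  -5  -2  -4  -4  -3  -1  -2  -3  -4  -4    0   0   0   0   0   0   0  100   0   0   0   0   0   0   0   0   0   0   0   0  0.97 0.10
    2 V    -1  -3  -4  -4  -2  -3  -3  -4  -4   2   0  -3   0  -2  -3  -2  -1  -4  -2   5    0   0   0   0   0   0   0   0   0  10   0   0   0   0   0   0   0   0   0  90  0.83 0.12
    3 A     4  -2  -2  -2  -1  -1  -1  -1  -2  -2  -2  -1  -1  -3  -1   1  -1  -3  -2  -1   80   0   0   0   0   0   0   0   0   0   0   0   0   0   0  20   0   0   0   0  0.30 0.08
    4 K    -1   2  -1  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1  -1  -1  -4  -2  -3    0  10   0   0   0   0   0   0   0   0   0  90   0   0   0   0   0   0   0   0  0.61 0.09
    5 F    -3  -3  -4  -4  -3  -4  -4  -4  -2   0   0  -4   0   7  -4  -3  -2   0   3  -1    0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0  0.90 0.11
"""


class TestParsePSSM:
    def test_five_residue_fixture(self, tmp_path):
        path = tmp_path / "p.pssm"
        path.write_text(PSSM_TEXT)
        prof = parse_pssm(path, sequence="GVAKF")
        assert prof.scores.shape == (5, 20)
        assert prof.residues == "GVAKF"
        # row 1 is glycine: +6 in the G column, alphabetical layout
        assert prof.scores[0, AMINO_ACIDS.index("G")] == 6
        assert prof.scores[4, AMINO_ACIDS.index("F")] == 7
        assert prof.scores[1, AMINO_ACIDS.index("V")] == 5

    def test_sequence_mismatch_names_position(self, tmp_path):
        path = tmp_path / "p.pssm"
        path.write_text(PSSM_TEXT)
        with pytest.raises(PSSMParseError, match="position 2"):
            parse_pssm(path, sequence="GAAKF")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "e.pssm"
        path.write_text("")
        with pytest.raises(PSSMParseError):
            parse_pssm(path)


# -- sample encoding -----------------------------------------------------

class TestEncodeSample:
    def test_zero_fallback_without_pssm(self):
        enc = encode_sample(Peptide("p", EXAMPLE))
        assert enc.Xs.shape == (50, 40)
        assert (enc.Xs[:, 20:] == 0).all()
        assert (enc.Xs[:, :20].sum(axis=1) == enc.mask).all()

    def test_pssm_block_matches_profile(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(-5, 8, size=(23, 20)).astype(float)
        prof = PSSMProfile(residues=EXAMPLE, scores=scores)
        enc = encode_sample(Peptide("p", EXAMPLE), pssm=prof)
        assert np.array_equal(enc.Xs[:23, 20:], scores)
        assert (enc.Xs[23:, 20:] == 0).all()

    def test_pssm_spliced_like_sequence(self):
        seq = "".join(AMINO_ACIDS[i % 20] for i in range(60))
        scores = np.arange(60 * 20, dtype=float).reshape(60, 20)
        enc = encode_sample(Peptide("p", seq),
                            pssm=PSSMProfile(residues=seq, scores=scores))
        assert np.array_equal(enc.Xs[:25, 20:], scores[:25])
        assert np.array_equal(enc.Xs[25:, 20:], scores[-25:])

    def test_function_input_is_identity(self):
        enc = encode_sample(Peptide("p", EXAMPLE))
        assert enc.Xt.shape == (15, 15)
        assert np.array_equal(enc.Xt, np.eye(15))

    def test_length_mismatch_rejected(self):
        prof = PSSMProfile(residues="GVAKF", scores=np.zeros((5, 20)))
        with pytest.raises(ValueError, match="5 rows"):
            encode_sample(Peptide("p", EXAMPLE), pssm=prof)

    def test_blosum62_fallback_has_nonzero_profile(self):
        enc = encode_sample(Peptide("p", EXAMPLE), pssm_fallback="blosum62")
        assert np.abs(enc.Xs[:23, 20:]).sum() > 0
        # alanine row: BLOSUM62 diagonal value 4
        assert enc.Xs[2, 20 + AMINO_ACIDS.index("A")] == 4
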