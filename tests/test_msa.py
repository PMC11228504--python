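"""Alignment reading, species grouping, padding and pair assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paramatch.msa import (
    GAP_CHAR,
    Msa,
    MsaLengthError,
    SpeciesAnnotationError,
    build_paired_msa,
    group_species,
    pad_species,
    pairs_table,
    perms_from_pairs,
    read_msa,
    write_msa,
)

AA = "ACDEFGHIKL"


def _msa(rows):
    """rows: list of (id, species, seq)."""
    return Msa(
        ids=[r[0] for r in rows],
        species=[r[1] for r in rows],
        seqs=[r[2] for r in rows],
    )


class TestReadWrite:
    def test_header_dialect_roundtrip(self, tmp_path):
        msa = _msa([("s1", "E.coli", "ACD-EF"), ("s2", "B.sub", "GHKL-M".replace("M", "A")), ("s3", "E.coli", "------")])
        path = tmp_path / "a.fasta"
        write_msa(msa, path)
        back = read_msa(path)
        assert back.ids == msa.ids
        assert back.species == msa.species
        assert back.seqs == msa.seqs

    def test_sidecar_species_table(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">seq1\nACDE\n>seq2\nGHKL\n")
        table = tmp_path / "species.tsv"
        table.write_text("seq1\tE.coli\nseq2\tB.sub\n")
        msa = read_msa(path, species_table=table)
        assert msa.species == ["E.coli", "B.sub"]

    def test_sidecar_missing_id_names_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">seq1\nACDE\n>orphan\nGHKL\n")
        table = tmp_path / "species.tsv"
        table.write_text("seq1\tE.coli\n")
        with pytest.raises(SpeciesAnnotationError, match="orphan"):
            read_msa(path, species_table=table)

    def test_missing_header_delimiter(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">nodelim\nACDE\n")
        with pytest.raises(SpeciesAnnotationError):
            read_msa(path)

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">s1|x\nACDE\n>s2|x\nAC\n")
        with pytest.raises(MsaLengthError):
            read_msa(path)

    def test_lowercase_and_dot_normalized(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">s1|x\nac.e\n")
        msa = read_msa(path)
        assert msa.seqs == ["AC" + GAP_CHAR + "E"]

    def test_foreign_token_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            _msa([("s1", "x", "AC?E")])


class TestGrouping:
    def test_species_in_one_msa_discarded(self):
        msa_a = _msa([("a1", "X", "AC"), ("a2", "X", "CD"), ("a3", "Y", "EF")])
        msa_b = _msa([("b1", "X", "GH"), ("b2", "X", "KL"), ("b3", "Z", "AC"), ("b4", "Z", "CD"), ("b5", "Z", "DE")])
        ds = group_species(msa_a, msa_b)
        assert [b.species for b in ds.blocks] == ["X"]
        assert ds.blocks[0].nk_a == 2 and ds.blocks[0].nk_b == 2
        assert ds.trivial_pairs == []

    def test_singleton_species_is_trivial(self):
        msa_a = _msa([("a1", "X", "AC")])
        msa_b = _msa([("b1", "X", "GH")])
        ds = group_species(msa_a, msa_b)
        assert ds.blocks == []
        assert ds.trivial_pairs == [(0, 0)]

    def test_empty_inputs(self):
        ds = group_species(_msa([]), _msa([]))
        assert ds.blocks == [] and ds.trivial_pairs == []

    def test_positives_removed_from_blocks(self):
        msa_a = _msa([("a1", "X", "AC"), ("a2", "X", "CD"), ("a3", "X", "EF")])
        msa_b = _msa([("b1", "X", "GH"), ("b2", "X", "KL"), ("b3", "X", "AC")])
        ds = group_species(msa_a, msa_b, positives=[(0, 0)])
        assert ds.positives == [(0, 0)]
        assert ds.blocks[0].rows_a == [1, 2]
        assert ds.blocks[0].rows_b == [1, 2]

    def test_oversized_species_excluded(self):
        rows_a = [(f"a{i}", "X", "AC") for i in range(4)]
        rows_b = [(f"b{i}", "X", "GH") for i in range(4)]
        ds = group_species(_msa(rows_a), _msa(rows_b), max_block_size=3)
        assert ds.blocks == []
        assert ds.oversized_species == ["X"]


class TestPadding:
    def _asym(self, na, nb):
        msa_a = _msa([(f"a{i}", "X", "AC") for i in range(na)])
        msa_b = _msa([(f"b{i}", "X", "GH") for i in range(nb)])
        return pad_species(group_species(msa_a, msa_b))

    def test_pads_smaller_a_side(self):
        ds = self._asym(2, 5)
        block = ds.blocks[0]
        assert len(block.padding_a) == 3 and block.padding_b == []
        assert block.nk == 5
        assert all(set(ds.msa_a.seqs[i]) == {GAP_CHAR} for i in block.padding_a)

    def test_symmetric_block_unchanged(self):
        ds = self._asym(3, 3)
        block = ds.blocks[0]
        assert block.padding_a == [] and block.padding_b == []

    def test_pads_smaller_b_side(self):
        ds = self._asym(4, 1)
        block = ds.blocks[0]
        assert len(block.padding_b) == 3 and block.padding_a == []
        assert len(block.side_a) == len(block.side_b) == 4

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 6), st.integers(1, 6)), min_size=1, max_size=5))
    def test_padding_equalizes_any_profile(self, profile):
        rows_a, rows_b = [], []
        for k, (na, nb) in enumerate(profile):
            rows_a += [(f"a{k}_{i}", f"sp{k}", "ACDE") for i in range(na)]
            rows_b += [(f"b{k}_{i}", f"sp{k}", "GH") for i in range(nb)]
        ds = pad_species(group_species(_msa(rows_a), _msa(rows_b)))
        for block in ds.blocks:
            assert len(block.side_a) == len(block.side_b) == block.nk


class TestPairedAssembly:
    def _problem(self):
        msa_a = _msa(
            [("a1", "X", "AC"), ("a2", "X", "CD"),
             ("a3", "Y", "EF"), ("a4", "Y", "FG"), ("a5", "Y", "GH")]
        )
        msa_b = _msa(
            [("b1", "X", "KLM".replace("M", "A")), ("b2", "X", "LKA"),
             ("b3", "Y", "ACD"), ("b4", "Y", "CDE"), ("b5", "Y", "DEF")]
        )
        return pad_species(group_species(msa_a, msa_b))

    def test_identity_preserves_order(self):
        ds = self._problem()
        paired = build_paired_msa(ds, [np.eye(2), np.eye(3)])
        assert len(paired.rows) == 5
        assert paired.rows[0] == ds.msa_a.seqs[0] + ds.msa_b.seqs[0]
        assert paired.boundary == 2
        # extracting the A-side columns reproduces the A alignment
        assert [r[: paired.boundary] for r in paired.rows] == ds.msa_a.seqs

    def test_swap_exchanges_a_rows(self):
        ds = self._problem()
        swap = np.array([[0.0, 1.0], [1.0, 0.0]])
        paired = build_paired_msa(ds, [swap, np.eye(3)])
        assert paired.rows[0] == ds.msa_a.seqs[1] + ds.msa_b.seqs[0]
        assert paired.rows[1] == ds.msa_a.seqs[0] + ds.msa_b.seqs[1]

    def test_positive_rows_are_non_maskable(self):
        msa_a = _msa([("a1", "X", "AC"), ("a2", "X", "CD"), ("a3", "X", "DE"), ("p1", "Z", "EF")])
        msa_b = _msa([("b1", "X", "GH"), ("b2", "X", "HK"), ("b3", "X", "KL"), ("q1", "Z", "LA")])
        ds = pad_species(group_species(msa_a, msa_b, positives=[(3, 3), (0, 0)]))
        paired = build_paired_msa(ds, [np.eye(2)], include_positives=True)
        assert len(paired.rows) == 4  # 2 block rows + 2 positives
        assert paired.is_positive == [False, False, True, True]
        assert not paired.maskable[2:].any()
        assert paired.maskable[:2].all()

    def test_size_mismatch_rejected(self):
        ds = self._problem()
        with pytest.raises(ValueError):
            build_paired_msa(ds, [np.eye(3), np.eye(3)])

    def test_pairs_table_roundtrip_through_perms(self):
        ds = self._problem()
        perms = [np.array([[0.0, 1.0], [1.0, 0.0]]), np.eye(3)]
        rows = pairs_table(ds, perms)
        rebuilt = perms_from_pairs(ds, [(r["id_A"], r["id_B"]) for r in rows])
        assert all(np.array_equal(p, q) for p, q in zip(perms, rebuilt))
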