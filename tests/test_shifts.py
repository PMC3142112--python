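"""Shift-table parsing, secondary shifts and CSI segmentation."""
import pytest

from noeturn.sequences import parse_sequence
from noeturn.shifts import (
    RandomCoilTable,
    ShiftParseError,
    ShiftRecord,
    ShiftTable,
    ShiftValidationError,
    csi_segments,
    load_random_coil,
    parse_nmrstar_shifts,
    parse_shift_table,
    secondary_shifts,
    write_long_tsv,
    write_shift_table,
)


class TestParsing:
    def test_nle35_amide_shift(self, paper):
        assert paper.shifts_full.get(35, "NH") == pytest.approx(8.301)

    def test_proline_rows_have_no_amide(self, paper):
        assert paper.shifts_full.get(37, "NH") is None
        assert paper.shifts_truncated.get(37, "NH") is None
        assert paper.shifts_full.get(37, "HA") == pytest.approx(4.22)

    def test_assigned_residues_match_the_tables(self, paper):
        assert paper.shifts_full.residues == [10, 16] + list(range(22, 43))
        assert paper.shifts_truncated.residues == list(range(22, 43))

    def test_decimal_comma_cell(self, paper):
        # the K16 delta-proton cell is printed with a decimal comma
        assert paper.shifts_full.get(16, "HD") == pytest.approx(1.405)

    def test_multivalue_cells_get_branch_suffixes(self, paper):
        assert paper.shifts_full.get(10, "HB1") == pytest.approx(2.95)
        assert paper.shifts_full.get(10, "HB2") == pytest.approx(3.08)
        # no-space comma between full decimals is a separator
        assert paper.shifts_truncated.get(28, "HB1") == pytest.approx(1.978)
        assert paper.shifts_truncated.get(28, "HB2") == pytest.approx(1.885)

    def test_empty_body_gives_empty_table(self):
        seq = parse_sequence("AG")
        table = parse_shift_table("Amino acid\tNH\tαH\tβH\tOthers\n", seq)
        assert table.records == []

    def test_unknown_residue_code_names_the_row(self):
        seq = parse_sequence("AG")
        with pytest.raises(ShiftParseError, match="row 2"):
            parse_shift_table(
                "Amino acid\tNH\tαH\tβH\tOthers\nXX1\t8.1\t4.2\t\t\n", seq
            )

    def test_duplicate_nucleus_is_a_validation_error(self):
        seq = parse_sequence("A")
        with pytest.raises(ShiftValidationError, match="duplicate"):
            ShiftTable("x", seq, [ShiftRecord(1, "ALA", "HA", 4.3),
                                  ShiftRecord(1, "ALA", "HA", 4.4)])

    def test_code_mismatch_with_sequence(self):
        seq = parse_sequence("AG")
        with pytest.raises(ShiftValidationError, match="GLY"):
            ShiftTable("x", seq, [ShiftRecord(2, "ALA", "HA", 4.3)])

    def test_shift_out_of_proton_range(self):
        with pytest.raises(ShiftValidationError):
            ShiftRecord(1, "ALA", "HA", 14.0)

    @pytest.mark.parametrize("which", ["shifts_full", "shifts_truncated"])
    def test_roundtrip_through_the_wide_format(self, paper, which):
        table = getattr(paper, which)
        text = write_shift_table(table)
        again = parse_shift_table(text, table.sequence, table.peptide_id)
        assert sorted(again.records) == sorted(table.records)

    def test_long_tsv_has_one_row_per_record(self, paper):
        text = write_long_tsv(paper.shifts_full)
        assert len(text.strip().splitlines()) == len(paper.shifts_full.records) + 1


class TestNmrStar:
    STAR = """\
data_test
loop_
_Atom_chem_shift.Seq_ID
_Atom_chem_shift.Comp_ID
_Atom_chem_shift.Atom_ID
_Atom_chem_shift.Val
1 ALA H 8.24
1 ALA HA 4.32
2 GLY HA 3.96
stop_
"""

    def test_atom_chem_shift_loop(self):
        seq = parse_sequence("AG")
        table = parse_nmrstar_shifts(self.STAR, seq)
        assert table.get(1, "NH") == pytest.approx(8.24)
        assert table.get(2, "HA") == pytest.approx(3.96)
        assert len(table.records) == 3


class TestSecondaryShifts:
    def test_a30_alanine_delta(self, paper):
        deltas = {(i, n): d for i, n, d in secondary_shifts(paper.shifts_full)}
        assert deltas[(30, "HA")] == pytest.approx(0.046, abs=1e-9)

    def test_zero_when_observed_equals_reference(self):
        seq = parse_sequence("A")
        ref = load_random_coil()
        table = ShiftTable("x", seq, [ShiftRecord(1, "ALA", "HA", ref[("ALA", "HA")])])
        (_, _, d), = secondary_shifts(table)
        assert d == 0.0

    def test_all_glycine_identity(self):
        seq = parse_sequence("GGGG")
        ref = load_random_coil()
        recs = [ShiftRecord(i, "GLY", "HA", ref[("GLY", "HA")]) for i in range(1, 5)]
        out = secondary_shifts(ShiftTable("g", seq, recs))
        assert all(d == 0.0 for _, _, d in out)

    def test_antisymmetric_under_observed_reference_swap(self):
        seq = parse_sequence("AVG")
        ref = load_random_coil()
        obs = {1: 4.50, 2: 4.00, 3: 4.10}
        table = ShiftTable("x", seq, [
            ShiftRecord(i, seq.code(i), "HA", v) for i, v in obs.items()
        ])
        fwd = [d for _, _, d in secondary_shifts(table, ref)]
        swapped_ref = RandomCoilTable(
            {(seq.code(i), "HA"): obs[i] for i in obs}
        )
        swapped_table = ShiftTable("x", seq, [
            ShiftRecord(i, seq.code(i), "HA", ref[(seq.code(i), "HA")])
            for i in obs
        ])
        bwd = [d for _, _, d in secondary_shifts(swapped_table, swapped_ref)]
        assert fwd == pytest.approx([-b for b in bwd])

    def test_missing_reference_entry_is_named(self):
        seq = parse_sequence("A")
        table = ShiftTable("x", seq, [ShiftRecord(1, "ALA", "HA", 4.3)])
        with pytest.raises(ShiftValidationError, match="ALA"):
            secondary_shifts(table, RandomCoilTable())

    def test_absent_residues_are_omitted_not_zero_filled(self, paper):
        indices = {i for i, n, _ in secondary_shifts(paper.shifts_full) if n == "HA"}
        assert 11 not in indices  # unassigned N-terminal residue


class TestCsi:
    def test_paper_table_is_all_coil(self, paper):
        ha = [(i, d) for i, n, d in secondary_shifts(paper.shifts_full) if n == "HA"]
        assert csi_segments(ha, threshold=0.1, min_run=4) == []

    def test_synthetic_strand_run(self):
        deltas = [(i, 0.2) for i in range(1, 6)]
        assert csi_segments(deltas, 0.1, 4) == [(1, 5, "strand")]

    def test_alternating_deltas_make_no_segment(self):
        deltas = [(i, 0.2 if i % 2 else -0.2) for i in range(1, 9)]
        assert csi_segments(deltas, 0.1, 4) == []

    def test_helix_run_is_labelled(self):
        deltas = [(i, -0.3) for i in range(5, 10)]
        assert csi_segments(deltas, 0.1, 4) == [(5, 9, "helix")]

    def test_min_run_must_be_positive(self):
        with pytest.raises(ValueError):
            csi_segments([(1, 0.2)], 0.1, 0)
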