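"""All-atom builder: geometry, chirality, caps, torsion manipulation, PDB."""
import numpy as np
import pytest

import biotite.structure.info as struc_info

from noeturn.builder import (
    BuildError,
    CapSpec,
    TorsionConstraintError,
    build_extended,
    measure_dihedrals,
    read_pdb,
    set_torsions,
    write_pdb,
)
from noeturn.geometry import dihedral
from noeturn.sequences import parse_sequence


def _dihedral_map(conf):
    return {r: (phi, psi, om) for r, phi, psi, om in measure_dihedrals(conf)}


class TestBuildExtended:
    def test_backbone_torsions_are_extended(self):
        conf = build_extended("DVGSNKGA", CapSpec())
        for r, phi, psi, om in measure_dihedrals(conf):
            assert phi == pytest.approx(-120.0, abs=0.5)
            assert psi == pytest.approx(120.0, abs=0.5)
            assert abs(abs(om) - 180.0) < 1.0

    def test_first_turn_fragment_is_all_l(self):
        seq = parse_sequence("DVGSNKGA", start=23)
        conf = build_extended(seq, CapSpec())
        assert set(np.unique(conf.res_index)) == set(range(22, 32))
        assert "ACE" in conf.res_code and "NME" in conf.res_code
        assert "D" not in conf.chirality.values()
        assert conf.chirality[25] == "achiral"  # glycine

    def test_second_turn_fragment_has_d_proline(self, s42):
        conf = build_extended(s42.subsequence(34, 41), CapSpec())
        assert conf.chirality[37] == "D"
        md = _dihedral_map(conf)
        assert md[37][0] == pytest.approx(75.0, abs=0.5)

    def test_d_proline_is_the_exact_mirror_of_l_proline(self):
        pro = build_extended("A{PRO}A", CapSpec())
        dpr = build_extended("A{DPR}A", CapSpec())
        def improper(conf):
            return dihedral(*(conf.coord[conf.atom_index(2, a)]
                              for a in ("N", "CA", "C", "CB")))
        assert improper(pro) == pytest.approx(-improper(dpr), abs=1e-9)

    def test_uncapped_ag_atom_count_matches_ccd_templates(self):
        # independent count from the chemical component dictionary:
        # N-terminal Ala keeps H+H2 and loses OXT/HXT, C-terminal Gly keeps
        # the carboxylate O+OXT and loses HXT/H2
        ala = set(struc_info.residue("ALA").atom_name) - {"OXT", "HXT"}
        gly = set(struc_info.residue("GLY").atom_name) - {"HXT", "H2"}
        conf = build_extended("AG", CapSpec("none", "none"))
        assert len(conf) == len(ala) + len(gly)

    def test_capped_chain_has_no_charged_termini(self):
        conf = build_extended("AG", CapSpec())
        assert "OXT" not in conf.atom_name
        n_term_h = [a for a, r in zip(conf.atom_name, conf.res_index)
                    if r == 1 and a in ("H", "H2", "H3")]
        assert n_term_h == ["H"]

    def test_unsupported_code_lists_supported(self):
        with pytest.raises(Exception, match="supported"):
            build_extended("A{XYZ}A", CapSpec())

    def test_bond_lengths_within_ten_percent_of_ideal(self):
        conf = build_extended("LVFFA", CapSpec())
        d = np.linalg.norm(conf.coord[conf.bonds[:, 0]]
                           - conf.coord[conf.bonds[:, 1]], axis=1)
        assert d.min() > 0.09 and d.max() < 0.17

    def test_no_atom_pair_closer_than_half_angstrom(self):
        from scipy.spatial.distance import pdist

        conf = build_extended("DVGSNKGA", CapSpec())
        assert pdist(conf.coord).min() > 0.05

    def test_proline_ring_is_closed(self):
        conf = build_extended("A{DPR}A", CapSpec())
        d = conf.distance(conf.atom_index(2, "CD"), conf.atom_index(2, "N"))
        assert 0.13 < d < 0.16


class TestSetTorsions:
    def test_requested_angles_are_reached(self, s42):
        conf = build_extended(s42.subsequence(34, 41), CapSpec())
        new = set_torsions(conf, 38, phi=-60.0, psi=-30.0)
        md = _dihedral_map(new)
        assert md[38][0] == pytest.approx(-60.0, abs=0.5)
        assert md[38][1] == pytest.approx(-30.0, abs=0.5)

    def test_inverse_restores_coordinates(self, s42):
        conf = build_extended(s42.subsequence(34, 41), CapSpec())
        new = set_torsions(conf, 38, phi=-60.0, psi=-30.0)
        back = set_torsions(new, 38, phi=-120.0, psi=120.0)
        assert np.abs(back.coord - conf.coord).max() < 1e-6

    def test_psi_only_leaves_phi_untouched(self):
        conf = build_extended("AVAVA", CapSpec())
        new = set_torsions(conf, 3, psi=-40.0)
        md = _dihedral_map(new)
        assert md[3][0] == pytest.approx(-120.0, abs=0.5)
        assert md[3][1] == pytest.approx(-40.0, abs=0.5)

    def test_bond_lengths_are_preserved_exactly(self):
        conf = build_extended("AVAVA", CapSpec())
        new = set_torsions(conf, 3, phi=-57.0, psi=-47.0)
        d0 = np.linalg.norm(conf.coord[conf.bonds[:, 0]]
                            - conf.coord[conf.bonds[:, 1]], axis=1)
        d1 = np.linalg.norm(new.coord[new.bonds[:, 0]]
                            - new.coord[new.bonds[:, 1]], axis=1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_proline_phi_is_ring_constrained(self):
        conf = build_extended("A{DPR}A", CapSpec())
        with pytest.raises(TorsionConstraintError):
            set_torsions(conf, 2, phi=-60.0)
        # within the window it is allowed
        set_torsions(conf, 2, phi=80.0)

    def test_build_measure_set_is_idempotent(self):
        conf = build_extended("GSNK", CapSpec())
        for r, phi, psi, _ in measure_dihedrals(conf):
            conf2 = set_torsions(conf, r, phi=phi, psi=psi)
            assert np.abs(conf2.coord - conf.coord).max() < 1e-6


class TestMeasureDihedrals:
    def test_mirroring_flips_all_signs(self):
        conf = build_extended("AVSA", CapSpec())
        mirror = conf.copy()
        mirror.coord[:, 0] *= -1.0
        for (r1, p1, s1, o1), (r2, p2, s2, o2) in zip(
            measure_dihedrals(conf), measure_dihedrals(mirror)
        ):
            assert p1 == pytest.approx(-p2, abs=1e-6)
            assert s1 == pytest.approx(-s2, abs=1e-6)

    def test_free_termini_have_undefined_angles(self):
        conf = build_extended("AVA", CapSpec("none", "none"))
        md = _dihedral_map(conf)
        assert md[1][0] is None  # phi of the first residue
        assert md[3][1] is None  # psi of the last residue

    def test_missing_backbone_atom_is_an_error(self):
        conf = build_extended("AVA", CapSpec())
        conf.atom_name[conf.atom_index(2, "CA")] = "XX"
        conf._index.pop((2, "CA"))
        with pytest.raises(BuildError, match="residue 2"):
            measure_dihedrals(conf)


class TestPdbIO:
    def test_multi_model_roundtrip(self, tmp_path, s42):
        conf = build_extended(s42.subsequence(34, 41), CapSpec())
        bent = set_torsions(conf, 38, phi=-80.0, psi=0.0)
        path = tmp_path / "ens.pdb"
        write_pdb(path, [conf, bent])
        text = path.read_text()
        assert text.count("MODEL") >= 2
        assert "NLE" in text and "DPR" in text
        models = read_pdb(path)
        assert len(models) == 2
        assert np.abs(models[0].coord - conf.coord).max() < 5e-4
        assert np.abs(models[1].coord - bent.coord).max() < 5e-4

    def test_occupancy_and_chain(self, tmp_path):
        conf = build_extended("AG", CapSpec())
        path = tmp_path / "x.pdb"
        write_pdb(path, conf)
        atom_lines = [l for l in path.read_text().splitlines()
                      if l.startswith(("ATOM", "HETATM"))]
        assert all(l[21] == "A" for l in atom_lines)
        assert all(l[54:60].strip() == "1.00" for l in atom_lines)
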