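import numpy as np
import pytest

from krigfield import constants
from krigfield.chem_io import (
    HessianMatrix,
    LabeledGeometry,
    MultipoleSet,
    ParseError,
    TrainingTable,
    read_hessian,
    read_multipoles,
    read_training_table,
    read_xyz,
    write_hessian,
    write_multipoles,
    write_training_table,
    write_xyz,
)


def _water(comment="w"):
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.8], [1.7, 0.0, -0.4]])
    masses = np.array([constants.atomic_mass_me(e) for e in ("O", "H", "H")])
    return LabeledGeometry(("O", "H", "H"), coords, masses, comment)


class TestLabeledGeometry:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            LabeledGeometry(("O", "H"), np.zeros((3, 3)), np.ones(2))

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            LabeledGeometry(("Xx", "H"), np.zeros((2, 3)), np.ones(2))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            LabeledGeometry(("O", "H"), np.zeros((2, 3)), np.array([1.0, 0.0]))

    def test_center_of_mass_weighted(self):
        g = _water()
        com = g.center_of_mass()
        ref = g.masses @ g.coords / g.masses.sum()
        assert np.allclose(com, ref, atol=1e-14)


class TestXYZ:
    def test_round_trip_multiframe(self, tmp_path):
        g1, g2 = _water("first"), _water("second")
        g2 = g2.with_coords(g2.coords + 0.1)
        path = tmp_path / "ens.xyz"
        write_xyz([g1, g2], path)
        back = read_xyz(path)
        assert len(back) == 2
        assert back[0].comment == "first"
        assert back[1].comment == "second"
        assert np.allclose(back[1].coords, g2.coords, atol=1e-10)

    def test_units_are_angstrom_on_disk(self, tmp_path):
        path = tmp_path / "a.xyz"
        path.write_text("2\nc\nH 0 0 0\nH 0 0 1.0\n")
        g = read_xyz(path)[0]
        assert np.isclose(
            np.linalg.norm(g.coords[1] - g.coords[0]), constants.BOHR_PER_ANGSTROM
        )

    def test_bad_count_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("nope\nc\nH 0 0 0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_xyz(path)

    def test_truncated_frame_rejected(self, tmp_path):
        path = tmp_path / "trunc.xyz"
        path.write_text("3\nc\nH 0 0 0\nH 0 0 1\n")
        with pytest.raises(ParseError, match="expected 3 atom lines"):
            read_xyz(path)

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        path = tmp_path / "nan.xyz"
        path.write_text("2\nc\nH 0 0 0\nH 0 zero 1\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_xyz(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.xyz"
        path.write_text("\n\n")
        with pytest.raises(ParseError, match="no frames"):
            read_xyz(path)


class TestHessian:
    def _random_hessian(self, n_atoms, seed=0):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(3 * n_atoms, 3 * n_atoms))
        return HessianMatrix(m + m.T, n_atoms)

    def test_full_round_trip(self, tmp_path):
        h = self._random_hessian(3)
        path = tmp_path / "h.txt"
        write_hessian(h, path)
        back = read_hessian(path, 3)
        assert np.allclose(back.values, h.values, atol=1e-12)

    def test_lower_triangle_detected(self, tmp_path):
        h = self._random_hessian(2)
        rows, cols = np.tril_indices(6)
        path = tmp_path / "tri.txt"
        path.write_text(" ".join(f"{v:.16e}" for v in h.values[rows, cols]))
        back = read_hessian(path, 2)
        assert np.allclose(back.values, h.values, atol=1e-12)

    def test_wrong_count_reports_both_expected_sizes(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(" ".join(["0.0"] * 7))
        with pytest.raises(ParseError, match=r"36.*21"):
            read_hessian(path, 2)

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((6, 6))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="asymmetric"):
            HessianMatrix(m, 2)


class TestMultipoles:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        ms = MultipoleSet(rng.normal(size=(3, 25)), frame="ALF")
        path = tmp_path / "m.csv"
        write_multipoles(ms, ("O", "H", "H"), path)
        back = read_multipoles(path)
        assert back.frame == "ALF"
        assert np.allclose(back.values, ms.values, atol=1e-12)

    def test_missing_component_column_not_zero_filled(self, tmp_path):
        ms = MultipoleSet(np.zeros((2, 25)), frame="global")
        path = tmp_path / "m.csv"
        write_multipoles(ms, ("H", "H"), path)
        text = path.read_text()
        header, rest = text.split("\n", 1)
        header = header.replace(",Q44s", "")
        rest = "\n".join(line.rsplit(",", 1)[0] for line in rest.splitlines())
        path.write_text(header + "\n" + rest + "\n")
        with pytest.raises(ParseError, match="never implicitly zero-filled"):
            read_multipoles(path)

    def test_mixed_frames_rejected(self, tmp_path):
        ms = MultipoleSet(np.zeros((2, 25)), frame="global")
        path = tmp_path / "m.csv"
        write_multipoles(ms, ("H", "H"), path)
        lines = path.read_text().splitlines()
        lines[1] = lines[1].replace("global", "ALF")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="mixed frame"):
            read_multipoles(path)

    def test_bad_frame_tag_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            MultipoleSet(np.zeros((2, 25)), frame="lab")

    def test_wrong_component_count_rejected(self):
        with pytest.raises(ValueError, match="25"):
            MultipoleSet(np.zeros((2, 24)), frame="ALF")


class TestTrainingTable:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        t = TrainingTable(atom=3, features=rng.normal(size=(5, 4)),
                          outputs=rng.normal(size=(5, 25)))
        path = tmp_path / "t.csv"
        write_training_table(t, path)
        back = read_training_table(path)
        assert back.atom == 3
        assert np.allclose(back.features, t.features, atol=1e-12)
        assert np.allclose(back.outputs, t.outputs, atol=1e-12)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TrainingTable(0, np.zeros((4, 2)), np.zeros((5, 25)))
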