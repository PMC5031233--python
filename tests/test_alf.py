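import networkx as nx
import numpy as np
import pytest

import krigfield as kf
from krigfield.alf import (
    ALFDefinition,
    DegenerateFrameError,
    alf_rotation,
    assign_alf,
    build_bond_graph,
    feature_matrix,
    features,
    rotate_multipole_set,
    rotate_multipoles,
)
from krigfield.chem_io import LabeledGeometry, MultipoleSet
from krigfield import constants


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rigidly_moved(geom, seed):
    c = _random_rotation(seed)
    shift = np.random.default_rng(seed + 1).normal(size=3) * 3.0
    return geom.with_coords(geom.coords @ c.T + shift)


class TestBondGraph:
    def test_ring16_topology(self, ring16):
        g = build_bond_graph(ring16.geometry)
        assert g.number_of_edges() == 16
        cycles = nx.cycle_basis(g)
        assert len(cycles) == 1 and len(cycles[0]) == 5
        ring_elements = sorted(ring16.geometry.elements[i] for i in cycles[0])
        assert ring_elements == ["C", "C", "C", "C", "O"]

    def test_chain16_is_a_tree(self, chain16):
        g = build_bond_graph(chain16.geometry)
        assert g.number_of_edges() == 15
        assert nx.is_tree(g)

    def test_disconnected_fragments_rejected(self):
        coords = np.array(
            [[0.0, 0.0, 0.0], [0.0, 0.0, 1.8], [50.0, 0.0, 0.0], [50.0, 0.0, 1.8]]
        )
        masses = np.array([constants.atomic_mass_me("H")] * 4)
        geom = LabeledGeometry(("H", "H", "H", "H"), coords, masses)
        with pytest.raises(ValueError, match="disconnected"):
            build_bond_graph(geom)


class TestAssignALF:
    def test_anchors_distinct_for_every_atom(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        for i in range(16):
            assert len({i, alf.x_axis[i], alf.xy_plane[i]}) == 3

    def test_x_axis_is_heaviest_neighbour(self, triatomic):
        g = build_bond_graph(triatomic.geometry)
        alf = assign_alf(g, triatomic.geometry.elements)
        # both hydrogens bond only to the oxygen
        assert alf.x_axis[1] == 0 and alf.x_axis[2] == 0

    def test_terminal_atom_uses_neighbour_of_neighbour(self, triatomic):
        g = build_bond_graph(triatomic.geometry)
        alf = assign_alf(g, triatomic.geometry.elements)
        # hydrogen 1 is terminal: xy-plane atom must be the other hydrogen
        assert alf.xy_plane[1] == 2

    def test_definition_validates_distinctness(self):
        with pytest.raises(ValueError):
            ALFDefinition(x_axis=(0, 0, 0), xy_plane=(1, 1, 1))


class TestFrames:
    def test_rotation_is_proper_orthogonal(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        for a in range(16):
            c = alf_rotation(ring16.geometry, alf, a)
            assert np.abs(c @ c.T - np.eye(3)).max() < 1e-12
            assert np.isclose(np.linalg.det(c), 1.0)

    def test_x_axis_atom_maps_to_positive_x(self, triatomic):
        g = build_bond_graph(triatomic.geometry)
        alf = assign_alf(g, triatomic.geometry.elements)
        geom = triatomic.geometry
        for a in range(3):
            c = alf_rotation(geom, alf, a)
            v = c @ (geom.coords[alf.x_axis[a]] - geom.coords[a])
            assert v[0] > 0
            assert np.abs(v[1:]).max() < 1e-12

    def test_collinear_frame_rejected(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.8], [0.0, 0.0, 3.6],
                           [1.7, 0.0, 1.8]])
        masses = np.array([constants.atomic_mass_me("C")] * 4)
        geom = LabeledGeometry(("C", "C", "C", "C"), coords, masses)
        alf = ALFDefinition(x_axis=(1, 0, 1, 1), xy_plane=(2, 2, 0, 0))
        with pytest.raises(DegenerateFrameError):
            alf_rotation(geom, alf, 1)


class TestFeatures:
    def test_dimension_is_3n_minus_6(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        f = features(ring16.geometry, alf, 0)
        assert f.shape == (42,)

    def test_invariant_under_rigid_motion(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        moved = _rigidly_moved(ring16.geometry, 9)
        for a in (0, 5, 12):
            f0 = features(ring16.geometry, alf, a)
            f1 = features(moved, alf, a)
            assert np.abs(f0 - f1).max() < 1e-10

    def test_first_three_entries_are_alf_internal_coordinates(self, triatomic):
        g = build_bond_graph(triatomic.geometry)
        alf = assign_alf(g, triatomic.geometry.elements)
        geom = triatomic.geometry
        f = features(geom, alf, 0)
        rx = np.linalg.norm(geom.coords[alf.x_axis[0]] - geom.coords[0])
        assert np.isclose(f[0], rx)
        assert np.isclose(np.degrees(f[2]), 104.5, atol=1e-8)

    def test_feature_matrix_stacks_conformers(self, triatomic, triatomic_modes):
        g = build_bond_graph(triatomic.geometry)
        alf = assign_alf(g, triatomic.geometry.elements)
        ens = kf.generate(triatomic.geometry, triatomic_modes,
                          kf.SamplerConfig(n_samples=4, seed=0))
        X = feature_matrix(ens, alf, 0)
        assert X.shape == (4, 3)
        assert np.allclose(X[2], features(ens[2], alf, 0))


class TestMomentRotation:
    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=25)
        c = _random_rotation(5)
        back = rotate_multipoles(rotate_multipoles(q, c), c.T)
        assert np.abs(back - q).max() < 1e-10

    def test_monopole_is_invariant(self):
        q = np.zeros(25)
        q[0] = -0.73
        out = rotate_multipoles(q, _random_rotation(6))
        assert np.isclose(out[0], -0.73)
        assert np.abs(out[1:]).max() < 1e-12

    def test_dipole_transforms_as_a_vector(self):
        q = np.zeros(25)
        d_zxy = np.array([0.3, -0.2, 0.9])  # (Q10, Q11c, Q11s) = (z, x, y)
        q[1:4] = d_zxy
        c = _random_rotation(8)
        out = rotate_multipoles(q, c)
        vec_xyz = np.array([d_zxy[1], d_zxy[2], d_zxy[0]])
        rotated = c @ vec_xyz
        assert np.allclose(out[1:4], [rotated[2], rotated[0], rotated[1]],
                           atol=1e-10)

    def test_set_round_trip_through_frames(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        rng = np.random.default_rng(10)
        ms = MultipoleSet(rng.normal(size=(16, 25)), frame="ALF")
        glob = rotate_multipole_set(ms, ring16.geometry, alf, "global")
        assert glob.frame == "global"
        back = rotate_multipole_set(glob, ring16.geometry, alf, "ALF")
        assert np.abs(back.values - ms.values).max() < 1e-10

    def test_noop_when_already_in_frame(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        ms = MultipoleSet(np.zeros((16, 25)), frame="ALF")
        assert rotate_multipole_set(ms, ring16.geometry, alf, "ALF") is ms

    def test_unknown_frame_rejected(self, ring16):
        g = build_bond_graph(ring16.geometry)
        alf = assign_alf(g, ring16.geometry.elements)
        ms = MultipoleSet(np.zeros((16, 25)), frame="ALF")
        with pytest.raises(ValueError):
            rotate_multipole_set(ms, ring16.geometry, alf, "lab")
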