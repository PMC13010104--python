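"""Structure construction, mass distribution and stiffness assembly."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from trunksim.config import RunConfig
from trunksim.trunk_model import (ConfigError, Rod, assemble_global,
                                  build_structure, distribute_mass,
                                  frustum_volume, globalize_stiffness,
                                  local_stiffness_matrix, rod_rotation_matrix)


class TestBuildStructure:
    def test_default_structure_sizes(self, default_structure):
        s = default_structure
        assert s.n_nodes == 50
        assert s.n_sections == 10
        assert s.n_segments == 9
        assert s.n_dof == 150

    def test_default_segment_rest_length(self, default_structure):
        centers = [nd.rest_position for nd in default_structure.nodes
                   if nd.role == "O"]
        lengths = [np.linalg.norm(b - a) for a, b in zip(centers, centers[1:])]
        assert np.allclose(lengths, 1.85 / 9)
        assert lengths[0] == pytest.approx(0.2, abs=0.01)

    def test_masses_sum_to_total(self, default_structure):
        assert sum(nd.mass for nd in default_structure.nodes) == pytest.approx(
            100.0, rel=1e-12)

    def test_five_nodes_per_section_one_center(self, default_structure):
        for sec in range(1, 11):
            roles = [nd.role for nd in default_structure.nodes
                     if nd.section_index == sec]
            assert sorted(roles) == sorted(["O", "P", "B", "Q", "A"])

    def test_test_scale_structure(self, toy_structure):
        assert toy_structure.n_nodes == 15
        assert toy_structure.n_dof == 45
        assert toy_structure.n_segments == 2

    def test_base_section_fixed(self, default_structure):
        assert default_structure.fixed_nodes == frozenset(range(5))

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            RunConfig(total_mass=-5.0)
        with pytest.raises(Exception):
            RunConfig(youngs_modulus={"proximal": -1.0})

    def test_reproducible_build(self):
        a = build_structure()
        b = build_structure()
        assert np.array_equal(a.rest_positions(), b.rest_positions())
        assert np.array_equal(a.masses(), b.masses())
        assert [r.rest_length for r in a.rods] == [r.rest_length for r in b.rods]

    def test_rod_topology(self, default_structure):
        s = default_structure
        by_type = {}
        for rod in s.rods:
            by_type.setdefault(rod.rod_type, []).append(rod)
        assert len(by_type["radial"]) == 40
        # 40 in-section perimeter rods + 72 inter-section web diagonals
        assert len(by_type["connective"]) == 40 + 72
        assert len(by_type["longitudinal"]) == 36
        sec_of = {nd.node_id: nd.section_index for nd in s.nodes}
        role_of = {nd.node_id: nd.role for nd in s.nodes}
        for rod in by_type["longitudinal"]:
            i, j = rod.endpoints
            assert role_of[i] == role_of[j] != "O"
            assert sec_of[j] == sec_of[i] + 1
        for rod in by_type["radial"]:
            i, j = rod.endpoints
            assert role_of[i] == "O" and role_of[j] != "O"
            assert sec_of[i] == sec_of[j]


class TestDistributeMass:
    def test_cylinder_gives_equal_masses(self):
        m = distribute_mass(50.0, np.full(11, 0.1), 0.2)
        assert np.allclose(m, 1.0)

    def test_taper_concentrates_mass_proximally(self):
        radii = np.linspace(0.15, 0.05, 11)
        m = distribute_mass(100.0, radii, 0.185)
        assert m.sum() == pytest.approx(100.0, rel=1e-12)
        sections = m.reshape(10, 5).sum(axis=1)
        assert sections[0] > sections[-1]
        assert np.all(np.diff(sections) < 0)

    def test_matches_quadrature_oracle(self):
        radii = np.array([0.2, 0.17, 0.16, 0.12, 0.11, 0.08, 0.075, 0.06,
                          0.055, 0.051, 0.05])
        h = 0.185
        m = distribute_mass(80.0, radii, h).reshape(10, 5).sum(axis=1)
        vols = []
        for r1, r2 in zip(radii[:-1], radii[1:]):
            v, _ = quad(lambda z: np.pi * (r1 + (r2 - r1) * z / h) ** 2, 0, h)
            vols.append(v)
        expected = 80.0 * np.array(vols) / np.sum(vols)
        assert np.allclose(m, expected, rtol=1e-6)

    def test_non_monotone_radii_warn(self):
        with pytest.warns(UserWarning):
            distribute_mass(10.0, np.array([0.1, 0.12, 0.1]), 0.2)

    def test_non_positive_inputs_error(self):
        with pytest.raises(ConfigError):
            distribute_mass(10.0, np.array([0.1, -0.1, 0.1]), 0.2)
        with pytest.raises(ConfigError):
            distribute_mass(-1.0, np.full(3, 0.1), 0.2)


class TestElementMatrices:
    def test_local_stiffness_eigenstructure(self):
        K = local_stiffness_matrix(1000.0)
        assert np.allclose(K, K.T)
        w = np.sort(np.linalg.eigvalsh(K))
        assert np.allclose(w[:5], 0.0, atol=1e-9)
        assert w[5] == pytest.approx(2000.0)

    def test_local_stiffness_rigid_translation_equilibrium(self):
        K = local_stiffness_matrix(123.0)
        rigid = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        assert np.allclose(K @ rigid, 0.0)

    def test_local_stiffness_rejects_nonpositive(self):
        with pytest.raises(ConfigError):
            local_stiffness_matrix(0.0)

    @staticmethod
    def _rod(p0, p1):
        return Rod(0, (0, 1), "longitudinal",
                   float(np.linalg.norm(np.array(p1) - np.array(p0))),
                   1e6, 1e-3, 1, "P"), np.array([p0, p1], float)

    def test_rotation_along_x_is_identity_blocks(self):
        rod, pos = self._rod([0, 0, 0], [2, 0, 0])
        R = rod_rotation_matrix(rod, pos)
        assert np.allclose(R[:3, 0], [1, 0, 0])
        assert np.allclose(R.T @ R, np.eye(6), atol=1e-12)

    def test_rotation_along_y(self):
        rod, pos = self._rod([0, 0, 0], [0, 1, 0])
        R = rod_rotation_matrix(rod, pos)
        assert np.allclose(R[0, :3], [0, 1, 0])

    def test_rotation_orthonormal_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = rng.normal(size=3)
            rod, pos = self._rod([0, 0, 0], d)
            R = rod_rotation_matrix(rod, pos)
            assert np.linalg.norm(R.T @ R - np.eye(6)) < 1e-12

    def test_zero_length_rod_errors(self):
        rod, pos = self._rod([0, 0, 0], [1, 0, 0])
        pos[1] = pos[0]
        with pytest.raises(ConfigError):
            rod_rotation_matrix(rod, pos)

    def test_globalize_identity(self):
        K = local_stiffness_matrix(100.0)
        assert np.allclose(globalize_stiffness(K, np.eye(6)), K)

    def test_globalize_rod_along_y_couples_y_only(self):
        rod, pos = self._rod([0, 0, 0], [0, 1, 0])
        Kg = globalize_stiffness(local_stiffness_matrix(100.0),
                                 rod_rotation_matrix(rod, pos))
        k = rod.axial_stiffness
        expected = np.zeros((6, 6))
        expected[1, 1] = expected[4, 4] = 100.0
        expected[1, 4] = expected[4, 1] = -100.0
        assert np.allclose(Kg, expected, atol=1e-12)

    def test_globalize_preserves_eigenvalues(self):
        rng = np.random.default_rng(3)
        K = local_stiffness_matrix(543.2)
        for _ in range(10):
            block = Rotation.random(rng=rng).as_matrix()
            R = np.zeros((6, 6))
            R[:3, :3] = R[3:, 3:] = block
            Kg = globalize_stiffness(K, R)
            assert np.allclose(np.sort(np.linalg.eigvalsh(Kg)),
                               np.sort(np.linalg.eigvalsh(K)), atol=1e-9)


class TestAssembly:
    def test_global_sizes(self, default_structure):
        K, M = assemble_global(default_structure)
        assert K.shape == (150, 150)
        assert M.shape == (150, 150)
        assert np.allclose(M, np.diag(np.diag(M)))
        assert np.allclose(np.diag(M), np.repeat(default_structure.masses(), 3))

    def test_symmetric_psd_with_translation_nullspace(self, default_structure):
        K, _ = assemble_global(default_structure)
        assert np.allclose(K, K.T, atol=1e-9)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-8 * w.max()
        for d in range(3):
            v = np.zeros(150)
            v[d::3] = 1.0
            assert np.abs(K @ v).max() < 1e-8

    def test_single_rod_assembly_equals_element(self):
        from tests.conftest import make_spring_structure

        s = make_spring_structure(k=200.0)
        K, M = assemble_global(s)
        rod = s.rods[0]
        Ke = globalize_stiffness(local_stiffness_matrix(rod.axial_stiffness),
                                 rod_rotation_matrix(rod, s.rest_positions()))
        assert np.allclose(K, Ke)

    def test_two_rod_chain_matches_hand_assembly(self):
        """Collinear 3-node chain against an independently built 9x9 matrix."""
        from trunksim.trunk_model import NodePointMass, TrunkStructure

        k1, k2 = 150.0, 75.0
        nodes = [NodePointMass(i, i + 1, "O", 1.0, np.array([float(i), 0, 0]))
                 for i in range(3)]
        rods = [Rod(0, (0, 1), "longitudinal", 1.0, k1, 1.0, 1, "O"),
                Rod(1, (1, 2), "longitudinal", 1.0, k2, 1.0, 2, "O")]
        s = TrunkStructure(nodes=nodes, rods=rods, fixed_nodes=frozenset(),
                           total_mass=3.0, total_length=2.0, n_sections=3)
        K, _ = assemble_global(s)
        expected = np.zeros((9, 9))
        for (i, j, k) in ((0, 3, k1), (3, 6, k2)):  # x DoFs of the two rods
            expected[i, i] += k
            expected[j, j] += k
            expected[i, j] -= k
            expected[j, i] -= k
        assert np.allclose(K, expected, atol=1e-9)

    def test_assembly_linearity_in_stiffness(self, toy_config):
        s1 = build_structure(toy_config)
        s2 = build_structure(toy_config, youngs_modulus={
            "proximal": 2e6, "middle": 2e6, "distal": 2e6})
        K1, _ = assemble_global(s1)
        K2, _ = assemble_global(s2)
        assert np.allclose(K2, 2.0 * K1, atol=1e-9 * np.abs(K1).max())

    def test_serialization_round_trip(self, toy_structure, tmp_path):
        p = tmp_path / "structure.json"
        toy_structure.to_json(p)
        from trunksim.trunk_model import TrunkStructure

        back = TrunkStructure.from_json(p)
        assert np.array_equal(back.rest_positions(), toy_structure.rest_positions())
        assert back.fixed_nodes == toy_structure.fixed_nodes
        assert [r.axial_stiffness for r in back.rods] == [
            r.axial_stiffness for r in toy_structure.rods]


def test_frustum_volume_closed_form():
    # cylinder and cone limits
    assert frustum_volume(0.1, 0.1, 1.0) == pytest.approx(np.pi * 0.01)
    assert frustum_volume(0.3, 0.0, 0.9) == pytest.approx(np.pi * 0.09 * 0.3)
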