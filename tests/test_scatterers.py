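"""Sphere polarizability, coupled-dipole tensors, rotations, orientations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from mpsim import (AtomicStructure, Orientation, PolarizabilityTensor,
                   SphereScatterer, coupled_dipole_tensor, effective_response,
                   read_pdb, rotate_tensor, sample_orientation,
                   sphere_polarizability, tensor_from_structure)
from mpsim.scatterers import (ATOMIC_POLARIZABILITY_A3, ConditioningError,
                              ParameterTableError)


class TestSphere:
    def test_index_matched_sphere_vanishes(self):
        s = SphereScatterer(radius=5e-9, n_particle=1.333, n_medium=1.333)
        assert sphere_polarizability(s) == 0.0

    def test_volume_scaling(self):
        a1 = sphere_polarizability(SphereScatterer(radius=3e-9))
        a2 = sphere_polarizability(SphereScatterer(radius=6e-9))
        assert a2 / a1 == pytest.approx(8.0, rel=1e-12)

    def test_clausius_mossotti_value(self, hsp_sphere):
        v = 4 / 3 * np.pi * 5.6**3 * 1e3  # Å^3 (5.6 nm radius)
        expected = 3 * v * (1.480**2 - 1.333**2) / (1.480**2 + 2 * 1.333**2)
        assert sphere_polarizability(hsp_sphere) == pytest.approx(expected, rel=1e-12)

    def test_rayleigh_validity_flag(self):
        assert SphereScatterer(radius=5e-9, wavelength=445e-9).rayleigh_valid
        assert not SphereScatterer(radius=80e-9, wavelength=445e-9).rayleigh_valid

    def test_rejects_nonphysical(self):
        with pytest.raises(ValueError):
            SphereScatterer(radius=-1e-9)


class TestCoupledDipole:
    def test_single_atom_is_isotropic(self):
        t = coupled_dipole_tensor(np.zeros((1, 3)), np.array([1.7]))
        assert np.allclose(t, 1.7 * np.eye(3))

    def test_two_atom_against_explicit_6x6_solve(self):
        d, a = 3.0, 1.5
        coords = np.array([[0, 0, 0], [0, 0, d]], float)
        t = coupled_dipole_tensor(coords, np.array([a, a]))
        # brute force: A p = E with T = (3 rr - I)/d^3
        big = np.zeros((6, 6))
        big[:3, :3] = big[3:, 3:] = np.eye(3) / a
        tij = (3 * np.outer([0, 0, 1], [0, 0, 1]) - np.eye(3)) / d**3
        big[:3, 3:] = big[3:, :3] = -tij
        expected = np.zeros((3, 3))
        for k in range(3):
            e = np.zeros(6)
            e[k] = e[3 + k] = 1.0
            p = np.linalg.solve(big, e)
            expected[:, k] = p[:3] + p[3:]
        assert np.allclose(t, expected, atol=1e-12)
        # zz enhanced, xx/yy reduced relative to non-interacting atoms
        assert t[2, 2] > 2 * a > t[0, 0]

    def test_reduces_to_sum_at_large_separation(self):
        coords = np.array([[0, 0, 0], [0, 0, 1e6]], float)
        t = coupled_dipole_tensor(coords, np.array([1.2, 2.3]))
        assert np.allclose(t, 3.5 * np.eye(3), atol=1e-9)

    def test_equivariance_under_rigid_rotation(self, rng):
        coords = rng.uniform(-4, 4, (12, 3))
        elements = np.array(["C"] * 12, dtype=object)
        s = AtomicStructure(elements=elements, coords=coords)
        t = tensor_from_structure(s)
        o = Orientation(0.3, -0.8, 1.1)
        r = o.matrix
        s_rot = AtomicStructure(elements=elements, coords=coords @ r.T)
        t_rot = tensor_from_structure(s_rot)
        expected = r @ t.matrix @ r.T
        assert np.abs(t_rot.matrix - expected).max() / np.abs(expected).max() < 1e-8

    def test_adding_an_atom_increases_mean_polarizability(self, rng):
        for _ in range(5):
            coords = rng.uniform(0, 6, (8, 3))
            # enforce the pairwise floor
            while True:
                d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
                bad = np.argwhere((d < 2.0) & (d > 0))
                if not len(bad):
                    break
                coords[bad[0][0]] += 0.7
            base = coupled_dipole_tensor(coords[:-1], np.full(7, 1.5))
            bigger = coupled_dipole_tensor(coords, np.full(8, 1.5))
            assert np.trace(bigger) / 3 > np.trace(base) / 3

    def test_mean_alpha_tracks_mass_on_synthetic_clouds(self, rng):
        masses, means = [], []
        for n in (10, 20, 40, 80, 150):
            coords = rng.uniform(0, 3.0 * n ** (1 / 3), (n, 3)) * 1.8
            elements = np.array(rng.choice(["C", "N", "O"], n), dtype=object)
            s = AtomicStructure(elements=elements, coords=coords)
            try:
                t = tensor_from_structure(s)
            except ConditioningError:
                continue
            masses.append(s.mass_kda)
            means.append(t.mean)
        r = np.corrcoef(masses, means)[0, 1]
        assert r > 0.99

    def test_distance_floor_raises(self):
        s = AtomicStructure(elements=np.array(["C", "C"], dtype=object),
                            coords=np.array([[0, 0, 0], [0, 0, 0.3]]))
        with pytest.raises(ConditioningError):
            tensor_from_structure(s)

    def test_unknown_element_raises(self):
        s = AtomicStructure(elements=np.array(["Xx"], dtype=object),
                            coords=np.zeros((1, 3)))
        with pytest.raises(ParameterTableError):
            tensor_from_structure(s)

    def test_coarse_graining_close_to_all_atom(self):
        # two "residues" of 8 atoms on a 2.5 A lattice, 25 A apart
        cell = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                         for k in (0, 1)], float) * 2.5
        coords = np.vstack([cell, cell + [25.0, 0, 0]])
        elements = np.array(["C"] * 16, dtype=object)
        rid = np.array([0] * 8 + [1] * 8)
        s = AtomicStructure(elements=elements, coords=coords)
        t_all = tensor_from_structure(s)
        t_cg = tensor_from_structure(s, coarse_grain=True, residue_ids=rid)
        # coarse graining drops intra-residue coupling: close, not exact
        assert t_cg.mean == pytest.approx(t_all.mean, rel=0.2)


class TestRotations:
    def test_identity_orientation(self):
        t = PolarizabilityTensor(np.diag([1.0, 2.0, 3.0]))
        out = rotate_tensor(t, Orientation())
        assert np.allclose(out.matrix, t.matrix)

    def test_isotropic_tensor_invariant(self):
        t = PolarizabilityTensor(2.5 * np.eye(3))
        out = rotate_tensor(t, Orientation(0.4, 1.2, -0.7))
        assert np.allclose(out.matrix, t.matrix, atol=1e-12)

    def test_z90_permutes_principal_axes(self):
        t = PolarizabilityTensor(np.diag([1.0, 2.0, 3.0]))
        out = rotate_tensor(t, Orientation(theta_z=np.pi / 2))
        assert np.allclose(out.matrix, np.diag([2.0, 1.0, 3.0]), atol=1e-12)

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=30, deadline=None)
    def test_trace_invariant_under_any_rotation(self, tx, ty, tz):
        t = PolarizabilityTensor(np.diag([1.0, 2.0, 5.0]))
        out = rotate_tensor(t, Orientation(tx, ty, tz))
        assert np.trace(out.matrix) == pytest.approx(8.0, rel=1e-12)
        r = Orientation(tx, ty, tz).matrix
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0)


class TestOrientationSampling:
    def test_seeded_determinism(self):
        import numpy as np
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        a = [sample_orientation(r1) for _ in range(2)]
        b = [sample_orientation(r2) for _ in range(2)]
        assert a == b
        assert a[0] != a[1]

    def test_rotated_vector_mean_is_zero(self, rng):
        n = 20000
        v = np.array([0.0, 0.0, 1.0])
        out = np.array([sample_orientation(rng).matrix @ v for _ in range(n)])
        # each component: mean 0 with sd 1/sqrt(3n)
        assert np.all(np.abs(out.mean(axis=0)) < 3.0 / np.sqrt(3 * n))

    def test_rotation_angle_density(self, rng):
        # uniform SO(3): angle density (1 - cos t)/pi on [0, pi]
        n = 20000
        angles = np.empty(n)
        for i in range(n):
            m = sample_orientation(rng).matrix
            angles[i] = np.arccos(np.clip((np.trace(m) - 1) / 2, -1, 1))
        cdf = lambda t: (t - np.sin(t)) / np.pi
        stat, pval = kstest(angles, cdf)
        assert pval > 1e-3


class TestEffectiveResponse:
    def test_isotropic_tensor_polarization_independent(self):
        t = PolarizabilityTensor(4.0 * np.eye(3))
        o = Orientation(0.5, 0.2, -1.0)
        assert effective_response(t, "circular") == pytest.approx(4.0)
        assert effective_response(t, 0.73, orientation=o) == pytest.approx(4.0)

    def test_anisotropic_linear_depends_on_alignment(self):
        t = PolarizabilityTensor(np.diag([2.0, 1.0, 1.0]))
        aligned = effective_response(t, 0.0)
        misaligned = effective_response(t, np.pi / 2)
        assert aligned == pytest.approx(2.0)
        assert misaligned == pytest.approx(1.0)

    def test_circular_averages_in_plane(self):
        t = PolarizabilityTensor(np.diag([2.0, 1.0, 5.0]))
        assert effective_response(t, "circular") == pytest.approx(1.5)

    def test_scalar_passthrough(self):
        assert effective_response(123.0, "circular") == 123.0


_SYNTHETIC_PDB = """\
HEADER    SYNTHETIC TEST MOLECULE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.250   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.320   1.540   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.950   2.860   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.470   2.750   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.050   1.660   0.000  1.00  0.00           O
END
"""


class TestPdbReading:
    def test_synthetic_pdb_roundtrip(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(_SYNTHETIC_PDB)
        structure, residue_ids = read_pdb(p, source_id="toy")
        assert len(structure.coords) == 9
        assert list(structure.elements[:2]) == ["N", "C"]
        assert len(np.unique(residue_ids)) == 2
        # mass counts only the atoms present (no hydrogen imputation)
        expected = 2 * 14.007 + 5 * 12.011 + 2 * 15.999
        assert structure.mass_kda == pytest.approx(expected / 1000, rel=1e-6)
        t = tensor_from_structure(structure)
        assert t.mean > 0
        assert np.allclose(t.matrix, t.matrix.T)

    def test_parameter_table_has_protein_elements(self):
        for el in ("H", "C", "N", "O", "S", "P"):
            assert el in ATOMIC_POLARIZABILITY_A3
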