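"""Elastic network Hessians, modes, derived profiles and RMSIP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cadyn import (CalphaStructure, ForceField, build_hessian,
                   cross_correlation, deformation_energy,
                   deformation_of_displacement, fluctuations, ideal_helix,
                   normal_modes, progressive_msa, rmsip, rmsip_matrix)


def two_residue_system(d=3.8):
    return CalphaStructure("pair", [1, 2], "AA",
                           np.array([[0, 0, 0], [d, 0, 0.0]]))


class TestHessian:
    def test_two_residue_analytic_spectrum(self):
        """One spring k at distance d: single non-zero eigenvalue 2k along
        the pair axis (6×6 case solvable by hand)."""
        d = 3.8
        s = two_residue_system(d)
        k = ForceField().spring_constants(np.array([d]))[0]
        assert k == pytest.approx(8.6e2 * d - 2.39e3)
        h = build_hessian(s)
        evals, evecs = np.linalg.eigh(h)
        assert np.sum(evals > 1e-8) == 1
        assert evals[-1] == pytest.approx(2 * k, rel=1e-10)
        mode = evecs[:, -1].reshape(2, 3)
        # displacement along the pair axis (x), antisymmetric
        assert abs(mode[0, 0]) == pytest.approx(1 / np.sqrt(2), rel=1e-9)
        np.testing.assert_allclose(mode[:, 1:], 0.0, atol=1e-9)

    def test_super_row_sums_zero(self, bundle):
        h = build_hessian(bundle)
        n = len(bundle)
        rows = h.reshape(n, 3, n, 3).sum(axis=2)
        assert np.abs(rows).max() < 1e-10
        np.testing.assert_allclose(h, h.T, atol=1e-12)

    def test_collinear_chain_is_floppy(self, caplog):
        """Nearest-neighbour springs on a line leave transverse zero modes."""
        coords = np.outer(np.arange(3), [3.8, 0, 0])
        s = CalphaStructure("line", [1, 2, 3], "AAA", coords)
        h = build_hessian(s, ForceField(name="uniform-cutoff", cutoff=4.0))
        evals = np.linalg.eigvalsh(h)
        assert np.sum(np.abs(evals) < 1e-8) > 6
        with caplog.at_level("WARNING"):
            m = normal_modes(h)
        assert m.n_trivial_removed > 6
        assert "rigid-body" in caplog.text

    def test_disconnected_network_named(self):
        coords = np.vstack([ideal_helix(5), ideal_helix(5) + [500, 0, 0]])
        s = CalphaStructure("far", list(range(1, 11)), "A" * 10, coords,
                            chain_breaks=[4])
        with pytest.raises(ValueError, match="disconnected.*\\[5, 6, 7, 8, 9\\]"):
            build_hessian(s, ForceField(name="uniform-cutoff", cutoff=15.0))


class TestNormalModes:
    def test_mode_count_3n_minus_6(self, bundle_modes, small_bundle):
        assert bundle_modes.n_modes == 3 * len(small_bundle) - 6
        assert bundle_modes.n_trivial_removed == 6

    def test_orthonormal_and_reconstructs(self, small_bundle, bundle_modes):
        v = bundle_modes.vectors
        gram = v.T @ v
        np.testing.assert_allclose(gram, np.eye(v.shape[1]), atol=1e-8)
        h = build_hessian(small_bundle)
        recon = v @ np.diag(bundle_modes.eigenvalues) @ v.T
        np.testing.assert_allclose(recon, h,
                                   atol=1e-8 * np.abs(h).max())

    def test_eigenvalues_ascending_positive(self, bundle_modes):
        assert np.all(np.diff(bundle_modes.eigenvalues) >= -1e-12)
        assert bundle_modes.eigenvalues[0] > 0


class TestFluctuations:
    def test_equals_pseudoinverse_oracle(self, small_bundle, bundle_modes):
        f = fluctuations(bundle_modes)
        h = build_hessian(small_bundle)
        pinv = np.linalg.pinv(h, rcond=1e-8)
        n = len(small_bundle)
        oracle = np.array([np.trace(pinv[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                           for i in range(n)])
        np.testing.assert_allclose(f, oracle, rtol=1e-6)

    def test_strictly_positive_and_end_effect(self):
        s = CalphaStructure("h20", list(range(1, 21)), "A" * 20,
                            ideal_helix(20))
        m = normal_modes(build_hessian(s))
        f = fluctuations(m)
        assert np.all(f > 0)
        assert f[0] > np.median(f[5:15]) and f[-1] > np.median(f[5:15])

    def test_empty_subset_rejected(self, bundle_modes):
        with pytest.raises(ValueError):
            fluctuations(bundle_modes, mode_subset=[])


class TestDeformation:
    def test_rigid_displacements_zero(self, small_bundle):
        n = len(small_bundle)
        translation = np.tile([1.0, -2.0, 0.5], (n, 1))
        assert deformation_of_displacement(small_bundle, translation).max() == 0
        # infinitesimal rotation field about the centroid
        c = small_bundle.coords - small_bundle.coords.mean(axis=0)
        rot_field = np.cross(np.tile([0.3, 0.1, -0.2], (n, 1)), c)
        d = deformation_of_displacement(small_bundle, rot_field)
        assert d.max() < 1e-9 * np.abs(rot_field).max()

    def test_two_residue_equal_split(self):
        s = two_residue_system()
        m = normal_modes(build_hessian(s))
        e = deformation_energy(m, s, normalize=False)
        assert e[0] == pytest.approx(e[1], rel=1e-12)
        assert e[0] > 0

    def test_hinge_concentrates_at_junction(self):
        """A two-helix hinge: junction residues deform most in soft modes."""
        from cadyn.synthetic import HingeEnsembleSpec, hinge_ensemble
        he = hinge_ensemble(HingeEnsembleSpec(20, 20, [0.0], noise_sigma=0.0,
                                              n_frames=2))
        s = he.structure
        m = normal_modes(build_hessian(s))
        e = deformation_energy(m, s, mode_subset=range(3), normalize=False)
        junction = e[18:22].mean()
        interior = np.r_[e[5:15], e[25:35]].mean()
        assert junction > interior

    def test_normalized_range(self, small_bundle, bundle_modes):
        e = deformation_energy(bundle_modes, small_bundle)
        assert e.min() == 0.0 and e.max() == 1.0


class TestCrossCorrelation:
    def test_diagonal_symmetry_range(self, bundle_modes):
        c = cross_correlation(bundle_modes)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        np.testing.assert_allclose(c, c.T, atol=1e-10)
        assert c.min() >= -1.0 and c.max() <= 1.0

    def test_matches_pseudoinverse_oracle(self, small_bundle, bundle_modes):
        h = build_hessian(small_bundle)
        pinv = np.linalg.pinv(h, rcond=1e-8)
        n = len(small_bundle)
        blocks = pinv.reshape(n, 3, n, 3)
        cov = np.einsum("iaja->ij", blocks.transpose(0, 1, 2, 3))
        cov = np.trace(blocks, axis1=1, axis2=3)
        d = np.sqrt(np.diag(cov))
        oracle = cov / np.outer(d, d)
        np.testing.assert_allclose(cross_correlation(bundle_modes), oracle,
                                   atol=1e-6)


class TestRmsip:
    def test_self_is_one(self, bundle_modes):
        assert rmsip(bundle_modes, bundle_modes, 10) == pytest.approx(1.0)

    def test_orthogonal_subspaces_zero(self, bundle_modes):
        from cadyn.enm import ModeSet
        n3 = bundle_modes.vectors.shape[0]
        a = ModeSet(eigenvalues=np.ones(10),
                    vectors=np.eye(n3)[:, :10],
                    n_trivial_removed=6, n_atoms=n3 // 3)
        b = ModeSet(eigenvalues=np.ones(10),
                    vectors=np.eye(n3)[:, 10:20],
                    n_trivial_removed=6, n_atoms=n3 // 3)
        assert rmsip(a, b, 10) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_subspace_mixing(self, bundle_modes):
        from cadyn.enm import ModeSet
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        mixed = bundle_modes.vectors[:, :10] @ q
        a = ModeSet(eigenvalues=bundle_modes.eigenvalues[:10].copy(),
                    vectors=mixed, n_trivial_removed=6,
                    n_atoms=bundle_modes.n_atoms)
        r = rmsip(a, bundle_modes, 10)
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_n_modes_overflow(self, bundle_modes):
        with pytest.raises(ValueError, match="exceeds"):
            rmsip(bundle_modes, bundle_modes, bundle_modes.n_modes + 1)

    def test_duplicate_structures_in_matrix(self, core_family):
        members, _ = core_family
        structs = [members[0], members[1], members[0]]
        # relabel the duplicate to keep labels unique
        from dataclasses import replace
        structs[2] = replace(members[0], label="dup")
        msa = progressive_msa(structs)
        modes = [normal_modes(build_hessian(s)) for s in structs]
        m = rmsip_matrix(modes, msa, n_modes=10)
        assert m.values[0, 2] >= 0.99
        assert np.all(np.diag(m.values) == 1.0)


class TestProfileInvariance:
    def test_profiles_invariant_under_rigid_motion(self, small_bundle):
        rot = Rotation.from_euler("zxz", [40, 30, 20], degrees=True).as_matrix()
        moved = small_bundle.transformed(rot, np.array([3.0, -7.0, 2.0]))
        m1 = normal_modes(build_hessian(small_bundle))
        m2 = normal_modes(build_hessian(moved))
        np.testing.assert_allclose(fluctuations(m1), fluctuations(m2),
                                   rtol=1e-6)
        np.testing.assert_allclose(
            deformation_energy(m1, small_bundle),
            deformation_energy(m2, moved), atol=1e-6)
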