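"""Structural alignment, identity/RMSD matrices, clustering, serialization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cadyn import (AlignmentError, CalphaStructure, SimilarityMatrix,
                   StructuralMSA, cluster_matrix, cut_k_clusters,
                   linkage_to_newick, pairwise_structure_align,
                   progressive_msa, rmsd_matrix, sequence_identity_matrix)


def rigid_copy(s, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    return s.transformed(rot, rng.uniform(-10, 10, 3))


class TestPairwiseAlign:
    def test_self_against_rigid_copy(self, bundle):
        pairs, rmsd, _ = pairwise_structure_align(bundle, rigid_copy(bundle))
        assert pairs == [(i, i) for i in range(len(bundle))]
        assert rmsd < 1e-6

    def test_loop_deletion_gaps_confined(self, bundle):
        """Deleting 5 linker residues: gaps stay near the deletion site."""
        # first linker sits between helices 0 and 1
        (h0s, h0e), (h1s, h1e) = bundle.helices[0], bundle.helices[1]
        cut = slice(h0e, h0e + 5)
        keep = np.r_[0:cut.start, cut.stop:len(bundle)]
        truncated = CalphaStructure(
            "trunc", [bundle.residue_ids[i] for i in keep],
            "".join(bundle.sequence[i] for i in keep), bundle.coords[keep])
        pairs, rmsd, _ = pairwise_structure_align(bundle, truncated)
        assert rmsd < 0.5
        mismatched = [(i, j) for i, j in pairs
                      if keep[j] != i]
        # any disagreement with the true mapping must hug the deletion
        for i, _ in mismatched:
            assert cut.start - 2 <= i <= cut.stop + 2

    def test_random_coils_fail_or_report_honest_rmsd(self):
        """Unrelated self-avoiding walks never get a spuriously low RMSD."""
        rng = np.random.default_rng(42)
        outcomes = []
        for trial in range(10):
            coils = []
            for _ in range(2):
                steps = rng.normal(size=(40, 3))
                steps = 3.8 * steps / np.linalg.norm(steps, axis=1)[:, None]
                coords = np.cumsum(steps, axis=0)
                coils.append(CalphaStructure(
                    "c", list(range(1, 41)), "A" * 40, coords))
            try:
                pairs, rmsd, _ = pairwise_structure_align(*coils)
                outcomes.append(rmsd)
            except AlignmentError:
                outcomes.append(None)
        reported = [r for r in outcomes if r is not None]
        # honest: no reported RMSD may pretend the coils are similar
        assert all(r > 1.5 for r in reported)

    def test_short_structures_rejected(self, bundle):
        short = CalphaStructure("s", list(range(1, 11)), "A" * 10,
                                bundle.coords[:10])
        with pytest.raises(ValueError, match="at least 20"):
            pairwise_structure_align(short, bundle)


class TestProgressiveMSA:
    def test_rigid_copies_full_occupancy(self, bundle):
        msa = progressive_msa([bundle, rigid_copy(bundle, 1),
                               rigid_copy(bundle, 2)])
        assert msa.n_columns == len(bundle)
        assert np.all(msa.occupancy == 1.0)

    def test_noisy_family_forced_correspondence(self, core_family):
        members, _ = core_family
        msa = progressive_msa(members[:6])
        assert len(msa.full_occupancy_columns()) >= 0.9 * msa.n_columns

    def test_row_monotonicity(self, two_families):
        members, _ = two_families
        msa = progressive_msa(members)
        for row in msa.columns:
            idx = row[row >= 0]
            assert np.all(np.diff(idx) > 0)

    def test_fasta_roundtrip(self, core_family):
        members, _ = core_family
        msa = progressive_msa(members[:4])
        back = StructuralMSA.from_fasta(msa.to_fasta(), members[:4])
        np.testing.assert_array_equal(back.columns, msa.columns)


def _msa_from_strings(rows, sequences=None):
    """Build an MSA directly from gapped strings (test helper)."""
    sequences = sequences or [r.replace("-", "") for r in rows]
    columns = []
    for gseq in rows:
        row, k = [], 0
        for ch in gseq:
            row.append(-1 if ch == "-" else k)
            k += ch != "-"
        columns.append(row)
    return StructuralMSA(labels=[f"s{i}" for i in range(len(rows))],
                         sequences=sequences, columns=np.array(columns))


class TestIdentityMatrix:
    def test_identical_sequences(self):
        m = sequence_identity_matrix(_msa_from_strings(["AAAA", "AAAA"]))
        assert m.values[0, 1] == 1.0

    def test_half_identity_without_gaps(self):
        m = sequence_identity_matrix(_msa_from_strings(["AAAA", "AATT"]))
        assert m.values[0, 1] == 0.5

    def test_gap_columns_count_in_length(self):
        # pairwise length = columns where at least one is non-gap (5);
        # 3 identical residues -> 0.6
        m = sequence_identity_matrix(_msa_from_strings(["AAA-A", "AAAC-"]))
        assert m.values[0, 1] == pytest.approx(3 / 5)

    def test_range_and_symmetry(self, two_families):
        members, _ = two_families
        m = sequence_identity_matrix(progressive_msa(members))
        assert np.allclose(m.values, m.values.T)
        assert m.values.min() >= 0 and m.values.max() <= 1
        assert np.all(np.diag(m.values) == 1.0)


class TestRmsdMatrix:
    def test_self_zero_and_symmetry(self, core_family):
        members, _ = core_family
        msa = progressive_msa(members[:5])
        m = rmsd_matrix(members[:5], msa)
        assert np.all(np.diag(m.values) == 0)
        assert np.allclose(m.values, m.values.T, atol=1e-9)

    def test_isotropic_noise_oracle(self, bundle):
        """Kabsch RMSD against the direct displacement computation."""
        rng = np.random.default_rng(9)
        sigma = 0.5
        disp = rng.normal(0, sigma, bundle.coords.shape)
        noisy = CalphaStructure("n", list(bundle.residue_ids), bundle.sequence,
                                bundle.coords + disp)
        plain = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
        msa = progressive_msa([bundle, noisy])
        fitted = rmsd_matrix([bundle, noisy], msa).values[0, 1]
        # the rigid fit removes at most 6 of 3N degrees of freedom
        assert fitted <= plain + 1e-9
        assert fitted >= plain * np.sqrt(1 - 8 / (3 * len(bundle)))

    def test_gap_columns_rejected(self):
        msa = _msa_from_strings(["AAA-A", "AAAAA"])
        structs = [CalphaStructure(f"s{i}", list(range(1, len(seq) + 1)), seq,
                                   np.outer(np.arange(len(seq)), [3.8, 0, 0]))
                   for i, seq in enumerate(msa.sequences)]
        with pytest.raises(ValueError, match="gaps"):
            rmsd_matrix(structs, msa, positions=np.arange(5))


class TestClustering:
    def test_planted_pairs_split_at_cut(self):
        labels = ["a1", "a2", "b1", "b2"]
        v = np.full((4, 4), 5.0)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.3
        np.fill_diagonal(v, 0.0)
        m = SimilarityMatrix(labels, v, kind="rmsd")
        _, flat = cluster_matrix(m, cut=3.0)
        assert flat[0] == flat[1] != flat[2] == flat[3]

    def test_zero_matrix_single_cluster(self):
        m = SimilarityMatrix(["a", "b", "c"], np.zeros((3, 3)), kind="rmsd")
        _, flat = cluster_matrix(m, cut=0.5)
        assert len(set(flat)) == 1

    def test_nonfinite_entry_named(self):
        v = np.zeros((3, 3))
        v[0, 2] = v[2, 0] = np.nan
        m = SimilarityMatrix.__new__(SimilarityMatrix)
        m.labels, m.values, m.kind, m.linkage = ["x", "y", "z"], v, "rmsd", None
        with pytest.raises(ValueError, match="x.*z"):
            cluster_matrix(m)

    def test_relabeling_permutes_leaves_only(self, two_families):
        members, truth = two_families
        msa = progressive_msa(members)
        m = rmsd_matrix(members, msa)
        cluster_matrix(m)
        cut = cut_k_clusters(m, 2)
        perm = [5, 0, 3, 1, 4, 2]
        m2 = SimilarityMatrix([m.labels[i] for i in perm],
                              m.values[np.ix_(perm, perm)], kind="rmsd")
        cluster_matrix(m2)
        cut2 = cut_k_clusters(m2, 2)
        same = [(cut[perm[i]] == cut[perm[j]]) == (cut2[i] == cut2[j])
                for i in range(6) for j in range(6)]
        assert all(same)

    def test_newick_contains_all_labels(self, two_families):
        members, _ = two_families
        msa = progressive_msa(members)
        m = rmsd_matrix(members, msa)
        cluster_matrix(m)
        nwk = linkage_to_newick(m.linkage, m.labels)
        assert nwk.endswith(";")
        for lab in m.labels:
            assert lab in nwk

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.4, 1.0]]),
                             kind="identity")
        with pytest.raises(ValueError, match="diagonal"):
            SimilarityMatrix(["a", "b"], np.array([[0.5, 0.2], [0.2, 0.5]]),
                             kind="identity")
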