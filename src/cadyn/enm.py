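"""Cα elastic network models and normal mode analysis.

The default force field is the distance-dependent Cα parameterization of
Hinsen and co-workers as implemented in the standard NMA toolchains:
pair distances are clamped below at 2.9 Å, pairs closer than 4 Å (in
practice the backbone-adjacent pairs at ~3.8 Å) get the linear constant
k(r) = 8.6·10²·r − 2.39·10³ and all other pairs the rapidly decaying
k(r) = 128·10⁴·r⁻⁶ (r in Å, k in arbitrary consistent units).  Masses
are unity: the network is a pure Cα bead model.

From the mode spectrum the module derives thermal fluctuations,
per-residue deformation energies, residue–residue cross-correlations and
the RMSIP mode-subspace similarity between structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .align import SimilarityMatrix, StructuralMSA, cluster_matrix
from .structures import CalphaStructure

logger = logging.getLogger(__name__)

_TRIVIAL_RATIO = 1e-6      # eigenvalue < ratio * max  -> rigid-body mode
_SPRING_DROP = 1e-6        # springs weaker than this are dropped for sparsity


@dataclass(frozen=True)
class ForceField:
    """Pairwise spring-constant rule for the elastic network."""

    name: str = "calpha"
    cutoff: float = 15.0       # used by the uniform-cutoff variant only

    def spring_constants(self, dist: np.ndarray) -> np.ndarray:
        """Spring constant for every pair distance (Å); 0 = no spring."""
        if self.name == "calpha":
            r = np.maximum(dist, 2.9)
            k = np.where(r < 4.0, 8.6e2 * r - 2.39e3, 128e4 * r ** -6.0)
            k[k < _SPRING_DROP] = 0.0
            return k
        if self.name == "uniform-cutoff":
            return (dist <= self.cutoff).astype(float)
        raise ValueError(f"unknown force field {self.name!r}")


@dataclass
class ModeSet:
    """Non-trivial normal modes of an ENM Hessian.

    ``eigenvalues`` ascend; ``vectors`` holds the orthonormal 3N mode
    shapes as columns.  ``amplitudes`` are the relative thermal scaling
    factors 1/sqrt(λ), normalized so the largest is 1.
    """

    eigenvalues: np.ndarray          # (M,)
    vectors: np.ndarray              # (3N, M)
    n_trivial_removed: int
    n_atoms: int
    amplitudes: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.amplitudes is None:
            a = 1.0 / np.sqrt(self.eigenvalues)
            self.amplitudes = a / a.max()

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode_shape(self, m: int) -> np.ndarray:
        """Mode m as an (N, 3) displacement field."""
        return self.vectors[:, m].reshape(self.n_atoms, 3)


def build_hessian(s: CalphaStructure, ff: ForceField | None = None) -> np.ndarray:
    """Anisotropic-network Hessian of 3×3 super-elements.

    Exactly translationally invariant by construction (every 3-row
    super-row sums to zero).  Raises if the spring network is
    disconnected, naming the components.
    """
    ff = ff or ForceField()
    x = np.asarray(s.coords, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 residues")
    diff = x[:, None, :] - x[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    k = ff.spring_constants(dist)
    np.fill_diagonal(k, 0.0)

    ncomp, labels = connected_components(csr_matrix(k > 0), directed=False)
    if ncomp > 1:
        groups = [[int(i) for i in np.nonzero(labels == c)[0]]
                  for c in range(ncomp)]
        raise ValueError(f"elastic network is disconnected: components {groups}")

    unit = diff / dist[..., None]
    blocks = -k[..., None, None] * np.einsum("ija,ijb->ijab", unit, unit)
    h = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    # diagonal super-blocks enforce the zero row-sum identity
    diag = -blocks.sum(axis=1)
    for i in range(n):
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] = diag[i]
    return (h + h.T) / 2.0


def normal_modes(h: np.ndarray) -> ModeSet:
    """Eigendecomposition with rigid-body modes removed.

    Modes with eigenvalue below 1e-6 × the largest are treated as trivial
    (translations/rotations).  Any count other than 6 signals chain
    breaks or a degenerate geometry and is warned about.
    """
    h = np.asarray(h, float)
    n3 = h.shape[0]
    if h.shape != (n3, n3) or n3 % 3:
        raise ValueError("Hessian must be 3N x 3N")
    evals, evecs = linalg.eigh(h)
    thresh = _TRIVIAL_RATIO * max(evals.max(), 1e-30)
    trivial = evals < thresh
    n_trivial = int(trivial.sum())
    if n_trivial != 6:
        logger.warning("expected 6 rigid-body modes, found %d "
                       "(chain break / degenerate geometry?)", n_trivial)
    keep = ~trivial
    return ModeSet(eigenvalues=evals[keep], vectors=evecs[:, keep],
                   n_trivial_removed=n_trivial, n_atoms=n3 // 3)


def _subset(m: ModeSet, mode_subset) -> np.ndarray:
    if mode_subset is None:
        idx = np.arange(m.n_modes)
    else:
        idx = np.asarray(mode_subset, int)
        if idx.size == 0:
            raise ValueError("mode subset must not be empty")
        if idx.min() < 0 or idx.max() >= m.n_modes:
            raise IndexError("mode subset out of range")
    return idx


def fluctuations(m: ModeSet, mode_subset=None, normalize: bool = False) -> np.ndarray:
    """Per-residue mean-square fluctuation: Σ_modes ‖v_i‖² / λ.

    With all modes this equals the 3×3-block traces of the Hessian
    pseudoinverse.  ``normalize`` rescales to [0, 1] (min-max).
    """
    idx = _subset(m, mode_subset)
    v = m.vectors[:, idx].reshape(m.n_atoms, 3, len(idx))
    f = np.einsum("iam,iam,m->i", v, v, 1.0 / m.eigenvalues[idx])
    if normalize:
        f = _minmax(f)
    return f


def _minmax(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span <= 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def _spring_list(s: CalphaStructure, ff: ForceField):
    x = s.coords
    diff = x[:, None, :] - x[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    k = ff.spring_constants(dist)
    np.fill_diagonal(k, 0.0)
    i, j = np.nonzero(np.triu(k, 1) > 0)
    unit = diff[i, j] / dist[i, j][:, None]
    return i, j, k[i, j], unit


def deformation_of_displacement(s: CalphaStructure, disp: np.ndarray,
                                ff: ForceField | None = None) -> np.ndarray:
    """Per-residue spring-stretching energy of one displacement field.

    Each spring's harmonic energy ½ k (Δlength)² is split equally between
    its two endpoints.  Rigid-body displacements stretch no spring and
    give identically zero.
    """
    ff = ff or ForceField()
    disp = np.asarray(disp, float).reshape(len(s), 3)
    i, j, k, unit = _spring_list(s, ff)
    dl = np.einsum("pa,pa->p", disp[i] - disp[j], unit)
    e = 0.5 * k * dl ** 2
    out = np.zeros(len(s))
    np.add.at(out, i, 0.5 * e)
    np.add.at(out, j, 0.5 * e)
    return out


def deformation_energy(m: ModeSet, s: CalphaStructure,
                       ff: ForceField | None = None, mode_subset=None,
                       normalize: bool = True) -> np.ndarray:
    """Per-residue deformation energy averaged over modes.

    Each mode is taken at its thermal amplitude (displacement ∝ 1/sqrt λ),
    so softer modes contribute more, then the per-residue energies are
    averaged and (by default) min-max normalized.  The absolute scale is
    meaningless; only the profile shape carries information.
    """
    ff = ff or ForceField()
    if 3 * len(s) != m.vectors.shape[0]:
        raise ValueError("structure and mode set sizes disagree")
    idx = _subset(m, mode_subset)
    i, j, k, unit = _spring_list(s, ff)
    out = np.zeros(len(s))
    for mm in idx:
        v = m.mode_shape(mm) * m.amplitudes[mm]
        dl = np.einsum("pa,pa->p", v[i] - v[j], unit)
        e = 0.5 * k * dl ** 2
        np.add.at(out, i, 0.5 * e)
        np.add.at(out, j, 0.5 * e)
    out /= len(idx)
    if normalize:
        out = _minmax(out)
    return out


def cross_correlation(m: ModeSet, mode_subset=None) -> np.ndarray:
    """Normalized residue–residue cross-correlation matrix in [−1, 1].

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩) with the covariance built
    from the 1/λ-weighted mode sum (all non-trivial modes by default).
    """
    idx = _subset(m, mode_subset)
    v = m.vectors[:, idx].reshape(m.n_atoms, 3, len(idx))
    cov = np.einsum("iam,jam,m->ij", v, v, 1.0 / m.eigenvalues[idx])
    d = np.sqrt(np.diag(cov))
    c = cov / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def rmsip(a: ModeSet, b: ModeSet, n_modes: int = 10,
          mapping: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Root-mean-square inner product of the two lowest mode subspaces.

    ``mapping`` is a pair of residue-index arrays selecting equivalent
    residues in a and b; mode vectors are restricted to those residues
    and re-normalized to unit length (orthogonality is not re-imposed).
    1 = identical subspaces, 0 = orthogonal.
    """
    if n_modes > min(a.n_modes, b.n_modes):
        raise ValueError(f"n_modes={n_modes} exceeds available modes")
    if mapping is None:
        if a.n_atoms != b.n_atoms:
            raise ValueError("mode sets differ in size; a mapping is required")
        ia = ib = np.arange(a.n_atoms)
    else:
        ia, ib = (np.asarray(m, int) for m in mapping)
    if len(ia) < 3:
        raise ValueError("mapping must cover at least 3 residues")

    def restrict(ms: ModeSet, ridx) -> np.ndarray:
        v = ms.vectors[:, :n_modes].reshape(ms.n_atoms, 3, n_modes)
        sub = v[ridx].reshape(3 * len(ridx), n_modes)
        norms = np.linalg.norm(sub, axis=0)
        norms[norms == 0] = 1.0
        return sub / norms

    u, w = restrict(a, ia), restrict(b, ib)
    ip = u.T @ w
    return float(np.sqrt(np.sum(ip ** 2) / n_modes))


def rmsip_matrix(mode_sets: list[ModeSet], msa: StructuralMSA,
                 n_modes: int = 10, linkage_method: str = "complete") -> SimilarityMatrix:
    """All-pairs RMSIP over the 100%-occupancy MSA columns, clustered."""
    cols = msa.full_occupancy_columns()
    if len(cols) < 3:
        raise ValueError("fewer than 3 fully occupied columns")
    n = len(mode_sets)
    if n != msa.n_structures:
        raise ValueError("one mode set per aligned structure required")
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = rmsip(
                mode_sets[i], mode_sets[j], n_modes=n_modes,
                mapping=(msa.columns[i, cols], msa.columns[j, cols]))
    m = SimilarityMatrix(labels=list(msa.labels), values=vals, kind="rmsip")
    cluster_matrix(m, method=linkage_method)
    return m
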