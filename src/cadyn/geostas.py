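"""Dynamic-domain detection from mode-generated ensembles.

The atomic movement similarity matrix (AMSM) compares the across-frame
trajectory of every residue pair after allowing a best-fit rotation
between the two trajectories.  Residues that co-rotate therefore score
as co-moving even when their displacement vectors point in opposite
directions — the property that distinguishes this analysis from plain
cross-correlation, which detects common translation only.  Domains are
extracted by k-medoids clustering of 1 − AMSM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enm import ModeSet
from .structures import CalphaStructure

logger = logging.getLogger(__name__)

_MOTIONLESS = 1e-8


def mode_ensemble(s: CalphaStructure, m: ModeSet, n_modes: int = 5,
                  n_frames_per_mode: int = 8, amplitude: float = 2.0) -> np.ndarray:
    """Deterministic frames sampling sinusoidal motion along the lowest modes.

    For each of the ``n_modes`` lowest non-trivial modes, frames displace
    the structure by A_m · sin(2πt/F) · v_m with A_m ∝ 1/sqrt(λ_m);
    ``amplitude`` is the displacement (Å, per-mode vector norm) given to
    the softest mode.  Phases sum to zero so the frame average equals the
    input structure exactly.
    """
    if n_modes > m.n_modes:
        raise ValueError("n_modes exceeds available non-trivial modes")
    if n_frames_per_mode < 4:
        raise ValueError("need at least 4 frames per mode")
    x = s.coords
    amps = amplitude * np.sqrt(m.eigenvalues[0] / m.eigenvalues[:n_modes])
    phases = np.sin(2 * np.pi * np.arange(n_frames_per_mode) / n_frames_per_mode)
    frames = np.empty((n_modes * n_frames_per_mode, len(s), 3))
    for j in range(n_modes):
        shape = m.mode_shape(j)
        for t, ph in enumerate(phases):
            frames[j * n_frames_per_mode + t] = x + amps[j] * ph * shape
    return frames


@dataclass
class AMSM:
    """Atomic movement similarity matrix over an ensemble of frames."""

    values: np.ndarray           # (N, N) in [0, 1], diagonal 1
    labels: np.ndarray           # residue indices
    source: dict

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("AMSM must be symmetric")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("AMSM entries must lie in [0, 1]")


_SIGMA_SHAPE = 0.5


def _best_rotation_trace(ta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    """max_R tr(R · T_j^T T_i) for every trajectory pair, proper rotations."""
    cross = np.einsum("nfa,mfb->nmab", ta, tb)
    u, sv, vt = np.linalg.svd(cross)
    sign = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    return sv[..., 0] + sv[..., 1] + sign * sv[..., 2]


def amsm(frames: np.ndarray, source: dict | None = None) -> AMSM:
    """Trajectory similarity for every residue pair, rotations allowed.

    Each residue's across-frame trajectory is centred.  Two residues are
    co-moving when either of two rotation-fit criteria holds, and the
    similarity is the larger of the two mappings:

    * absolute: the residual RMSD after the best proper rotation of
      trajectory j onto trajectory i, mapped through exp(−RMSD/σ) with σ
      the median RMS trajectory displacement — this groups residues that
      move in lockstep *and* residues that share quiescence;
    * shape: the same residual after normalizing both trajectories to
      unit size, mapped through exp(−d/σ_shape) — this groups residues
      that co-rotate about a common axis at different radii, which pure
      magnitude comparison (and plain cross-correlation) misses.

    Pairs where both residues are motionless are defined as perfectly
    similar (with a warning).
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must be (F, N, 3)")
    f, n = frames.shape[:2]
    if f < 4:
        raise ValueError("need at least 4 frames")
    if n < 2:
        raise ValueError("need at least 2 residues")
    traj = frames.transpose(1, 0, 2)                     # (N, F, 3)
    traj = traj - traj.mean(axis=1, keepdims=True)
    ssq = np.einsum("nfa,nfa->n", traj, traj)            # Σ|T_i|²
    rms = np.sqrt(ssq / f)
    moving = rms > _MOTIONLESS
    if not np.all(moving):
        logger.warning("%d motionless residues; their mutual similarity "
                       "is defined as 1", int((~moving).sum()))
    sigma = float(np.median(rms[moving])) if moving.any() else 1.0
    if sigma <= 0:
        sigma = 1.0

    best = _best_rotation_trace(traj, traj)
    resid2 = np.maximum(ssq[:, None] + ssq[None, :] - 2 * best, 0.0)
    sim_abs = np.exp(-np.sqrt(resid2 / f) / sigma)

    norms = np.sqrt(ssq)
    norms_safe = np.where(moving, norms, 1.0)
    that = traj / norms_safe[:, None, None]
    best_shape = _best_rotation_trace(that, that)
    mov2 = moving[:, None] & moving[None, :]
    d_shape = np.sqrt(np.maximum(np.where(mov2, 2.0 - 2.0 * best_shape, 4.0),
                                 0.0))
    sim_shape = np.exp(-d_shape / _SIGMA_SHAPE)

    vals = np.maximum(sim_abs, sim_shape)
    both_still = ~moving[:, None] & ~moving[None, :]
    vals[both_still] = 1.0
    np.fill_diagonal(vals, 1.0)
    vals = np.clip((vals + vals.T) / 2, 0.0, 1.0)
    return AMSM(values=vals, labels=np.arange(n),
                source=source or {"n_frames": f})


@dataclass
class DomainAssignment:
    labels: np.ndarray      # domain index per residue (0-based)
    k: int
    quality: float          # mean within-domain AMSM − mean between-domain
    medoids: np.ndarray


def _kmedoids(d: np.ndarray, k: int, seed: int = 0,
              max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids: farthest-point init + Voronoi iteration."""
    n = len(d)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_near = d[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_near)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if members.size:
                within = d[np.ix_(members, members)].sum(axis=1)
                new[c] = members[int(np.argmin(within))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    assign = np.argmin(d[:, medoids], axis=1)
    return assign, medoids


def _quality(values: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(n, dtype=bool)
    within = values[same & off]
    between = values[~same]
    if between.size == 0 or within.size == 0:
        return 0.0
    return float(within.mean() - between.mean())


def assign_domains(a: AMSM, k: int | str = "auto", seed: int = 0,
                   min_quality: float = 0.01) -> DomainAssignment:
    """k-medoids domain assignment on the dissimilarity 1 − AMSM.

    ``k="auto"`` scans k ∈ {2..6}, maximizing the quality score (mean
    within-domain similarity minus mean between-domain similarity), with
    ties broken toward smaller k; if no split beats ``min_quality`` a
    single domain is returned.
    """
    n = len(a.labels)
    d = 1.0 - a.values
    if k == "auto":
        best = None
        for kk in range(2, min(6, n) + 1):
            labels, medoids = _kmedoids(d, kk, seed=seed)
            q = _quality(a.values, labels)
            if best is None or q > best[0] + 1e-9:
                best = (q, kk, labels, medoids)
        q, kk, labels, medoids = best
        if q < min_quality:
            return DomainAssignment(labels=np.zeros(n, int), k=1, quality=0.0,
                                    medoids=np.array([int(np.argmin(d.sum(1)))]))
        return DomainAssignment(labels=labels, k=kk, quality=q, medoids=medoids)
    k = int(k)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} residues")
    if k == 1:
        return DomainAssignment(labels=np.zeros(n, int), k=1, quality=0.0,
                                medoids=np.array([int(np.argmin(d.sum(1)))]))
    labels, medoids = _kmedoids(d, k, seed=seed)
    return DomainAssignment(labels=labels, k=k,
                            quality=_quality(a.values, labels), medoids=medoids)
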