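"""Rigid-body superposition, ensemble fitting, core finding, helix geometry.

The iterated-superposition core finder mirrors the classical invariant-core
procedure: refit the ensemble on the currently retained positions, score
each position by the volume of its positional-scatter ellipsoid, drop the
worst, and stop once every pairwise RMSD over the retained positions falls
below a threshold (default 1 Å).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)


def kabsch_fit(mobile: np.ndarray, target: np.ndarray,
               weights: np.ndarray | None = None):
    """Optimal proper-rotation superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``mobile @ rotation.T + translation ≈ target``.  The rotation always
    has determinant +1 (reflections are excluded by construction).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (N, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 positions for a rigid fit")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    cm = np.average(mobile, axis=0, weights=w)
    ct = np.average(target, axis=0, weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(target - ct, mobile - cm, weights=w)
    rmat = rot.as_matrix()
    trans = ct - cm @ rmat.T
    # recompute the residual directly: the lsq residual from align_vectors
    # cancels catastrophically for near-congruent inputs
    d = mobile @ rmat.T + trans - target
    rmsd = np.sqrt(np.sum(w * np.sum(d * d, axis=1)) / w.sum())
    return rmat, trans, float(rmsd)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray,
                weights: np.ndarray | None = None) -> float:
    """Minimized RMSD between two coordinate sets (symmetric in a, b)."""
    return kabsch_fit(a, b, weights)[2]


@dataclass
class SuperposedEnsemble:
    """Coordinate stack over shared positions after mutual best-fit."""

    labels: list[str]
    positions: np.ndarray          # aligned-column indices used
    coords: np.ndarray             # (S, P, 3)
    mean_structure: np.ndarray     # (P, 3)

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_positions(self) -> int:
        return self.coords.shape[1]

    def rmsd_to_mean(self) -> np.ndarray:
        d = self.coords - self.mean_structure
        return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def fit_ensemble(coords, labels=None, positions=None,
                 tol: float = 1e-8, max_iter: int = 500,
                 initial_mean: np.ndarray | None = None) -> SuperposedEnsemble:
    """Iteratively superpose all structures onto their evolving mean.

    The initial reference is the structure with the smallest summed
    pairwise RMSD to the rest, which makes the converged mean independent
    of input order; an explicit ``initial_mean`` (e.g. from a previous
    fit) overrides it.  Iteration stops when the mean moves by less than
    ``tol`` Å RMS.
    """
    stack = np.asarray([np.asarray(c, float) for c in coords])
    if stack.ndim != 3 or stack.shape[2] != 3:
        raise ValueError("expected a list/stack of (P, 3) coordinate sets")
    s, p = stack.shape[:2]
    if s < 2:
        raise ValueError("need at least 2 structures")
    if p < 3:
        raise ValueError("need at least 3 shared positions")
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(s)]
    positions = (np.arange(p) if positions is None
                 else np.asarray(positions, int))

    if initial_mean is not None:
        mean = np.asarray(initial_mean, float).copy()
    else:
        pair = np.zeros((s, s))
        for i in range(s):
            for j in range(i + 1, s):
                pair[i, j] = pair[j, i] = kabsch_rmsd(stack[i], stack[j])
        ref = int(np.argmin(pair.sum(axis=1)))
        mean = stack[ref] - stack[ref].mean(axis=0)
    fitted = np.empty_like(stack)
    for _ in range(max_iter):
        for i in range(s):
            r, t, _ = kabsch_fit(stack[i], mean)
            fitted[i] = stack[i] @ r.T + t
        new_mean = fitted.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return SuperposedEnsemble(labels=labels, positions=positions,
                              coords=fitted, mean_structure=mean)


def refit(ensemble: SuperposedEnsemble,
          position_mask: np.ndarray | None = None) -> SuperposedEnsemble:
    """Re-run the mutual fit, optionally weighting only a subset of positions.

    Coordinates for *all* positions are kept; only the fit is restricted.
    """
    if position_mask is None:
        return fit_ensemble(ensemble.coords, ensemble.labels,
                            ensemble.positions,
                            initial_mean=ensemble.mean_structure)
    mask = np.asarray(position_mask, bool)
    core = fit_ensemble(ensemble.coords[:, mask], ensemble.labels,
                        initial_mean=ensemble.mean_structure[mask])
    fitted = np.empty_like(ensemble.coords)
    for i in range(ensemble.n_structures):
        r, t, _ = kabsch_fit(ensemble.coords[i][mask], core.coords[i])
        fitted[i] = ensemble.coords[i] @ r.T + t
    return SuperposedEnsemble(labels=ensemble.labels,
                              positions=ensemble.positions, coords=fitted,
                              mean_structure=fitted.mean(axis=0))


@dataclass
class CoreSelection:
    """Result of the iterated-superposition core search."""

    retained_positions: np.ndarray
    elimination_order: np.ndarray
    per_round_volume: np.ndarray     # scatter statistic of each eliminated position
    threshold_met: bool

    @property
    def n_core(self) -> int:
        return len(self.retained_positions)


def _scatter_volume(coords: np.ndarray) -> np.ndarray:
    """Per-position scatter-ellipsoid volume statistic sqrt(det(cov))."""
    centred = coords - coords.mean(axis=0, keepdims=True)
    s, p = coords.shape[:2]
    cov = np.einsum("spi,spj->pij", centred, centred) / max(s - 1, 1)
    det = np.maximum(np.linalg.det(cov), 0.0)
    return np.sqrt(det)


def _max_pairwise_rmsd(coords: np.ndarray) -> float:
    s = coords.shape[0]
    worst = 0.0
    for i in range(s):
        for j in range(i + 1, s):
            worst = max(worst, kabsch_rmsd(coords[i], coords[j]))
    return worst


def find_core(ensemble: SuperposedEnsemble, threshold: float = 1.0,
              target_count: int | None = None) -> CoreSelection:
    """Iteratively eliminate the most variable positions.

    Each round refits the ensemble on the retained positions, computes the
    per-position scatter-ellipsoid volume, and removes the single worst
    position.  Success: every pairwise RMSD over retained positions is
    below ``threshold`` (or the ``target_count`` is reached).  If fewer
    than 4 positions would remain, the best achieved selection is returned
    with ``threshold_met=False``.
    """
    p = ensemble.n_positions
    if p < 4:
        raise ValueError("need at least 4 positions")
    mask = np.ones(p, dtype=bool)
    order, volumes = [], []
    while True:
        fitted = refit(ensemble, mask)
        sub = fitted.coords[:, mask]
        if target_count is not None and mask.sum() <= target_count:
            return CoreSelection(ensemble.positions[mask], np.array(order, int),
                                 np.array(volumes), True)
        if _max_pairwise_rmsd(sub) < threshold:
            return CoreSelection(ensemble.positions[mask], np.array(order, int),
                                 np.array(volumes), True)
        if mask.sum() <= 4:
            logger.warning("core search stopped at 4 positions without "
                           "reaching threshold %.2f A", threshold)
            return CoreSelection(ensemble.positions[mask], np.array(order, int),
                                 np.array(volumes), False)
        vol = _scatter_volume(fitted.coords)
        vol[~mask] = -np.inf
        worst = int(np.argmax(vol))
        mask[worst] = False
        order.append(int(ensemble.positions[worst]))
        volumes.append(float(vol[worst]))


@dataclass
class AxisSegment:
    """A fitted finite line segment: point + unit direction + extent."""

    point: np.ndarray
    direction: np.ndarray
    extent: tuple[float, float]

    @property
    def start(self) -> np.ndarray:
        return self.point + self.extent[0] * self.direction

    @property
    def end(self) -> np.ndarray:
        return self.point + self.extent[1] * self.direction


@dataclass
class HelixGeometry:
    axis_a: AxisSegment
    axis_b: AxisSegment
    angle: float                 # degrees, acute convention [0, 90]
    distance: float              # min distance between finite segments, Å
    centroid_distance: float


def helix_axis(coords: np.ndarray) -> AxisSegment:
    """Fit the axis of a helical Cα segment.

    Midpoints of consecutive Cα pairs damp the helical wobble; the first
    principal direction of those midpoints is the axis.  For ≥ 2 points
    on an exact line, the axis is the line itself.
    """
    coords = np.asarray(coords, float)
    if len(coords) < 5:
        raise ValueError("need at least 5 positions to fit a helix axis")
    mid = 0.5 * (coords[1:] + coords[:-1])
    centre = mid.mean(axis=0)
    _, _, vt = np.linalg.svd(mid - centre)
    direction = vt[0]
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    t = (coords - centre) @ direction
    return AxisSegment(point=centre, direction=direction,
                       extent=(float(t.min()), float(t.max())))


def _segment_distance(p1, d1, e1, p2, d2, e2) -> float:
    """Minimum distance between two finite 3D segments (dense parameter scan
    refined by local optimization of the bilinear closest-approach problem)."""
    a0, a1 = p1 + e1[0] * d1, p1 + e1[1] * d1
    b0, b1 = p2 + e2[0] * d2, p2 + e2[1] * d2
    u, v, w0 = a1 - a0, b1 - b0, a0 - b0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w0, v @ w0
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t (one extra pass handles the corner cases)
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    t = np.clip((b * s + e) / c, 0.0, 1.0) if c > 1e-12 else t
    return float(np.linalg.norm((a0 + s * u) - (b0 + t * v)))


def interhelix_geometry(a: AxisSegment, b: AxisSegment) -> HelixGeometry:
    """Acute angle and minimum segment distance between two helix axes."""
    cosang = abs(float(np.dot(a.direction, b.direction)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    dist = _segment_distance(a.point, a.direction, a.extent,
                             b.point, b.direction, b.extent)
    cdist = float(np.linalg.norm(
        0.5 * (a.start + a.end) - 0.5 * (b.start + b.end)))
    return HelixGeometry(axis_a=a, axis_b=b, angle=angle, distance=dist,
                         centroid_distance=cdist)
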