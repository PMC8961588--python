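"""Principal component analysis of a superposed structural ensemble.

PCA is run on the flattened Cartesian coordinates of the fitted ensemble
(equivalent positions only, no mass weighting, sample covariance with
divisor n−1).  The eigenvalue spectrum partitions the total positional
mean-square displacement; scores place each structure in the reduced
space and loadings attribute variance to individual positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .superpose import SuperposedEnsemble

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray      # descending, length n_components
    scores: np.ndarray           # (S, n_components)
    loadings: np.ndarray         # (n_components, P, 3), rows orthonormal
    mean: np.ndarray             # (P, 3)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def ensemble_pca(e: SuperposedEnsemble) -> PcaResult:
    """Eigendecomposition of the ensemble's positional covariance."""
    s, p = e.n_structures, e.n_positions
    if s < 3:
        raise ValueError("need at least 3 structures for ensemble PCA")
    if p < 3:
        raise ValueError("need at least 3 positions")
    x = e.coords.reshape(s, 3 * p)
    n_comp = min(s - 1, 3 * p)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(x)
    return PcaResult(eigenvalues=model.explained_variance_.copy(),
                     scores=scores,
                     loadings=model.components_.reshape(n_comp, p, 3),
                     mean=model.mean_.reshape(p, 3))


def variance_explained(p: PcaResult, k: int) -> float:
    """Fraction of total variance captured by the first k components."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > p.n_components:
        logger.warning("k=%d exceeds %d available components; clamping",
                       k, p.n_components)
        k = p.n_components
    total = p.total_variance
    if total <= 0:
        return 0.0
    return float(p.eigenvalues[:k].sum() / total)


def loadings_profile(p: PcaResult, component: int) -> np.ndarray:
    """Per-position contribution of one component: ‖(x, y, z)‖ per residue.

    Squared values sum to 1 for a well-defined (unit) component.  For a
    degenerate component (zero eigenvalue) a zero profile is returned
    with a warning.
    """
    if not 0 <= component < p.n_components:
        raise IndexError(f"component {component} out of range")
    if p.eigenvalues[component] <= 1e-12 * max(p.total_variance, 1e-30):
        logger.warning("component %d has (near-)zero variance; "
                       "its loadings are undefined", component)
        return np.zeros(p.loadings.shape[1])
    return np.linalg.norm(p.loadings[component], axis=1)
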