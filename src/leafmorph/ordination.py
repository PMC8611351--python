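"""Low-dimensional embeddings of shape descriptors.

Both quantification methods end in an ordination: centered PCA of the
descriptor matrix (no variable scaling), with classical metric MDS
(principal coordinates) on Euclidean distances as an independent
alternative.  For Euclidean input the two agree up to an orthogonal
transform of the scores, which is exercised in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


class ZeroVarianceError(ValueError):
    """All samples identical: no variance to decompose."""


@dataclass
class PCAModel:
    """Fitted linear ordination.

    mean: (p,) data mean; components: (k, p) orthonormal rows (None for a
    distance-only MDS fit); explained_variance: (k,) eigenvalues;
    explained_variance_ratio: (k,) fractions of total variance;
    scores: (n, k) sample coordinates.
    """

    mean: np.ndarray
    components: np.ndarray | None
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.explained_variance)

    def n_components_for(self, fraction: float) -> int:
        """Smallest number of leading components explaining >= fraction."""
        csum = np.cumsum(self.explained_variance_ratio)
        return int(np.searchsorted(csum, fraction - 1e-12) + 1)


def pca_fit(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Centered PCA without variable scaling."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if np.allclose(X, X[0], atol=1e-300, rtol=0) or np.ptp(X, axis=0).max() == 0:
        raise ZeroVarianceError("all samples are identical")
    p = PCA(n_components=n_components, svd_solver="full")
    scores = p.fit_transform(X)
    return PCAModel(mean=p.mean_, components=p.components_,
                    explained_variance=p.explained_variance_,
                    explained_variance_ratio=p.explained_variance_ratio_,
                    scores=scores)


def classical_mds(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Classical metric MDS (principal coordinates) on Euclidean distances.

    Computed from first principles — pairwise distance matrix, double
    centering, eigendecomposition — deliberately sharing no code with
    :func:`pca_fit` so the two can cross-validate each other.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need >= 2 samples")
    sq = np.sum(X ** 2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(D2, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    if not pos.any():
        raise ZeroVarianceError("all samples are identical")
    w, V = w[pos], V[:, pos]
    if n_components is not None:
        w, V = w[:n_components], V[:, :n_components]
    scores = V * np.sqrt(w)
    var = w / (n - 1)  # matches PCA eigenvalue normalization
    return PCAModel(mean=X.mean(axis=0), components=None,
                    explained_variance=var,
                    explained_variance_ratio=var / var.sum(),
                    scores=scores)
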