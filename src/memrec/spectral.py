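"""Spectral (PCA) baselines for pattern reconstruction.

The simplest non-parametric estimate of a stored pattern is the leading
eigenvector of the connectivity matrix J; a better-adapted variant applies
PCA to the Fisher score matrix S, which is what linearising the message
passing around the uninformative fixed point yields.  Eigenvectors are
rescaled to squared norm N so that they have the same length as a draw
from the binary pattern prior, which fixes the high-noise error constants
(2 for binary patterns, 1+ρ for sparse, 1+ρ(1−ρ) for low coding level).

Because the rectified channel has a positive mean weight, raw J carries a
large Perron-type component along the uniform vector whose eigenvalue
grows like N and hides the pattern spike; PCA on connectivity therefore
subtracts the mean off-diagonal weight by default.  The score matrix has
zero mean under the null channel and needs no centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh
from sklearn.base import BaseEstimator

from .channel import ChannelSpec, fisher_score

__all__ = ["SpectralResult", "pca_reconstruct", "SpectralReconstructor"]


@dataclass
class SpectralResult:
    """Top-P eigenvector estimate of the stored patterns.

    ``estimate`` has one neuron per row (N×P); each column has squared
    norm exactly N and a deterministic sign (largest-magnitude component
    positive).  ``eigenvalues`` are the P largest algebraic eigenvalues,
    in decreasing order.
    """

    estimate: np.ndarray
    eigenvalues: np.ndarray
    source: str


def _top_eigenpairs(M: np.ndarray, P: int) -> tuple[np.ndarray, np.ndarray]:
    N = M.shape[0]
    if P >= N - 1 or N <= 200:
        vals, vecs = eigh(M)
        order = np.argsort(vals)[::-1][:P]
        return vals[order], vecs[:, order]
    vals, vecs = eigsh(M, k=P, which="LA")
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pca_reconstruct(
    M: np.ndarray, P: int, center: bool = False, source: str = "connectivity"
) -> SpectralResult:
    """Top-P eigenvectors of a symmetric matrix, scaled to pattern length.

    With ``center``, the mean of the off-diagonal entries is subtracted
    before the eigendecomposition (removes the uniform Perron component of
    a non-negative connectivity matrix).  For P > 1 the returned columns
    span the leading subspace; no attempt is made to undo the rotational
    ambiguity of the Hebbian outer product.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    N = M.shape[0]
    if center:
        mask = ~np.eye(N, dtype=bool)
        M = M - M[mask].mean() * mask
    vals, vecs = _top_eigenpairs(M, P)
    # squared norm N, deterministic sign before any alignment
    vecs = vecs * np.sqrt(N) / np.linalg.norm(vecs, axis=0)
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return SpectralResult(estimate=vecs, eigenvalues=vals, source=source)


class SpectralReconstructor(BaseEstimator):
    """PCA baseline as a scikit-learn estimator.

    ``fit(J)`` eigendecomposes either the connectivity itself
    (``source="connectivity"``, centered by default) or its Fisher score
    matrix (``source="fisher"``, requires the channel parameters tau/nu).
    Reconstructed patterns are exposed as ``components_``
    (n_patterns × n_neurons), scaled so each has squared norm n_neurons.
    """

    def __init__(
        self,
        n_patterns: int = 1,
        source: str = "connectivity",
        tau: float = 0.0,
        nu: float = 1.0,
        center: bool | None = None,
    ):
        self.n_patterns = n_patterns
        self.source = source
        self.tau = tau
        self.nu = nu
        self.center = center

    def fit(self, J: np.ndarray, y=None):
        if self.source not in ("connectivity", "fisher"):
            raise ValueError(f"unknown source {self.source!r}")
        J = np.asarray(J, dtype=float)
        if self.source == "fisher":
            M = fisher_score(J, ChannelSpec(self.tau, self.nu))
            center = False if self.center is None else self.center
        else:
            M = J
            center = True if self.center is None else self.center
        res = pca_reconstruct(M, self.n_patterns, center=center, source=self.source)
        self.components_ = res.estimate.T
        self.eigenvalues_ = res.eigenvalues
        return self
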