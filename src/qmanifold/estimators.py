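"""Scikit-learn-style estimators for the information-geometric pipeline.

:class:`ClassicalMDS` is Torgerson scaling: double-center the squared
distance matrix, eigendecompose, and scale the top eigenvectors by the
square roots of their eigenvalues. It is exact on Euclidean distance
matrices; Fisher (spherical) matrices are only approximately Euclidean and
produce some negative eigenvalues, which are reported in the spectrum but
never used for coordinates.

:class:`FisherInformationEmbedding` is the full method: factorized
per-group distribution estimation, Fisher distances on the hypersphere of
square-root probability coordinates, and classical MDS (optionally followed
by PCA for the full-rank-then-project variant used when the scree plot
suggests a high intrinsic dimension).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .exceptions import DimensionError, NumericDomainError
from .geometry import DistanceMatrix, distance_matrix_factorized
from .responses import ResponseTable, estimate_all_marginals

__all__ = ["ClassicalMDS", "FisherInformationEmbedding"]

#: eigenvalues below this fraction of the largest magnitude count as zero
_EIG_RTOL = 1e-12


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make each column's first nonzero entry positive (reproducible files)."""
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Parameters
    ----------
    n_components : int, default=2
        Target embedding dimension. Truncated (with a warning) to the
        number of strictly positive eigenvalues when the input distances
        are not Euclidean enough to support it.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_samples, n_components_)
        Centered coordinates, columns ordered by descending eigenvalue,
        each scaled by the square root of its eigenvalue.
    eigenvalues_ : ndarray of shape (n_samples,)
        Full signed spectrum of the double-centered Gram matrix, descending.
        Negative entries measure how far the distances are from Euclidean.
    n_components_ : int
        Dimension actually used (<= requested).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        """Fit from a symmetric zero-diagonal distance matrix.

        ``X`` may be a square array or a :class:`~qmanifold.geometry.DistanceMatrix`.
        """
        if isinstance(X, DistanceMatrix):
            d = X.values
        else:
            d = np.asarray(X, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DimensionError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise NumericDomainError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise NumericDomainError("distance matrix must have a zero diagonal")
        k = d.shape[0]
        if not (1 <= self.n_components <= k - 1):
            raise DimensionError(
                f"n_components must lie in [1, {k - 1}] for {k} points"
            )
        j = np.eye(k) - np.ones((k, k)) / k
        b = -0.5 * j @ (d * d) @ j
        b = (b + b.T) / 2.0
        eigvals, eigvecs = linalg.eigh(b)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        tol = _EIG_RTOL * max(np.abs(eigvals).max(), 1.0)
        n_pos = int(np.sum(eigvals > tol))
        d_used = min(self.n_components, n_pos)
        if d_used < self.n_components:
            warnings.warn(
                f"only {n_pos} strictly positive eigenvalues; reducing the "
                f"embedding dimension from {self.n_components} to {d_used}",
                UserWarning,
                stacklevel=2,
            )
        coords = eigvecs[:, :d_used] * np.sqrt(eigvals[:d_used])
        self.embedding_ = _fix_signs(coords)
        self.eigenvalues_ = eigvals
        self.n_components_ = d_used
        self.n_samples_ = k
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


class FisherInformationEmbedding(BaseEstimator):
    """Embed respondent groups via Fisher distances on the statistical manifold.

    Each group's response distribution is estimated as a product of
    per-question answer frequencies (plug-in, optionally smoothed), mapped to
    square-root coordinates on the unit hypersphere, and all-to-all Fisher
    (arc-length) distances are embedded with classical MDS. Analogous to PCA,
    but the "points" are whole groups and the geometry is the Fisher metric
    of the categorical distribution family.

    Parameters
    ----------
    n_components : int or "auto", default=2
        Embedding dimension; ``"auto"`` takes the scree-plot elbow of the
        MDS spectrum.
    alpha : float, default=0.0
        Pseudocount added to every answer cell when estimating frequencies.
        Zero (the default) is the plug-in estimate; groups with disjoint
        support on any question then sit at the maximal distance pi/2.
    pca_components : int or None, default=None
        When set, the MDS embedding is computed at full rank (``K - 1``) and
        then projected to this many dimensions with PCA — the two-stage
        variant appropriate when the scree plot indicates a high intrinsic
        dimension but a 2-D picture is wanted.

    Attributes
    ----------
    labels_ : tuple of str
        Group labels, in order of first appearance in the input.
    marginals_ : list of GroupMarginals
    distance_matrix_ : DistanceMatrix
        Fisher distances between the fitted group distributions (radians).
    embedding_ : ndarray of shape (n_groups, n_components_)
    eigenvalues_ : ndarray
        MDS spectrum (descending, signed).
    n_components_ : int
    variance_retained_ : float
        Fraction of variance kept by the PCA stage (1.0 when unused).
    """

    def __init__(
        self,
        n_components: int | str = 2,
        alpha: float = 0.0,
        pca_components: int | None = None,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.pca_components = pca_components

    # -- input handling -----------------------------------------------------

    @staticmethod
    def _as_table(X, y) -> ResponseTable:
        if isinstance(X, ResponseTable):
            return X
        X = pd.DataFrame(X)
        if y is None:
            raise ValueError(
                "group labels y are required when X is not a ResponseTable"
            )
        return ResponseTable(answers=X, groups=pd.Series(y, index=X.index))

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit from respondent answers ``X`` and group labels ``y``.

        ``X`` may be a :class:`~qmanifold.responses.ResponseTable` (then
        ``y`` is ignored) or a respondents-by-questions DataFrame/array of
        categorical codes with ``y`` giving each respondent's group.
        """
        table = self._as_table(X, y)
        self.labels_ = table.group_labels
        self.marginals_ = estimate_all_marginals(table, alpha=self.alpha)
        self.distance_matrix_ = distance_matrix_factorized(self.marginals_)
        k = len(self.labels_)

        if self.pca_components is not None:
            mds = ClassicalMDS(n_components=k - 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # rank < K-1 is routine
                full = mds.fit_transform(self.distance_matrix_)
            target = int(self.pca_components)
            if target > full.shape[1]:
                target = full.shape[1]
            pca = PCA(n_components=target)
            coords = pca.fit_transform(full)
            self.embedding_ = _fix_signs(coords)
            self.variance_retained_ = float(pca.explained_variance_ratio_.sum())
            self.eigenvalues_ = mds.eigenvalues_
            self.n_components_ = target
        else:
            d = self._resolve_dimension(k)
            mds = ClassicalMDS(n_components=d)
            self.embedding_ = mds.fit_transform(self.distance_matrix_)
            self.eigenvalues_ = mds.eigenvalues_
            self.n_components_ = mds.n_components_
            self.variance_retained_ = 1.0
        return self

    def _resolve_dimension(self, n_groups: int) -> int:
        if self.n_components == "auto":
            from .embedding import scree  # local import avoids a module cycle

            probe = ClassicalMDS(n_components=n_groups - 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                probe.fit(self.distance_matrix_)
            return max(1, scree(probe.eigenvalues_).suggestion)
        d = int(self.n_components)
        if not (1 <= d <= n_groups - 1):
            raise DimensionError(
                f"n_components must lie in [1, {n_groups - 1}] for {n_groups} groups"
            )
        return d

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the group coordinates (one row per group)."""
        return self.fit(X, y).embedding_
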