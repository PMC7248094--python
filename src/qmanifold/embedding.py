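"""Embedding operations: classical MDS, scree diagnostics, PCA, Procrustes.

Thin functional surface over :mod:`qmanifold.estimators`, plus the
diagnostics used to choose and compare embeddings: the scree elbow rule for
picking a dimension, PCA post-reduction for the full-rank-then-project
variant, and Procrustes alignment for comparing configurations up to
translation, rotation, reflection and isotropic scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA

from .estimators import _EIG_RTOL, ClassicalMDS, _fix_signs
from .exceptions import DegenerateInputError, DimensionError
from .geometry import DistanceMatrix

__all__ = [
    "EmbeddingResult",
    "ScreeReport",
    "ProcrustesResult",
    "classical_mds",
    "scree",
    "pca_reduce",
    "procrustes_align",
]


@dataclass(frozen=True)
class EmbeddingResult:
    """Coordinates, spectrum and chosen dimension of one MDS embedding."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    dimension: int
    labels: tuple[str, ...]

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances of the embedded points."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


def classical_mds(D: DistanceMatrix | np.ndarray, n_components: int = 2) -> EmbeddingResult:
    """Torgerson scaling of a distance matrix; see :class:`ClassicalMDS`."""
    est = ClassicalMDS(n_components=n_components).fit(D)
    labels = D.labels if isinstance(D, DistanceMatrix) else tuple(
        f"g{i}" for i in range(est.n_samples_)
    )
    return EmbeddingResult(
        coords=est.embedding_,
        eigenvalues=est.eigenvalues_,
        dimension=est.n_components_,
        labels=labels,
    )


@dataclass(frozen=True)
class ScreeReport:
    """Positive spectrum, cumulative shares, and an advisory elbow."""

    eigenvalues: np.ndarray
    cumulative_share: np.ndarray
    suggestion: int
    flat: bool


def scree(spectrum: np.ndarray) -> ScreeReport:
    """Summarise an eigenvalue spectrum and suggest an embedding dimension.

    Keeps the strictly positive eigenvalues, normalises their cumulative
    shares, and suggests the elbow: the dimension at which the drop to the
    next eigenvalue accelerates the most (largest second difference). On a
    flat spectrum there is no elbow; the suggestion falls back to the count
    of positive eigenvalues and ``flat`` is set. Advisory only.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size == 0:
        raise ValueError("empty spectrum")
    tol = _EIG_RTOL * max(np.abs(spectrum).max(), 1.0)
    pos = np.sort(spectrum[spectrum > tol])[::-1]
    if pos.size == 0:
        return ScreeReport(pos, pos, suggestion=0, flat=True)
    share = np.cumsum(pos) / pos.sum()
    if pos.size <= 2:
        flat = pos.size == 2 and abs(pos[0] - pos[1]) <= tol
        return ScreeReport(pos, share, suggestion=int(pos.size) if flat else 1 if pos.size == 1 else int(np.argmax(-np.diff(pos)) + 1), flat=flat)
    drops = -np.diff(pos)  # drop after dimension k (k = 1 .. p-1)
    accel = np.diff(drops)  # acceleration at dimension k (k = 2 .. p-1)
    if accel.max() <= tol and drops.max() <= tol:
        return ScreeReport(pos, share, suggestion=int(pos.size), flat=True)
    return ScreeReport(pos, share, suggestion=int(np.argmax(accel) + 2), flat=False)


def pca_reduce(coords: np.ndarray, n_components: int) -> tuple[np.ndarray, float]:
    """Project an embedding to fewer dimensions with PCA.

    Returns the projected coordinates (sign-fixed for reproducibility) and
    the retained variance fraction.
    """
    coords = np.asarray(coords, dtype=float)
    if n_components > coords.shape[1]:
        raise DimensionError(
            f"target dimension {n_components} exceeds input dimension {coords.shape[1]}"
        )
    pca = PCA(n_components=n_components)
    out = pca.fit_transform(coords)
    return _fix_signs(out), float(pca.explained_variance_ratio_.sum())


@dataclass(frozen=True)
class ProcrustesResult:
    """Source configuration aligned onto a target, with the residual."""

    aligned: np.ndarray
    disparity: float
    scale: float
    rotation: np.ndarray
    translation: np.ndarray


def procrustes_align(source: np.ndarray, target: np.ndarray) -> ProcrustesResult:
    """Optimally translate, rotate/reflect and scale ``source`` onto ``target``.

    Minimises the summed squared differences over similarity transforms
    (reflections allowed). ``disparity`` is the residual normalised by the
    target's centered sum of squares, so 0 means an exact match and it is
    invariant to the target's overall scale.
    """
    a = np.asarray(source, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch {a.shape} vs {b.shape}")
    b_mean = b.mean(axis=0)
    a_c = a - a.mean(axis=0)
    b_c = b - b_mean
    b_norm_sq = float((b_c**2).sum())
    if b_norm_sq <= 0.0:
        raise DegenerateInputError("target configuration has zero variance")
    a_norm_sq = float((a_c**2).sum())
    if a_norm_sq <= 0.0:
        # a single point maps onto the target centroid
        aligned = np.tile(b_mean, (a.shape[0], 1))
        return ProcrustesResult(aligned, 1.0, 0.0, np.eye(a.shape[1]), b_mean)
    rotation, s = linalg.orthogonal_procrustes(a_c, b_c)
    scale = s / a_norm_sq
    aligned = scale * a_c @ rotation + b_mean
    disparity = float(((aligned - b) ** 2).sum() / b_norm_sq)
    return ProcrustesResult(
        aligned=aligned,
        disparity=disparity,
        scale=float(scale),
        rotation=rotation,
        translation=b_mean,
    )
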