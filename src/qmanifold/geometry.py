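"""Fisher (great-circle) distances between group distributions.

In square-root coordinates ``xi_I = sqrt(p_I)`` every distribution is a unit
vector on the positive quadrant of a hypersphere, and the Fisher-information
distance between two distributions is the arc length of the great circle
joining them:

    D_ij = arccos( sum_I xi_I^i xi_I^j )

The inner product is the Bhattacharyya coefficient. Under the factorization
assumption it splits into a product of per-question sums,

    sum_I xi^1_I xi^2_I = prod_q sum_a sqrt(f^1_q(a) f^2_q(a)),

so the all-to-all distance matrix never requires enumerating the
exponentially many strings. The full-enumeration path is kept for ground
truth: the two agree exactly (same terms, regrouped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import NumericDomainError, SchemaMismatchError
from .responses import GroupMarginals, JointDistribution

__all__ = [
    "DistanceMatrix",
    "bhattacharyya_factorized",
    "fisher_distance",
    "distance_matrix_factorized",
    "distance_matrix_joint",
]

#: products of per-question sums may exceed 1 by a few ulps; anything beyond
#: this signals a broken upstream distribution rather than roundoff
_UPPER_SLACK = 1e-9
_LOWER_SLACK = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K x K matrix of pairwise group distances.

    Fisher distances are in radians and bounded by pi/2 (positive-quadrant
    geometry: two distributions are at pi/2 iff their supports are disjoint).
    Euclidean distance matrices from embeddings share the container.
    """

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise SchemaMismatchError(f"matrix shape {v.shape} != ({k}, {k})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise NumericDomainError("distance matrix is not symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle entries as a flat vector."""
        iu = np.triu_indices(self.n_groups, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        # repr round-trip precision so written matrices reload losslessly
        self.to_frame().to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(values=df.to_numpy(dtype=float), labels=tuple(map(str, df.index)))


def bhattacharyya_factorized(m1: GroupMarginals, m2: GroupMarginals) -> float:
    """Bhattacharyya coefficient of two factorized distributions, in [0, 1].

    ``prod_q sum_a sqrt(f^1_q(a) * f^2_q(a))`` — identical to the inner
    product of the two full square-root vectors.
    """
    if not m1.same_schema(m2):
        raise SchemaMismatchError(
            f"groups {m1.group!r} and {m2.group!r} have different questions/alphabets"
        )
    coeff = 1.0
    for q in m1.questions:
        coeff *= float(np.sqrt(m1.freqs[q] * m2.freqs[q]).sum())
    return coeff


def fisher_distance(coefficient: float) -> float:
    """Arc-length (Fisher) distance from a Bhattacharyya coefficient.

    ``arccos`` after clipping to [0, 1]: values a few ulps above 1 are
    legitimate roundoff and clip silently; values below ``-1e-12`` or above
    ``1 + 1e-9`` indicate an invalid upstream distribution and raise.
    """
    if not math.isfinite(coefficient):
        raise NumericDomainError(f"coefficient {coefficient!r} is not finite")
    if coefficient < -_LOWER_SLACK or coefficient > 1.0 + _UPPER_SLACK:
        raise NumericDomainError(
            f"Bhattacharyya coefficient {coefficient!r} outside [0, 1]"
        )
    return float(np.arccos(np.clip(coefficient, 0.0, 1.0)))


def distance_matrix_factorized(
    groups: Sequence[GroupMarginals],
) -> DistanceMatrix:
    """All-to-all Fisher distances between factorized group estimates."""
    if len(groups) < 2:
        raise SchemaMismatchError("need at least two groups")
    k = len(groups)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = fisher_distance(
                bhattacharyya_factorized(groups[i], groups[j])
            )
    return DistanceMatrix(values=d, labels=tuple(g.group for g in groups))


def distance_matrix_joint(
    joints: Sequence[JointDistribution],
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Fisher distances by direct evaluation on full probability vectors.

    The exact (ground-truth) path used to validate the factorized one and to
    build theoretical distance matrices in simulations.
    """
    if len(joints) < 2:
        raise SchemaMismatchError("need at least two distributions")
    n = joints[0].p.shape[0]
    for j in joints[1:]:
        if j.p.shape[0] != n:
            raise SchemaMismatchError("distributions live on different string spaces")
    xi = np.stack([j.xi for j in joints])
    gram = xi @ xi.T
    if np.any(gram < -_LOWER_SLACK) or np.any(gram > 1.0 + _UPPER_SLACK):
        raise NumericDomainError("inner products outside [0, 1]")
    d = np.arccos(np.clip(gram, 0.0, 1.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    if labels is None:
        labels = tuple(f"g{i}" for i in range(len(joints)))
    return DistanceMatrix(values=d, labels=tuple(labels))
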