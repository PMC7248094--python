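"""Validation metrics: multipartite information, matrix correlation, ablation.

Three quantities accompany the embedding method. The *multipartite
information* (total correlation) of a joint distribution,

    MI = sum_I p_I ln( p_I / prod_q p_q(a_q(I)) )     [nats],

is the KL divergence of the joint from the product of its per-question
marginals; it is zero iff the questions are independent, i.e. exactly when
the factorization assumption is lossless. The *distance-matrix Pearson
correlation* is the goodness-of-fit between a theoretical (exact) Fisher
distance matrix and the Euclidean distances of a low-dimensional embedding,
computed over the strictly upper triangle. The *question-ablation profile*
locates which questions drive an outlying group by re-embedding with each
question removed and tracking the focal group's distance from the line
through the remaining groups.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .estimators import FisherInformationEmbedding
from .exceptions import DegenerateInputError, SchemaMismatchError
from .geometry import DistanceMatrix
from .responses import JointDistribution, ResponseTable
from .simulate import CurveSpec, simulate_study

__all__ = [
    "multipartite_information",
    "matrix_pearson",
    "embedding_distances",
    "ValidationReport",
    "run_validation",
    "AblationResult",
    "ablate_questions",
]


def multipartite_information(joint: JointDistribution) -> float:
    """Total correlation of a joint distribution over questions, in nats.

    Zero-probability strings contribute zero. For a single question the
    product of marginals equals the joint, so the value is exactly 0.
    Results within float noise below zero are clamped to 0.
    """
    if len(joint.questions) < 2:
        return 0.0
    grid = joint.p.reshape(joint.shape)
    log_prod = np.zeros_like(grid)
    for axis, q in enumerate(joint.questions):
        marg = joint.marginal(q)
        with np.errstate(divide="ignore"):
            log_m = np.where(marg > 0, np.log(np.where(marg > 0, marg, 1.0)), 0.0)
        shape = [1] * grid.ndim
        shape[axis] = -1
        log_prod = log_prod + log_m.reshape(shape)
    mask = grid > 0
    with np.errstate(divide="ignore"):
        log_p = np.where(mask, np.log(np.where(mask, grid, 1.0)), 0.0)
    mi = float(np.sum(grid[mask] * (log_p[mask] - log_prod[mask])))
    if -1e-12 <= mi < 0.0:
        mi = 0.0
    return mi


def matrix_pearson(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation between two distance matrices.

    Computed over the strictly upper triangles only: the zero diagonal is
    excluded (it would inflate the correlation) and the lower triangle is
    redundant by symmetry.
    """
    if d1.values.shape != d2.values.shape:
        raise SchemaMismatchError("distance matrices have different shapes")
    if d1.labels != d2.labels:
        raise SchemaMismatchError("distance matrices have different group order")
    x, y = d1.upper_triangle(), d2.upper_triangle()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError(
            "correlation undefined: a distance matrix is constant"
        )
    return float(stats.pearsonr(x, y).statistic)


def embedding_distances(coords: np.ndarray, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distance matrix of embedded points."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 2:
        raise ValueError("need at least two points")
    d = squareform(pdist(coords))
    if labels is None:
        labels = tuple(f"g{i}" for i in range(coords.shape[0]))
    return DistanceMatrix(values=d, labels=tuple(labels))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of one simulated-study validation run."""

    pearson_r: float
    group_mi: tuple[float, ...]
    dimension: int
    n_groups: int
    n_per_group: int
    seed: int | None
    placement: str
    spec: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def run_validation(
    spec: CurveSpec,
    n_groups: int,
    n_per_group: int,
    n_components: int = 2,
    seed: int | None = None,
    placement: str = "uniform",
    alpha: float = 0.0,
) -> ValidationReport:
    """Simulate a study, run the full pipeline, and score it against truth.

    Pipeline: sample responses from the hypersphere curve, estimate each
    group's factorized distribution, compute the Fisher distance matrix,
    embed with classical MDS, and correlate the embedding's Euclidean
    distances with the theoretical Fisher distances of the exact joints.
    The per-group multipartite information of the ground-truth joints is
    recorded as well (it colours validation plots: high-MI groups are the
    ones a factorized estimate represents least faithfully).
    """
    study = simulate_study(spec, n_groups, n_per_group, placement, seed)
    est = FisherInformationEmbedding(n_components=n_components, alpha=alpha)
    coords = est.fit_transform(study.table)
    d_emb = embedding_distances(coords, labels=est.labels_)
    d_true = study.theoretical_distances()
    r = matrix_pearson(d_true, d_emb)
    mi = tuple(multipartite_information(j) for j in study.joints)
    return ValidationReport(
        pearson_r=r,
        group_mi=mi,
        dimension=est.n_components_,
        n_groups=n_groups,
        n_per_group=n_per_group,
        seed=seed,
        placement=placement,
        spec={
            "n_questions": spec.n_questions,
            "n_answers": spec.n_answers,
            "kappa": spec.kappa,
            "m": spec.m,
        },
    )


# ---------------------------------------------------------------------------
# question ablation
# ---------------------------------------------------------------------------

def _line_distance(points: np.ndarray, focal: np.ndarray) -> float:
    """Perpendicular distance of ``focal`` from the total-least-squares line
    through ``points`` (2-D). Rotation-invariant, so robust to the arbitrary
    orientation of an MDS embedding."""
    center = points.mean(axis=0)
    centered = points - center
    # first principal axis = TLS line direction
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s.size == 0 or s[0] <= 1e-12:
        # coincident points: no line; distance from their common location
        return float(np.linalg.norm(focal - center))
    direction = vt[0]
    resid = (focal - center) - np.dot(focal - center, direction) * direction
    return float(np.linalg.norm(resid))


@dataclass(frozen=True)
class AblationResult:
    """Per-question outlier-distance profile for a focal group."""

    baseline: float
    distances: dict[str, float]
    focal_group: tuple[str, ...]

    def ranked(self) -> list[tuple[str, float]]:
        """Questions sorted by how much their removal shrinks the focal
        group's distance from the line (largest drop first)."""
        return sorted(self.distances.items(), key=lambda kv: kv[1])


def ablate_questions(
    table: ResponseTable,
    focal_group: str | tuple[str, ...],
    n_components: int = 2,
    alpha: float = 0.0,
) -> AblationResult:
    """Attribute an outlying group's separation to individual questions.

    Embeds all groups in ``n_components`` dimensions (2 by default), fits a
    total-least-squares line to the non-focal group positions, and records
    the focal centroid's perpendicular distance from that line; then repeats
    with each question removed in turn. Questions whose removal collapses
    the distance are the ones driving the outlier. ``focal_group`` may be a
    single label or a collection of labels sharing a super-group (their
    centroid, the cluster's centre of mass, is used).
    """
    focal = (focal_group,) if isinstance(focal_group, str) else tuple(focal_group)
    labels = table.group_labels
    unknown = [g for g in focal if g not in labels]
    if unknown:
        raise SchemaMismatchError(f"focal groups {unknown} not in table")
    if len(labels) - len(focal) < 2:
        raise DegenerateInputError("need at least two non-focal groups to fit a line")
    if table.n_questions < 2:
        raise ValueError("need at least two questions to ablate")

    def distance_for(tbl: ResponseTable) -> float:
        est = FisherInformationEmbedding(n_components=n_components, alpha=alpha)
        with warnings.catch_warnings():
            # rank deficiency after removing a question is routine here
            warnings.simplefilter("ignore", UserWarning)
            coords = est.fit_transform(tbl)
        if coords.shape[1] == 0:  # all groups coincide
            return 0.0
        idx = {g: i for i, g in enumerate(est.labels_)}
        focal_pts = coords[[idx[g] for g in focal]]
        rest = coords[[idx[g] for g in est.labels_ if g not in focal]]
        return _line_distance(rest, focal_pts.mean(axis=0))

    baseline = distance_for(table)
    distances = {
        q: distance_for(table.drop_question(q)) for q in table.questions
    }
    return AblationResult(baseline=baseline, distances=distances, focal_group=focal)
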