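"""Synthetic questionnaire studies from curves on the probability hypersphere.

The validation framework parameterises the positive quadrant of the unit
``N``-sphere with generalised spherical coordinates (``N = N_A ** N_Q``
response strings, ``N - 1`` angles, each in ``[0, pi/2]``):

    xi_1 = cos(phi_1)
    xi_j = sin(phi_1) ... sin(phi_{j-1}) cos(phi_j),   1 < j < N
    xi_N = sin(phi_1) ... sin(phi_{N-1})

and draws group distributions from a one-parameter family of angles,

    phi_i(t) = (pi/2) sin^2(m pi t)   if i == kappa
               (pi/2) t               otherwise,        t in [0, 1].

``kappa`` selects which angle oscillates and ``m`` how many times; larger
``m`` makes the curve (and hence the group manifold) more non-linear. Each
of ``K`` groups gets a parameter value ``t_k`` (uniformly spaced or random),
its exact joint ``p_I = xi_I^2``, and ``n`` responses sampled i.i.d. from
that joint — so every study carries its own ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, NumericDomainError
from .geometry import DistanceMatrix, distance_matrix_joint
from .responses import JointDistribution, ResponseTable, index_to_string

__all__ = [
    "CurveSpec",
    "SimulatedStudy",
    "spherical_to_sqrt_coords",
    "curve_angles",
    "curve_distribution",
    "sample_responses",
    "simulate_study",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of the hypersphere curve and questionnaire geometry.

    Parameters
    ----------
    n_questions, n_answers : int
        Questionnaire shape; the hypersphere dimension is
        ``N = n_answers ** n_questions``.
    kappa : int
        Index (1-based, ``1 <= kappa <= N - 1``) of the angle driven by the
        sine-squared term.
    m : int
        Oscillation count of that term over ``t in [0, 1]``; positive
        integer (the ``t = 1`` endpoint identities rely on integrality).
    """

    n_questions: int
    n_answers: int
    kappa: int = 1
    m: int = 1

    def __post_init__(self) -> None:
        if self.n_questions < 1 or self.n_answers < 2:
            raise ValueError("need n_questions >= 1 and n_answers >= 2")
        if self.n_answers > len(_LETTERS):
            raise ValueError(f"at most {len(_LETTERS)} answers per question")
        if not (1 <= self.kappa <= self.n_strings - 1):
            raise ValueError(f"kappa must lie in [1, {self.n_strings - 1}]")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError("m must be a positive integer")

    @property
    def n_strings(self) -> int:
        return self.n_answers**self.n_questions

    @property
    def questions(self) -> tuple[str, ...]:
        return tuple(f"q{i + 1}" for i in range(self.n_questions))

    @property
    def alphabets(self) -> dict[str, tuple[str, ...]]:
        codes = tuple(_LETTERS[: self.n_answers])
        return {q: codes for q in self.questions}


def spherical_to_sqrt_coords(angles: Sequence[float]) -> np.ndarray:
    """Map ``N - 1`` spherical angles to an ``N``-vector of sqrt coordinates.

    All angles must lie in ``[0, pi/2]`` so the vector stays in the positive
    quadrant; the result is a unit vector by construction.
    """
    phi = np.asarray(angles, dtype=float)
    if phi.ndim != 1 or phi.size < 1:
        raise ValueError("angles must be a non-empty 1-D sequence")
    if np.any(phi < 0.0) or np.any(phi > np.pi / 2 + 1e-12):
        raise NumericDomainError("angles must lie in [0, pi/2]")
    sin_prod = np.concatenate(([1.0], np.cumprod(np.sin(phi))))
    xi = np.empty(phi.size + 1)
    xi[:-1] = sin_prod[:-1] * np.cos(phi)
    xi[-1] = sin_prod[-1]
    return xi


def curve_angles(t: float, spec: CurveSpec) -> np.ndarray:
    """Angles of the one-parameter family at curve parameter ``t``."""
    if not (0.0 <= t <= 1.0):
        raise NumericDomainError(f"t = {t!r} outside [0, 1]")
    phi = np.full(spec.n_strings - 1, (np.pi / 2) * t)
    phi[spec.kappa - 1] = (np.pi / 2) * np.sin(spec.m * np.pi * t) ** 2
    return phi


def curve_distribution(t: float, spec: CurveSpec) -> JointDistribution:
    """Exact joint distribution at curve parameter ``t`` (``p_I = xi_I^2``).

    Coordinate ``xi_j`` corresponds to the ``j``-th response string in
    lexicographic order (question 1 most significant).
    """
    xi = spherical_to_sqrt_coords(curve_angles(t, spec))
    p = xi**2
    p = p / p.sum()  # renormalise away the ~1e-16 from squaring
    return JointDistribution(p=p, questions=spec.questions, alphabets=spec.alphabets)


def sample_responses(
    joint: JointDistribution,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw ``n`` i.i.d. response strings and decode them to answers.

    Returns a DataFrame with one respondent per row and one question per
    column, reproducible under a fixed seed/generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = joint.p
    if np.any(np.isnan(p)) or np.any(p < 0):
        raise DegenerateInputError("joint has NaN or negative probabilities")
    rng = np.random.default_rng(rng)
    idx = rng.choice(p.shape[0], size=n, p=p)
    rows = [index_to_string(int(i), joint.questions, joint.alphabets) for i in idx]
    return pd.DataFrame(rows, columns=list(joint.questions))


@dataclass(frozen=True)
class SimulatedStudy:
    """A synthetic grouped questionnaire with its ground truth attached."""

    table: ResponseTable
    joints: tuple[JointDistribution, ...]
    t_values: tuple[float, ...]
    spec: CurveSpec
    placement: str
    n_per_group: int
    seed: int | None

    @property
    def group_labels(self) -> tuple[str, ...]:
        return self.table.group_labels

    def theoretical_distances(self) -> DistanceMatrix:
        """Exact Fisher distance matrix of the ground-truth joints."""
        return distance_matrix_joint(self.joints, labels=self.group_labels)


def simulate_study(
    spec: CurveSpec,
    n_groups: int,
    n_per_group: int,
    placement: str = "uniform",
    seed: int | None = None,
) -> SimulatedStudy:
    """Simulate a grouped questionnaire study from the hypersphere curve.

    ``K = n_groups`` parameter values are placed on the curve — uniformly,
    ``t_k = (k - 1) / (K - 1)`` with both endpoints included, or as sorted
    uniform random draws — and ``n_per_group`` responses are sampled from
    each group's exact joint. One seeded RNG stream drives the whole study;
    groups are sampled in ``t`` order, so changing ``K`` changes all draws.
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if placement not in ("uniform", "random"):
        raise ValueError("placement must be 'uniform' or 'random'")
    rng = np.random.default_rng(seed)
    if placement == "uniform":
        t_values = np.linspace(0.0, 1.0, n_groups)
    else:
        t_values = np.sort(rng.uniform(0.0, 1.0, size=n_groups))
    width = len(str(n_groups))
    labels = [f"group{k + 1:0{width}d}" for k in range(n_groups)]
    joints, frames = [], []
    for label, t in zip(labels, t_values):
        joint = curve_distribution(float(t), spec)
        joints.append(joint)
        frame = sample_responses(joint, n_per_group, rng)
        frame.insert(0, "group", label)
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    table = ResponseTable(
        answers=data[list(spec.questions)],
        groups=data["group"],
        alphabets=spec.alphabets,
    )
    return SimulatedStudy(
        table=table,
        joints=tuple(joints),
        t_values=tuple(float(t) for t in t_values),
        spec=spec,
        placement=placement,
        n_per_group=int(n_per_group),
        seed=seed,
    )
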