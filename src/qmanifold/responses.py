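"""Grouped categorical questionnaire responses and per-group distribution estimates.

A questionnaire with ``N_Q`` categorical questions, each with a finite answer
alphabet, induces a probability distribution over *response strings*: the
ordered sequence of one respondent's answers. Respondents are partitioned
into groups (by region, ethnicity, any categorical covariate), and each
group ``k`` is identified with its distribution ``p_I^k`` over strings ``I``.

Because the number of strings grows exponentially with ``N_Q``, per-group
distributions are estimated under a factorization (question-independence)
assumption: the joint probability of a string is the product of per-question
marginal answer frequencies. This module holds the data model
(:class:`ResponseTable`), the factorized estimate (:class:`GroupMarginals`),
and the materialised joint (:class:`JointDistribution`) used for ground truth
and validation on small questionnaires.

String-ordering convention
--------------------------
Wherever a joint distribution is stored as a flat vector, strings are ordered
lexicographically by answer code with the *first* question most significant
(mixed-radix, leftmost digit highest). All modules share this convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AnswerDomainError,
    EmptyGroupError,
    GroupNotFoundError,
    SchemaMismatchError,
    SizeLimitError,
)

__all__ = [
    "ResponseTable",
    "GroupMarginals",
    "JointDistribution",
    "estimate_group_marginals",
    "estimate_all_marginals",
    "factorized_joint",
    "string_probability",
    "validate_table",
    "ValidationSummary",
    "string_to_index",
    "index_to_string",
]

_DEFAULT_JOINT_CAP = 10**6


# ---------------------------------------------------------------------------
# string <-> flat index conversion (shared convention)
# ---------------------------------------------------------------------------

def string_to_index(
    answers: Sequence[str],
    questions: Sequence[str],
    alphabets: Mapping[str, Sequence[str]],
) -> int:
    """Map a response string to its flat index (question 1 most significant)."""
    idx = 0
    for q, a in zip(questions, answers):
        alphabet = alphabets[q]
        try:
            digit = alphabet.index(a)
        except ValueError:
            raise AnswerDomainError(
                f"answer {a!r} not in alphabet of question {q!r}"
            ) from None
        idx = idx * len(alphabet) + digit
    return idx


def index_to_string(
    index: int,
    questions: Sequence[str],
    alphabets: Mapping[str, Sequence[str]],
) -> tuple[str, ...]:
    """Inverse of :func:`string_to_index`."""
    digits: list[str] = []
    for q in reversed(questions):
        alphabet = alphabets[q]
        index, digit = divmod(index, len(alphabet))
        digits.append(alphabet[digit])
    if index:
        raise IndexError("string index out of range")
    return tuple(reversed(digits))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseTable:
    """Categorical answers per respondent per question, with group labels.

    Parameters
    ----------
    answers : pandas.DataFrame
        One row per respondent, one column per question; entries are opaque
        categorical answer codes (strings, never interpreted ordinally).
    groups : pandas.Series
        Group label per respondent, index-aligned with ``answers``.
    alphabets : dict
        Ordered answer alphabet per question. Inferred (sorted codes) when
        omitted; supply explicitly to pin dimensions across datasets, e.g.
        to keep answer codes that happen to be unseen in one table.
    """

    answers: pd.DataFrame
    groups: pd.Series
    alphabets: dict[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        answers = self.answers.astype(str)
        groups = self.groups.astype(str)
        if len(answers) != len(groups):
            raise SchemaMismatchError("answers and groups must have equal length")
        if len(answers) == 0:
            raise EmptyGroupError("response table has no respondents")
        if not answers.index.equals(groups.index):
            groups = groups.set_axis(answers.index)
        alphabets = self.alphabets
        if alphabets is None:
            alphabets = {
                q: tuple(sorted(answers[q].unique())) for q in answers.columns
            }
        else:
            alphabets = {q: tuple(str(a) for a in codes) for q, codes in alphabets.items()}
            missing = [q for q in answers.columns if q not in alphabets]
            if missing:
                raise SchemaMismatchError(f"no alphabet supplied for questions {missing}")
            for q in answers.columns:
                bad = set(answers[q].unique()) - set(alphabets[q])
                if bad:
                    raise AnswerDomainError(
                        f"answers {sorted(bad)} of question {q!r} outside its alphabet"
                    )
        object.__setattr__(self, "answers", answers)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "alphabets", alphabets)

    # -- derived views ------------------------------------------------------

    @property
    def questions(self) -> tuple[str, ...]:
        return tuple(self.answers.columns)

    @property
    def n_questions(self) -> int:
        return self.answers.shape[1]

    @property
    def n_respondents(self) -> int:
        return len(self.answers)

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Group labels in order of first appearance."""
        return tuple(dict.fromkeys(self.groups))

    def group_size(self, group: str) -> int:
        return int((self.groups == group).sum())

    def subset_questions(self, keep: Iterable[str]) -> "ResponseTable":
        """A new table restricted to the given questions (order preserved)."""
        wanted = set(keep)
        keep = [q for q in self.questions if q in wanted]
        return ResponseTable(
            answers=self.answers[keep].copy(),
            groups=self.groups.copy(),
            alphabets={q: self.alphabets[q] for q in keep},
        )

    def drop_question(self, question: str) -> "ResponseTable":
        return self.subset_questions(q for q in self.questions if q != question)


@dataclass(frozen=True)
class GroupMarginals:
    """Per-question answer frequencies of one respondent group.

    The factorized (question-independent) estimate of the group's joint
    distribution: ``f_q(a)`` is the frequency of answer ``a`` to question
    ``q``, optionally smoothed with a pseudocount ``alpha`` added to every
    cell. With ``alpha = 0`` this is the plug-in maximum-likelihood estimate.
    """

    group: str
    n: int
    questions: tuple[str, ...]
    alphabets: dict[str, tuple[str, ...]]
    freqs: dict[str, np.ndarray]
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for q in self.questions:
            f = np.asarray(self.freqs[q], dtype=float)
            if f.shape != (len(self.alphabets[q]),):
                raise SchemaMismatchError(f"frequency table of {q!r} has wrong length")
            if np.any(f < -1e-15) or np.any(f > 1 + 1e-15):
                raise ValueError(f"frequencies of {q!r} outside [0, 1]")
            if abs(f.sum() - 1.0) > 1e-12:
                raise ValueError(f"frequencies of {q!r} do not sum to 1")
            self.freqs[q] = f

    @property
    def n_strings(self) -> int:
        out = 1
        for q in self.questions:
            out *= len(self.alphabets[q])
        return out

    def same_schema(self, other: "GroupMarginals") -> bool:
        return self.questions == other.questions and self.alphabets == other.alphabets


@dataclass(frozen=True)
class JointDistribution:
    """A probability vector over all response strings, in lexicographic order.

    Also carries the square-root coordinates ``xi_I = sqrt(p_I)``, which place
    the distribution on the positive quadrant of the unit hypersphere — the
    representation in which the Fisher metric is the round-sphere metric.
    """

    p: np.ndarray
    questions: tuple[str, ...]
    alphabets: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        n = 1
        for q in self.questions:
            n *= len(self.alphabets[q])
        if p.shape != (n,):
            raise SchemaMismatchError(
                f"probability vector has length {p.shape}, expected {n}"
            )
        if np.any(np.isnan(p)) or np.any(p < -1e-15):
            raise ValueError("probabilities must be non-negative and finite")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "p", np.clip(p, 0.0, None))

    @property
    def xi(self) -> np.ndarray:
        """Square-root (hypersphere) coordinates; a unit vector."""
        return np.sqrt(self.p)

    @property
    def shape(self) -> tuple[int, ...]:
        """Alphabet sizes per question, in question order."""
        return tuple(len(self.alphabets[q]) for q in self.questions)

    def marginal(self, question: str) -> np.ndarray:
        """Marginal answer distribution of one question (sum over the rest)."""
        axis = self.questions.index(question)
        grid = self.p.reshape(self.shape)
        other = tuple(i for i in range(len(self.questions)) if i != axis)
        return grid.sum(axis=other)

    def strings(self) -> list[tuple[str, ...]]:
        """All response strings in storage (lexicographic) order."""
        return list(
            itertools.product(*(self.alphabets[q] for q in self.questions))
        )


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_group_marginals(
    table: ResponseTable, group: str, alpha: float = 0.0
) -> GroupMarginals:
    """Estimate per-question answer frequencies for one group.

    For question ``q`` with alphabet ``A_q`` and group size ``n``,

        f_q(a) = (count_q(a) + alpha) / (n + alpha * |A_q|)

    with ``alpha = 0`` (the default) the plug-in frequency estimate. Answer
    codes in the alphabet but unseen in the group keep frequency 0, so vector
    dimensions stay aligned across groups; two groups with disjoint support
    on any question are then at the maximal Fisher distance pi/2, which a
    small ``alpha > 0`` can soften.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    group = str(group)
    mask = table.groups == group
    if not mask.any():
        if group not in table.group_labels:
            raise GroupNotFoundError(group)
        raise EmptyGroupError(group)
    sub = table.answers.loc[mask]
    n = len(sub)
    freqs: dict[str, np.ndarray] = {}
    for q in table.questions:
        alphabet = table.alphabets[q]
        counts = sub[q].value_counts()
        c = np.array([counts.get(a, 0) for a in alphabet], dtype=float)
        freqs[q] = (c + alpha) / (n + alpha * len(alphabet))
    return GroupMarginals(
        group=group,
        n=n,
        questions=table.questions,
        alphabets=dict(table.alphabets),
        freqs=freqs,
        alpha=float(alpha),
    )


def estimate_all_marginals(
    table: ResponseTable, alpha: float = 0.0
) -> list[GroupMarginals]:
    """Factorized estimates for every group, in first-appearance order."""
    return [estimate_group_marginals(table, g, alpha) for g in table.group_labels]


def factorized_joint(
    marginals: GroupMarginals, max_size: int = _DEFAULT_JOINT_CAP
) -> JointDistribution:
    """Materialise the factorized joint ``p_I = prod_q f_q(a_q(I))``.

    Only feasible for small questionnaires (``N = prod |A_q| <= max_size``);
    distance computations never need it — see
    :func:`qmanifold.geometry.bhattacharyya_factorized` for the factorized
    path — but it is the ground-truth object in tests and simulations.
    """
    n = marginals.n_strings
    if n > max_size:
        raise SizeLimitError(
            f"joint over {n} strings exceeds cap {max_size}; use the "
            "factorized-path operations instead of materialising the joint"
        )
    p = np.array([1.0])
    for q in marginals.questions:
        p = np.multiply.outer(p, marginals.freqs[q]).ravel()
    return JointDistribution(
        p=p, questions=marginals.questions, alphabets=dict(marginals.alphabets)
    )


def string_probability(marginals: GroupMarginals, answers: Sequence[str]) -> float:
    """Probability of one response string under the factorized estimate."""
    if len(answers) != len(marginals.questions):
        raise SchemaMismatchError(
            f"expected {len(marginals.questions)} answers, got {len(answers)}"
        )
    prob = 1.0
    for q, a in zip(marginals.questions, answers):
        alphabet = marginals.alphabets[q]
        if a not in alphabet:
            raise AnswerDomainError(
                f"answer {a!r} not in alphabet of question {q!r}"
            )
        prob *= marginals.freqs[q][alphabet.index(a)]
    return prob


# ---------------------------------------------------------------------------
# advisory validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationSummary:
    """Advisory report on a response table; never blocks an analysis."""

    small_groups: dict[str, int]
    missing_cells: list[tuple[int, str]]
    invalid_cells: list[tuple[int, str, str]]
    unused_codes: dict[str, tuple[str, ...]]
    min_group_size: int

    @property
    def ok(self) -> bool:
        return not (
            self.small_groups
            or self.missing_cells
            or self.invalid_cells
            or self.unused_codes
        )


def validate_table(
    table: ResponseTable,
    min_group_size: int = 20,
    alphabets: Mapping[str, Sequence[str]] | None = None,
) -> ValidationSummary:
    """Report groups below ``min_group_size``, missing cells and unused codes.

    Distribution estimates from very small groups are noisy; embedding
    accuracy as a function of group size rises steeply up to roughly 20-25
    respondents and then levels off, hence the default threshold. When a
    reference ``alphabets`` schema is supplied, answers outside it are
    flagged with their row position. The report is advisory only.
    """
    small = {
        g: table.group_size(g)
        for g in table.group_labels
        if table.group_size(g) < min_group_size
    }
    missing: list[tuple[int, str]] = []
    for q in table.questions:
        col = table.answers[q]
        na = col.isin(("", "nan", "None")) | col.isna()
        for pos in np.flatnonzero(na.to_numpy()):
            missing.append((int(pos), q))
    invalid: list[tuple[int, str, str]] = []
    reference = {q: tuple(str(a) for a in alphabets[q]) for q in alphabets} if alphabets else table.alphabets
    for q in table.questions:
        allowed = set(reference.get(q, table.alphabets[q]))
        col = table.answers[q].to_numpy()
        for pos in range(len(col)):
            if col[pos] not in allowed:
                invalid.append((int(pos), q, str(col[pos])))
    unused = {}
    for q in table.questions:
        seen = set(table.answers[q].unique())
        extra = tuple(a for a in reference.get(q, table.alphabets[q]) if a not in seen)
        if extra:
            unused[q] = extra
    return ValidationSummary(
        small_groups=small,
        missing_cells=missing,
        invalid_cells=invalid,
        unused_codes=unused,
        min_group_size=int(min_group_size),
    )
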