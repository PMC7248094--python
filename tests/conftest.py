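"""Shared fixtures: small response tables built programmatically."""

import numpy as np
import pandas as pd
import pytest

from qmanifold import CurveSpec, ResponseTable


def answer_column(count_a: int, n: int) -> list[str]:
    """A binary answer column with an exact count of 'a' responses."""
    return ["a"] * count_a + ["b"] * (n - count_a)


@pytest.fixture
def toy_table() -> ResponseTable:
    """Two groups, two binary questions, counts chosen by hand."""
    data = pd.DataFrame(
        {
            "group": ["g", "g", "h", "h", "h", "h"],
            "q1": ["a", "a", "a", "b", "b", "b"],
            "q2": ["a", "b", "b", "b", "a", "b"],
        }
    )
    return ResponseTable(answers=data[["q1", "q2"]], groups=data["group"])


@pytest.fixture
def outlier_table() -> ResponseTable:
    """Seven groups: six on a line (driven by q1 and q3 jointly), one focal
    group that deviates only through q2. Removing q2 must collapse the focal
    group back onto the line."""
    n = 20
    frames = []
    for k, count in enumerate([2, 5, 8, 11, 14, 17]):
        frames.append(
            pd.DataFrame(
                {
                    "group": f"g{k}",
                    "q1": answer_column(count, n),
                    "q2": answer_column(10, n),
                    "q3": answer_column(count, n),
                    "q4": answer_column(10, n),
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "group": "focal",
                "q1": answer_column(10, n),
                "q2": answer_column(19, n),
                "q3": answer_column(10, n),
                "q4": answer_column(10, n),
            }
        )
    )
    data = pd.concat(frames, ignore_index=True)
    return ResponseTable(answers=data[["q1", "q2", "q3", "q4"]], groups=data["group"])


@pytest.fixture
def headline_spec() -> CurveSpec:
    """The validation-study curve: 8 ternary questions, kappa=1, m=3."""
    return CurveSpec(n_questions=8, n_answers=3, kappa=1, m=3)


def random_marginals_table(
    rng: np.random.Generator, n_groups=3, n_questions=3, n_answers=2, n=30
) -> ResponseTable:
    """A random table with alphabet letters a, b, c, ..."""
    codes = "abcdefghij"[:n_answers]
    frames = []
    for g in range(n_groups):
        cols = {"group": [f"g{g}"] * n}
        for q in range(n_questions):
            cols[f"q{q + 1}"] = rng.choice(list(codes), size=n)
        frames.append(pd.DataFrame(cols))
    data = pd.concat(frames, ignore_index=True)
    questions = [f"q{q + 1}" for q in range(n_questions)]
    return ResponseTable(
        answers=data[questions],
        groups=data["group"],
        alphabets={q: tuple(codes) for q in questions},
    )
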