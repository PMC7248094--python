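"""Multipartite information, matrix correlation, validation runs, ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmanifold import (
    CurveSpec,
    DistanceMatrix,
    GroupMarginals,
    JointDistribution,
    ablate_questions,
    embedding_distances,
    factorized_joint,
    matrix_pearson,
    multipartite_information,
    run_validation,
)
from qmanifold.exceptions import DegenerateInputError, SchemaMismatchError


def binary_pair(p_aa, p_ab, p_ba, p_bb):
    return JointDistribution(
        p=np.array([p_aa, p_ab, p_ba, p_bb]),
        questions=("q1", "q2"),
        alphabets={"q1": ("a", "b"), "q2": ("a", "b")},
    )


class TestMultipartiteInformation:
    def test_perfectly_correlated_pair_gives_ln2(self):
        assert multipartite_information(binary_pair(0.5, 0, 0, 0.5)) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_factorized_joint_gives_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            freqs = {
                "q1": rng.dirichlet([1, 1]),
                "q2": rng.dirichlet([1, 1, 1]),
                "q3": rng.dirichlet([1, 1]),
            }
            m = GroupMarginals(
                group="g", n=5,
                questions=("q1", "q2", "q3"),
                alphabets={"q1": ("a", "b"), "q2": ("a", "b", "c"), "q3": ("a", "b")},
                freqs=freqs,
            )
            assert multipartite_information(factorized_joint(m)) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_single_question_defined_as_zero(self):
        joint = JointDistribution(
            p=np.array([0.3, 0.7]), questions=("q1",), alphabets={"q1": ("a", "b")}
        )
        assert multipartite_information(joint) == 0.0

    def test_agrees_with_direct_summation(self):
        """Oracle: explicit loop over strings with plain marginal lookups."""
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(8))
        joint = JointDistribution(
            p=p,
            questions=("q1", "q2", "q3"),
            alphabets={q: ("a", "b") for q in ("q1", "q2", "q3")},
        )
        grid = p.reshape(2, 2, 2)
        m1, m2, m3 = grid.sum((1, 2)), grid.sum((0, 2)), grid.sum((0, 1))
        expected = sum(
            grid[i, j, k] * np.log(grid[i, j, k] / (m1[i] * m2[j] * m3[k]))
            for i in range(2) for j in range(2) for k in range(2)
            if grid[i, j, k] > 0
        )
        assert multipartite_information(joint) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=200)
    def test_non_negative_on_random_joints(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(12) * rng.uniform(0.2, 5.0))
        joint = JointDistribution(
            p=p,
            questions=("q1", "q2"),
            alphabets={"q1": ("a", "b", "c"), "q2": ("a", "b", "c", "d")},
        )
        assert multipartite_information(joint) >= 0.0

    def test_invariant_under_question_permutation_and_relabeling(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(6)).reshape(2, 3)
        j1 = JointDistribution(
            p=p.ravel(), questions=("q1", "q2"),
            alphabets={"q1": ("a", "b"), "q2": ("a", "b", "c")},
        )
        # swap question order (transpose the grid)
        j2 = JointDistribution(
            p=p.T.ravel(), questions=("q2", "q1"),
            alphabets={"q2": ("a", "b", "c"), "q1": ("a", "b")},
        )
        # relabel answer codes (pure renaming, same probabilities)
        j3 = JointDistribution(
            p=p.ravel(), questions=("q1", "q2"),
            alphabets={"q1": ("x", "y"), "q2": ("u", "v", "w")},
        )
        mi = multipartite_information(j1)
        assert multipartite_information(j2) == pytest.approx(mi, abs=1e-12)
        assert multipartite_information(j3) == pytest.approx(mi, abs=1e-12)


class TestMatrixPearson:
    def _pair(self, seed=0, k=5):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(k, 3))
        labels = tuple(f"g{i}" for i in range(k))
        d1 = embedding_distances(pts, labels)
        d2 = embedding_distances(pts + 0.3 * rng.normal(size=pts.shape), labels)
        return d1, d2

    def test_identical_matrices_give_one(self):
        d1, _ = self._pair()
        assert matrix_pearson(d1, d1) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        d1, _ = self._pair()
        d3 = DistanceMatrix(values=3.0 * d1.values, labels=d1.labels)
        assert matrix_pearson(d1, d3) == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        d1, d2 = self._pair(seed=11)
        x, y = d1.upper_triangle(), d2.upper_triangle()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert matrix_pearson(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_constant_matrix_raises(self):
        labels = ("a", "b", "c")
        d = DistanceMatrix(values=np.ones((3, 3)) - np.eye(3), labels=labels)
        with pytest.raises(DegenerateInputError):
            matrix_pearson(d, d)

    def test_shape_mismatch_raises(self):
        d1, _ = self._pair(k=5)
        d2, _ = self._pair(k=4)
        with pytest.raises(SchemaMismatchError):
            matrix_pearson(d1, d2)


class TestEmbeddingDistances:
    def test_two_points(self):
        d = embedding_distances(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert d.values[0, 1] == 1.0

    def test_duplicate_point_gives_zero_entry(self):
        d = embedding_distances(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]))
        assert d.values[0, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(4, 3))
        d = embedding_distances(pts).values
        for i in range(4):
            for j in range(4):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(pts[i] - pts[j]), abs=1e-12
                )


class TestRunValidation:
    def test_determinism_under_fixed_seed(self, headline_spec):
        r1 = run_validation(headline_spec, 10, 15, 2, seed=42)
        r2 = run_validation(headline_spec, 10, 15, 2, seed=42)
        assert r1.to_json() == r2.to_json()

    def test_report_fields(self, headline_spec):
        rep = run_validation(headline_spec, 8, 10, 2, seed=7)
        assert -1.0 <= rep.pearson_r <= 1.0
        assert len(rep.group_mi) == 8
        assert all(mi >= 0 for mi in rep.group_mi)
        assert rep.dimension == 2

    def test_estimation_noise_shrinks_with_sample_size(self):
        """A near-exact estimate (n = 10^5) cannot do worse than n = 25."""
        spec = CurveSpec(n_questions=2, n_answers=3, kappa=1, m=2)
        seeds = range(10)
        r_small = np.median(
            [run_validation(spec, 20, 25, 2, seed=s).pearson_r for s in seeds]
        )
        r_large = np.median(
            [run_validation(spec, 20, 10**5, 2, seed=s).pearson_r for s in seeds]
        )
        assert r_large >= r_small


class TestAblation:
    def test_planted_question_has_largest_drop(self, outlier_table):
        result = ablate_questions(outlier_table, "focal", n_components=2)
        assert result.baseline > 0.1
        best, dist = result.ranked()[0]
        assert best == "q2"
        # removing the planted question collapses the outlier; others don't
        assert result.baseline - dist > 0.3
        for q in ("q1", "q3", "q4"):
            assert result.distances[q] > dist

    def test_focal_identical_to_another_group_is_no_outlier(self):
        """A focal group with the same distribution as a mid-line group has
        (near-)zero baseline distance from the line."""
        import pandas as pd

        from conftest import answer_column
        from qmanifold import ResponseTable

        n = 20
        frames = []
        for label, count in [("g0", 6), ("g1", 8), ("g2", 10), ("g3", 12),
                             ("g4", 14), ("focal", 10)]:
            frames.append(
                pd.DataFrame(
                    {
                        "group": label,
                        "q1": answer_column(count, n),
                        "q2": answer_column(10, n),
                    }
                )
            )
        data = pd.concat(frames, ignore_index=True)
        table = ResponseTable(answers=data[["q1", "q2"]], groups=data["group"])
        result = ablate_questions(table, "focal", n_components=2)
        assert result.baseline < 0.05

    def test_too_few_non_focal_groups_raises(self, toy_table):
        with pytest.raises(DegenerateInputError):
            ablate_questions(toy_table, "g")
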