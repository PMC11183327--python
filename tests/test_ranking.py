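import math

import numpy as np
import pytest

from scmarkers import (
    CellLabels,
    EmptyResultError,
    ExpressionMatrix,
    GeneRanker,
    ValidationError,
    cv2_score,
    discretize,
    mic_score,
    mutual_information,
    pca_gene_scores,
    rank_genes,
)
from scmarkers.ranking import mic_score_exhaustive
from scmarkers.simulate import all_markers


def mi_bruteforce(x, y) -> float:
    """Independent plug-in MI oracle: dict-based joint counts, direct summation."""
    n = len(x)
    joint, px, py = {}, {}, {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        px[a] = px.get(a, 0) + 1
        py[b] = py.get(b, 0) + 1
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        total += p_ab * math.log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return total


def entropy(x) -> float:
    n = len(x)
    counts = {}
    for a in x:
        counts[a] = counts.get(a, 0) + 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


class TestMutualInformation:
    def test_self_information_is_entropy(self):
        x = [0, 0, 1, 1]
        assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_gives_zero(self):
        assert mutual_information([5, 5, 5, 5], [0, 1, 0, 1]) == 0.0

    def test_joint_2x2_matches_bruteforce(self):
        # joint counts [[2,1],[1,2]], n = 6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert mutual_information(x, y) == pytest.approx(mi_bruteforce(x, y), abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 0])

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_bruteforce_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        x = rng.integers(0, 4, n)
        y = rng.integers(0, 4, n)
        mi = mutual_information(x, y)
        assert mi == pytest.approx(mi_bruteforce(x, y), abs=1e-12)
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert -1e-12 <= mi <= min(entropy(x), entropy(y)) + 1e-12


class TestDiscretize:
    def test_median_cut(self):
        np.testing.assert_array_equal(discretize([1, 2, 3, 4], 2), [0, 0, 1, 1])

    def test_constant_collapses(self):
        np.testing.assert_array_equal(discretize([7, 7, 7], 3), [0, 0, 0])

    def test_equal_width_hand_edges(self):
        out = discretize([0, 0, 0, 5, 9, 9], 3, strategy="equal_width")
        np.testing.assert_array_equal(out, [0, 0, 0, 1, 2, 2])

    def test_equal_frequency_balanced_on_distinct(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(np.arange(17).astype(float))
        out = discretize(x, 4)
        sizes = np.bincount(out)
        assert sizes.max() - sizes.min() <= 1

    def test_ties_share_a_bin(self):
        out = discretize([1, 1, 1, 1, 2, 3], 3)
        assert len(set(out[:4])) == 1


class TestMicScore:
    def test_perfect_threshold_separation(self):
        x = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        y = [0, 0, 0, 1, 1, 1]
        assert mic_score(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_two_class_normalizer_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        # with k_y = 2 the score is exactly the best I_k over k >= 2 bins
        assert 0.0 <= mic_score(x, y, max_x_bins=8) <= 1.0

    def test_single_distinct_value_scores_zero(self):
        assert mic_score([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1]) == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_dp_equals_exhaustive_partition_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.integers(0, 5, n).astype(float)
        y = rng.integers(0, 3, n)
        if len(set(y)) < 2:
            y[0] = (y[1] + 1) % 3
        assert mic_score(x, y, max_x_bins=4) == pytest.approx(
            mic_score_exhaustive(x, y, max_x_bins=4), abs=1e-12
        )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = rng.integers(0, 3, 50)
        base = mic_score(x, y)
        assert mic_score(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert mic_score(x**3, y) == pytest.approx(base, abs=1e-12)

    def test_candidate_coarsening_stays_close_to_exact(self):
        """Pre-binning long vectors changes the score only marginally."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(2, 1, 150)])
        y = np.repeat([0, 1], 150)
        exact = mic_score(x, y, max_candidates=10_000)
        coarse = mic_score(x, y)  # default candidate budget
        assert coarse <= exact + 1e-12
        assert coarse == pytest.approx(exact, abs=0.05)


class TestCv2:
    def test_hand_computation(self):
        # population variance 1.25, mean 2.5 -> 1.25 / 6.25
        assert cv2_score([1, 2, 3, 4]) == pytest.approx(0.2, abs=1e-12)

    def test_constant_scores_zero(self):
        assert cv2_score([5, 5, 5]) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 1.0, 30)
        assert cv2_score(2 * x) == pytest.approx(cv2_score(x), rel=1e-12)

    def test_zero_mean_is_nan(self):
        assert math.isnan(cv2_score([0.0, 0.0]))


class TestPcaScores:
    def test_zero_variance_gene_scores_zero(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(3.0, (30, 4)).astype(float)
        values[:, 2] = 1.0
        X = ExpressionMatrix(values, [f"c{i}" for i in range(30)], list("abcd"))
        scores = pca_gene_scores(X, n_components=3)
        assert scores[2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_closed_form(self):
        """Gene a = 2 x gene b: one nontrivial component with loadings from
        the 2x2 covariance eigenvector (1,2)/sqrt(5)."""
        rng = np.random.default_rng(6)
        b = rng.gamma(3.0, 1.0, 200)
        values = np.column_stack([2 * b, b])
        X = ExpressionMatrix(values, [f"c{i}" for i in range(200)], ["a", "b"])
        scores = pca_gene_scores(X, n_components=1)
        np.testing.assert_allclose(scores, [4 / 5, 1 / 5], atol=1e-10)

    def test_scores_sum_to_explained_variance_ratio(self):
        rng = np.random.default_rng(7)
        values = rng.poisson(5.0, (40, 10)).astype(float)
        X = ExpressionMatrix(values, [f"c{i}" for i in range(40)],
                             [f"g{j}" for j in range(10)])
        scores = pca_gene_scores(X, n_components=4)
        assert 0 < scores.sum() <= 1 + 1e-12


class TestRankGenes:
    @staticmethod
    def _matrix(values, genes):
        n = values.shape[0]
        return ExpressionMatrix(values, [f"c{i}" for i in range(n)], genes)

    def test_filter_and_sort(self):
        rng = np.random.default_rng(8)
        values = rng.poisson(2.0, (30, 3)).astype(float)
        values[:, 1] = 1.0  # constant -> cv2 == 0 -> dropped
        X = self._matrix(values, ["g1", "g2", "g3"])
        ranking = rank_genes(X, method="cv2")
        assert "g2" not in ranking.genes
        scores = [s for _, s in ranking.entries]
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_by_gene_id(self):
        values = np.array([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        X = self._matrix(values, ["zeta", "alpha"])
        ranking = rank_genes(X, method="cv2")
        assert ranking.genes == ["alpha", "zeta"]

    def test_supervised_method_requires_labels(self, tiny_matrix):
        with pytest.raises(ValidationError):
            rank_genes(tiny_matrix, None, method="mic")

    def test_all_constant_gives_empty_result(self):
        X = self._matrix(np.ones((10, 3)), ["a", "b", "c"])
        with pytest.raises(EmptyResultError):
            rank_genes(X, method="cv2")

    def test_deterministic_given_inputs(self, small_normalized):
        X, y, _ = small_normalized
        a = rank_genes(X, y, method="mic")
        b = rank_genes(X, y, method="mic")
        assert a.entries == b.entries

    def test_mic_recovers_planted_markers(self, small_normalized):
        """>= 80% of planted markers in the top 2x(number planted)."""
        X, y, markers = small_normalized
        planted = set(all_markers(markers))
        ranking = rank_genes(X, y, method="mic")
        hits = planted & set(ranking.top(2 * len(planted)))
        assert len(hits) >= 0.8 * len(planted)


class TestGeneRankerEstimator:
    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        ranker = GeneRanker(method="mi", k=5, n_bins=8)
        cloned = clone(ranker)
        assert cloned.get_params() == ranker.get_params()

    def test_transform_selects_top_k_in_rank_order(self, small_normalized):
        X, y, markers = small_normalized
        df = X.to_df()
        ranker = GeneRanker(method="mic", k=10).fit(df, y.labels)
        out = ranker.transform(df)
        assert list(out.columns) == ranker.ranking_.top(10)
        assert out.shape == (X.n_cells, 10)

    def test_pipeline_composition(self, small_normalized):
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import Pipeline

        X, y, _ = small_normalized
        pipe = Pipeline([
            ("select", GeneRanker(method="mic", k=20)),
            ("clf", KNeighborsClassifier()),
        ])
        pipe.fit(X.to_df(), y.labels)
        assert pipe.score(X.to_df(), y.labels) > 0.8
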