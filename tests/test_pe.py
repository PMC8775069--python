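import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sstats

from eegsep.cnn import CNNSpec, ConvNet
from eegsep.pe import (
    PEParams,
    StatTestResult,
    channel_separability,
    friedman_nemenyi,
    layer_pe_table,
    ordinal_pattern_codes,
    permutation_entropy,
    permutation_entropy_batch,
    significant_channel_counts,
    wilcoxon_rank_sum,
)


def brute_force_pe(x, order, delay=1):
    """Independent oracle: explicit enumeration of ordinal patterns with
    stable (order-of-appearance) tie breaking."""
    n = len(x)
    patterns = []
    for i in range(n - (order - 1) * delay):
        window = [(x[i + j * delay], j) for j in range(order)]
        ranks = tuple(j for _, j in sorted(window))
        patterns.append(ranks)
    counts = Counter(patterns)
    total = len(patterns)
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


class TestPEParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            PEParams(order=1)
        with pytest.raises(ValueError):
            PEParams(delay=0)

    def test_max_entropy(self):
        assert PEParams(order=3).max_entropy_bits == pytest.approx(
            np.log2(6))


class TestPermutationEntropy:
    def test_monotone_series_zero_bits(self):
        assert permutation_entropy(np.array([1.0, 2, 3, 4, 5, 6])) == 0.0
        assert permutation_entropy(np.arange(100.0)[::-1]) == 0.0

    def test_order2_worked_example(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        pe = permutation_entropy(x, PEParams(order=2))
        expected = -(4 / 6) * np.log2(4 / 6) - (2 / 6) * np.log2(2 / 6)
        assert pe == pytest.approx(expected, abs=1e-12)
        assert pe == pytest.approx(0.918, abs=1e-3)

    def test_iid_uniform_approaches_log2_factorial(self, rng):
        x = rng.random(100_000)
        pe = permutation_entropy(x)
        assert abs(pe - np.log2(6)) < 0.02

    def test_matches_brute_force_on_random_short_series(self, rng):
        for _ in range(100):
            n = rng.integers(10, 40)
            order = int(rng.integers(2, 5))
            x = np.round(rng.random(n) * 5) / 5  # coarse grid forces ties
            got = permutation_entropy(x, PEParams(order=order))
            ref = brute_force_pe(list(x), order)
            assert got == pytest.approx(ref, abs=1e-12)

    def test_delay_handling_matches_brute_force(self, rng):
        x = rng.random(60)
        got = permutation_entropy(x, PEParams(order=3, delay=4))
        assert got == pytest.approx(brute_force_pe(list(x), 3, delay=4),
                                    abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            permutation_entropy(np.array([1.0, 2.0]), PEParams(order=3))

    def test_constant_series_permitted(self):
        # stable tie-breaking: one pattern, zero entropy
        assert permutation_entropy(np.zeros(50)) == 0.0

    def test_bounds_and_invariance(self, rng):
        x = rng.standard_normal(500)
        pe = permutation_entropy(x)
        assert 0.0 <= pe <= np.log2(6)
        # strictly increasing transform leaves PE unchanged
        assert permutation_entropy(np.exp(3 * x)) == pytest.approx(pe,
                                                                   abs=1e-12)

    def test_normalized_in_unit_interval(self, rng):
        x = rng.standard_normal(1000)
        pe = permutation_entropy(x, PEParams(normalize=True))
        assert 0.0 <= pe <= 1.0

    def test_batch_agrees_with_single(self, rng):
        X = rng.standard_normal((7, 80))
        batch = permutation_entropy_batch(X)
        singles = [permutation_entropy(row) for row in X]
        assert np.allclose(batch, singles, atol=1e-12)

    def test_codes_distinct_patterns(self):
        codes = ordinal_pattern_codes(np.array([1.0, 2, 1, 2, 1]), 2, 1)
        assert len(set(codes.tolist())) == 2


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        a = np.arange(18.0)
        res = wilcoxon_rank_sum(a, a)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_small_p(self, rng):
        a = rng.normal(0, 1, 18)
        b = rng.normal(3, 1, 18)
        assert wilcoxon_rank_sum(a, b).p_value < 0.001

    def test_exact_agrees_with_permutation_oracle_5v5(self, rng):
        """Exhaustive label-assignment oracle, 3-decimal agreement."""
        for trial in range(5):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 5)
            res = wilcoxon_rank_sum(a, b)
            pooled = np.concatenate([a, b])
            ranks = sstats.rankdata(pooled)
            mu = 5 * 11 / 2.0
            obs = abs(ranks[:5].sum() - mu)
            hits = total = 0
            for idx in itertools.combinations(range(10), 5):
                total += 1
                if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
                    hits += 1
            assert res.p_value == pytest.approx(hits / total, abs=5e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    def test_normal_approx_matches_scipy(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1, 45)
        res = wilcoxon_rank_sum(a, b, exact_limit=1)
        assert res.p_value == pytest.approx(sstats.ranksums(a, b).pvalue,
                                            abs=1e-10)

    def test_tie_correction_matches_mannwhitney(self, rng):
        a = np.repeat([1.0, 2.0, 3.0], 12)
        b = np.repeat([2.0, 3.0, 4.0], 12)
        res = wilcoxon_rank_sum(a, b, exact_limit=1)
        ref = sstats.mannwhitneyu(a, b, method="asymptotic",
                                  use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestFriedmanNemenyi:
    def test_identical_classifiers(self):
        mat = np.tile(np.arange(10.0)[:, None], (1, 4))
        res = friedman_nemenyi(mat)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_3x3(self):
        # ranks per row: [1,2,3],[1,2,3],[2,1,3] -> R = [4,5,9]
        mat = np.array([[0.1, 0.2, 0.3],
                        [0.4, 0.5, 0.6],
                        [0.8, 0.7, 0.9]])
        # classic formula: 12/(n k (k+1)) * sum Rj^2 - 3 n (k+1)
        expected = 12.0 / (3 * 3 * 4) * (16 + 25 + 81) - 3 * 3 * 4
        res = friedman_nemenyi(mat)
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_without_ties(self, rng):
        mat = rng.random((15, 5))
        res = friedman_nemenyi(mat)
        ref = sstats.friedmanchisquare(*[mat[:, j] for j in range(5)])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_dominant_classifier_detected(self, rng):
        mat = rng.random((20, 4))
        mat[:, 0] += 2.0
        res = friedman_nemenyi(mat, ["best", "b", "c", "d"])
        assert res.p_value < 0.01
        others = res.pairwise.loc["best", ["b", "c", "d"]]
        assert (others < 0.05).any()

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            friedman_nemenyi(np.zeros((5, 1)))

    def test_constant_rows_tolerated(self, rng):
        mat = rng.random((8, 3))
        mat[2] = 0.5
        res = friedman_nemenyi(mat)
        assert 0.0 <= res.p_value <= 1.0

    def test_p_value_validation(self):
        with pytest.raises(ValueError, match="p_value"):
            StatTestResult("t", 0.0, 1.5)


class TestLayerPETable:
    @pytest.fixture(scope="class")
    def small_model_and_subjects(self):
        spec = CNNSpec(input_shape=(4, 64, 3), conv1_filters=4,
                       conv2_filters=6, dense1_units=8, dense2_units=4)
        model = ConvNet(spec, seed=0)
        rng = np.random.default_rng(0)
        subjects = []
        for i in range(4):
            cls = "ES" if i % 2 == 0 else "PNES"
            subjects.append((f"s{i}", cls,
                             rng.standard_normal((3, 4, 64, 3))
                             .astype(np.float32)))
        return model, subjects

    def test_cardinality(self, small_model_and_subjects):
        model, subjects = small_model_and_subjects
        table = layer_pe_table(model, subjects)
        # subjects x layers x channels
        assert len(table) == 4 * 3 * 4
        assert set(table["layer"]) == {"input", "Conv1", "Conv2"}

    def test_pe_within_bounds(self, small_model_and_subjects):
        model, subjects = small_model_and_subjects
        table = layer_pe_table(model, subjects)
        assert (table["pe"] >= 0).all()
        assert (table["pe"] <= np.log2(6) + 1e-12).all()

    def test_input_pe_independent_of_model(self, small_model_and_subjects):
        model, subjects = small_model_and_subjects
        table = layer_pe_table(model, subjects, layers=("input",))
        sid, cls, values = subjects[0]
        manual = permutation_entropy_batch(
            np.moveaxis(values.astype(np.float64), 2, 3))
        expect = manual.mean(axis=(0, 2))
        got = table[table["subject_id"] == sid].sort_values("channel")["pe"]
        assert np.allclose(got, expect, atol=1e-6)

    def test_unknown_layer_rejected(self, small_model_and_subjects):
        model, subjects = small_model_and_subjects
        with pytest.raises(ValueError, match="layer"):
            layer_pe_table(model, subjects, layers=("Dense1",))

    def test_separability_table(self, small_model_and_subjects):
        model, subjects = small_model_and_subjects
        table = layer_pe_table(model, subjects)
        sep = channel_separability(table)
        assert len(sep) == 3 * 4
        assert ((sep["p_value"] >= 0) & (sep["p_value"] <= 1)).all()
        counts = significant_channel_counts(sep, alpha=0.5)
        assert set(counts) == {"input", "Conv1", "Conv2"}
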