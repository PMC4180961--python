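import math

import numpy as np
import pytest

from cnvmech.dhs import (
    SpecificityTable,
    TissueDesign,
    WindowCountMatrix,
    call_cts_dhs,
    log_transform_normalize,
    pooled_within_tissue_sd,
    sample_distance_matrix,
    split_half_reproducibility,
    tissue_t_statistics,
    ubiquitous_ranking,
)
from cnvmech.genome import GenomicInterval
from cnvmech.simulate import SimulationConfig, generate_count_matrix


def _windows(n, width=200):
    return tuple(GenomicInterval("chrD", i * width, (i + 1) * width) for i in range(n))


def _matrix(counts):
    counts = np.asarray(counts)
    samples = tuple(f"s{i}" for i in range(counts.shape[1]))
    return WindowCountMatrix(_windows(counts.shape[0]), samples, counts)


def naive_pooled_sd(X, groups):
    """Independent two-pass textbook implementation, one window at a time."""
    out = []
    for w in range(X.shape[0]):
        num, dof = 0.0, 0
        for idx in groups.values():
            vals = [X[w, i] for i in idx]
            mean = sum(vals) / len(vals)
            num += sum((v - mean) ** 2 for v in vals)
            dof += len(vals) - 1
        out.append(math.sqrt(num / dof))
    return np.array(out)


def naive_t_stats(X, groups, s0=None):
    tissues = list(groups)
    m = len(tissues)
    s = naive_pooled_sd(X, groups)
    if s0 is None:
        s0 = s.mean()
    t = np.zeros((X.shape[0], m))
    for w in range(X.shape[0]):
        means = [sum(X[w, i] for i in groups[tis]) / len(groups[tis]) for tis in tissues]
        grand = sum(means) / m
        for j, tis in enumerate(tissues):
            n_j = len(groups[tis])
            t[w, j] = (means[j] - grand) / (math.sqrt(1 / m + 1 / n_j) * (s[w] + s0))
    return t


class TestLogTransformNormalize:
    def test_factor_one_leaves_column(self):
        m = _matrix([[10, 10], [10, 10]])
        X = log_transform_normalize(m)
        assert np.allclose(X, np.log(11))

    def test_depth_factors(self):
        # means 10 and 20 -> global mean 15 -> factors 1.5 and 0.75
        m = _matrix([[10, 20], [10, 20]])
        X = log_transform_normalize(m)
        assert np.allclose(X[:, 0], 1.5 * np.log(11))
        assert np.allclose(X[:, 1], 0.75 * np.log(21))

    def test_zero_count_pseudocount(self):
        m = _matrix([[0, 4], [8, 4]])
        X = log_transform_normalize(m)
        assert X[0, 0] == 0.0  # ln(0 + 1) = 0, unchanged by any factor

    def test_all_zero_sample_errors(self):
        m = _matrix([[0, 4], [0, 4]])
        with pytest.raises(ValueError, match="all-zero"):
            log_transform_normalize(m)

    def test_scale_before_log_variant(self):
        m = _matrix([[10, 20], [10, 20]])
        X = log_transform_normalize(m, scale_before_log=True)
        assert np.allclose(X[:, 0], np.log1p(10 * 1.5))
        assert np.allclose(X[:, 1], np.log1p(20 * 0.75))


DESIGN22 = TissueDesign({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})


class TestPooledSD:
    def test_constant_within_tissue_zero(self):
        X = np.array([[3.0, 3.0, 7.0, 7.0]])
        s = pooled_within_tissue_sd(X, DESIGN22.groups(("s0", "s1", "s2", "s3")))
        assert s[0] == 0.0

    def test_hand_computed_case(self):
        # tissue A: (3, 1), tissue B: (1, -1) -> s = sqrt(2)
        X = np.array([[3.0, 1.0, 1.0, -1.0]])
        s = pooled_within_tissue_sd(X, DESIGN22.groups(("s0", "s1", "s2", "s3")))
        assert s[0] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_singleton_tissue_errors(self):
        design = TissueDesign({"s0": "A", "s1": "B", "s2": "B"})
        X = np.zeros((2, 3))
        with pytest.raises(ValueError, match="1 sample"):
            pooled_within_tissue_sd(X, design.groups(("s0", "s1", "s2")))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 6))
        design = TissueDesign({f"s{i}": ("A", "B", "C")[i // 2] for i in range(6)})
        groups = design.groups(tuple(f"s{i}" for i in range(6)))
        assert np.allclose(
            pooled_within_tissue_sd(X, groups), naive_pooled_sd(X, groups), atol=1e-10
        )


class TestTStatistics:
    samples = ("s0", "s1", "s2", "s3")

    def test_flat_window_zero_t(self):
        X = np.array([[5.0, 5.0, 5.0, 5.0], [3.0, 1.0, 1.0, -1.0]])
        table = tissue_t_statistics(X, self.samples, DESIGN22)
        assert np.allclose(table.t_stats[0], 0.0)

    def test_hand_computed_single_window(self):
        # tissue means 2 and 0, grand 1, s = s0 = sqrt(2):
        # t_A = (2-1)/(sqrt(1/2+1/2) * 2*sqrt(2)) = 1/(2 sqrt 2) ~ 0.3536
        X = np.array([[3.0, 1.0, 1.0, -1.0]])
        table = tissue_t_statistics(X, self.samples, DESIGN22)
        assert table.s0 == pytest.approx(math.sqrt(2), abs=1e-12)
        assert table.t_stats[0, 0] == pytest.approx(1 / (2 * math.sqrt(2)), abs=1e-4)
        assert table.t_stats[0, 0] == pytest.approx(0.3536, abs=1e-4)

    def test_two_tissue_antisymmetry(self):
        X = np.array([[3.0, 1.0, 1.0, -1.0], [0.0, 1.0, 5.0, 6.0]])
        table = tissue_t_statistics(X, self.samples, DESIGN22)
        assert np.allclose(table.t_stats[:, 0], -table.t_stats[:, 1])

    def test_constant_matrix_errors(self):
        X = np.full((3, 4), 2.0)
        with pytest.raises(ValueError, match="s \\+ s0"):
            tissue_t_statistics(X, self.samples, DESIGN22)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(40, 6))
        design = TissueDesign({f"s{i}": ("A", "B", "C")[i // 2] for i in range(6)})
        samples = tuple(f"s{i}" for i in range(6))
        table = tissue_t_statistics(X, samples, design)
        expected = naive_t_stats(X, design.groups(samples))
        assert np.allclose(table.t_stats, expected, atol=1e-10)

    def test_monotone_in_raised_tissue(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        table0 = tissue_t_statistics(X, self.samples, DESIGN22)
        X2 = X.copy()
        X2[0, :2] += 1.0  # raise tissue A in window 0
        table1 = tissue_t_statistics(X2, self.samples, DESIGN22)
        assert table1.t_stats[0, 0] >= table0.t_stats[0, 0]


class TestRankings:
    def test_top_n_equals_window_count(self):
        X = np.array([[3.0, 1.0, 1.0, -1.0], [0.0, 0.5, 5.0, 6.0]])
        m = _matrix(np.ones((2, 4), dtype=int))
        table = tissue_t_statistics(X, m.samples, DESIGN22)
        assert len(call_cts_dhs(table, m.windows, "A", 2)) == 2

    def test_top_one_is_argmax(self):
        X = np.array([[0.0, 0.0, 1.0, 1.2], [5.0, 6.0, 0.0, 0.1]])
        m = _matrix(np.ones((2, 4), dtype=int))
        table = tissue_t_statistics(X, m.samples, DESIGN22)
        assert call_cts_dhs(table, m.windows, "A", 1)[0] == m.windows[1]

    def test_top_n_too_large_errors(self):
        X = np.array([[3.0, 1.0, 1.0, -1.0]])
        m = _matrix(np.ones((1, 4), dtype=int))
        table = tissue_t_statistics(X, m.samples, DESIGN22)
        with pytest.raises(ValueError, match="exceeds"):
            call_cts_dhs(table, m.windows, "A", 2)

    def test_ubiquitous_tie_break_by_order(self):
        X = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0], [2.0, 2.1, 0.0, 0.2]])
        m = _matrix(np.ones((3, 4), dtype=int))
        table = tissue_t_statistics(X, m.samples, DESIGN22)
        order = table.ubiquitous_order()
        # windows 0 and 1 tie on the grand mean -> broken by genomic order
        assert list(order) == [2, 0, 1]

    def test_ubiquitous_vs_cts_disjoint_on_pure_signal(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(20, size=(300, 4))
        counts = base.copy()
        counts[:20, :2] *= 8  # tissue-A specific, not ubiquitous
        counts[20:40, :] *= 8  # ubiquitously open
        m = _matrix(counts)
        X = log_transform_normalize(m)
        table = tissue_t_statistics(X, m.samples, DESIGN22)
        cts = {(w.start) for w in call_cts_dhs(table, m.windows, "A", 20)}
        ubiq = {(w.start) for w in ubiquitous_ranking(table, m.windows, 20)}
        assert len(cts & ubiq) <= 2


class TestSplitHalf:
    def test_duplicated_samples_identical_halves_ratio_one(self):
        # two distinct profiles per tissue, each duplicated; seed 1 splits one
        # copy of every profile into each half, so the halves are identical
        # and every top-n list is fully shared
        rng = np.random.default_rng(0)
        prof = rng.poisson(20, size=(200, 4))
        counts = np.column_stack(
            [prof[:, 0], prof[:, 1], prof[:, 0], prof[:, 1],
             prof[:, 2], prof[:, 3], prof[:, 2], prof[:, 3]]
        )
        m = _matrix(counts)
        design = TissueDesign({f"s{i}": ("A", "B")[i // 4] for i in range(8)})
        grid, ratios, _ = split_half_reproducibility(m, design, [10, 50, 100], seed=1)
        assert np.allclose(ratios, 1.0)

    def test_ratio_bounds(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.poisson(20, size=(300, 8)))
        design = TissueDesign({f"s{i}": ("A", "B")[i // 4] for i in range(8)})
        _, ratios, _ = split_half_reproducibility(m, design, [10, 100, 300], seed=2)
        assert np.all(ratios >= 0) and np.all(ratios <= 1)

    def test_pure_noise_ratio_near_n_over_w(self):
        # independent halves: expected overlap of two random top-n lists is n/W
        rng = np.random.default_rng(2)
        m = _matrix(rng.poisson(20, size=(500, 8)))
        design = TissueDesign({f"s{i}": ("A", "B")[i // 4] for i in range(8)})
        grid, ratios, _ = split_half_reproducibility(m, design, [250], seed=3)
        assert abs(ratios[0] - 0.5) < 0.15  # n/W = 250/500

    def test_single_sample_tissue_errors(self):
        m = _matrix(np.ones((10, 3), dtype=int))
        design = TissueDesign({"s0": "A", "s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="single sample"):
            split_half_reproducibility(m, design, [5], seed=0)

    def test_planted_signal_maximum_near_plant_count(self):
        config = SimulationConfig(
            seed=5, n_windows=3000, dhs_tissues=2, dhs_replicates=4,
            planted_per_tissue=500, log_effect=2.5,
        )
        m, design, _ = generate_count_matrix(config, np.random.default_rng(5))
        grid = [100, 250, 400, 500, 600, 800, 1200, 2000]
        _, ratios, n_max = split_half_reproducibility(m, design, grid, seed=6)
        assert 300 <= n_max <= 700


class TestBlacklist:
    def test_overlapping_windows_dropped(self):
        from cnvmech.dhs import apply_window_blacklist

        m = _matrix(np.arange(20).reshape(5, 4))
        filtered = apply_window_blacklist(
            m, [GenomicInterval("chrD", 250, 450)]  # touches windows 1 and 2
        )
        assert [w.start for w in filtered.windows] == [0, 600, 800]
        assert np.array_equal(filtered.counts, m.counts[[0, 3, 4], :])

    def test_empty_blacklist_noop(self):
        from cnvmech.dhs import apply_window_blacklist

        m = _matrix(np.ones((3, 4), dtype=int))
        filtered = apply_window_blacklist(m, [])
        assert filtered.windows == m.windows


class TestSampleDistance:
    def test_identical_columns_zero(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 2))
        d = sample_distance_matrix(X)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_two(self):
        x = np.arange(10.0)
        X = np.column_stack([x, -x])
        d = sample_distance_matrix(X)
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 5))
        d = sample_distance_matrix(X)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else 1 - np.corrcoef(X[:, i], X[:, j])[0, 1]
                assert d[i, j] == pytest.approx(expected, abs=1e-10)


class TestPlantedRecovery:
    def test_planted_windows_dominate_top_ranks(self):
        config = SimulationConfig(seed=7)  # 10k windows, 4x4, Poisson(20), effect 2
        m, design, truth = generate_count_matrix(config, np.random.default_rng(7))
        X = log_transform_normalize(m)
        table = tissue_t_statistics(X, m.samples, design)
        for tissue, planted in truth.items():
            top = set(table.ranking(tissue)[: len(planted)].tolist())
            recovered = len(top & set(planted)) / len(planted)
            assert recovered >= 0.95

    def test_zero_effect_t_centered(self):
        config = SimulationConfig(seed=9, n_windows=2000, log_effect=0.0)
        m, design, _ = generate_count_matrix(config, np.random.default_rng(9))
        X = log_transform_normalize(m)
        table = tissue_t_statistics(X, m.samples, design)
        assert abs(float(table.t_stats.mean())) < 0.05
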