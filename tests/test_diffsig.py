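"""Normalization, NB testing and multiplicity adjustment.

The NB Wald test is additionally cross-checked against DESeq2 (pydeseq2) as
an independent implementation on a small simulated matrix.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from marktempo.diffsig import (
    ALPHA_FLOOR,
    AnalysisThresholds,
    CountMatrix,
    NoSpikeInError,
    SampleMeta,
    bh_adjust,
    call_significant,
    differential_analysis,
    estimate_dispersion,
    nb_wald_test,
    size_factors_min_coverage,
    size_factors_spike_in,
)


def make_cm(counts, assay="H3K4me3", spike=None, timepoints=None):
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    tps = timepoints or [0.0] * n_samples
    samples = [
        SampleMeta(f"s{i}", assay, tps[i], i + 1, tps[i] > 0)
        for i in range(n_samples)
    ]
    ids = [f"site{i}" for i in range(counts.shape[0])]
    return CountMatrix(ids, samples, counts, spike)


class TestMinCoverageFactors:
    def test_equal_totals_give_unit_factors(self):
        cm = make_cm([[50, 50], [50, 50]])
        assert np.allclose(size_factors_min_coverage(cm), [1.0, 1.0])

    def test_double_coverage_halved(self):
        cm = make_cm([[50, 100], [50, 100]])
        assert np.allclose(size_factors_min_coverage(cm), [1.0, 0.5])

    def test_scaled_totals_all_equal_min(self, rng):
        counts = rng.integers(0, 500, size=(300, 5))
        counts[0] += 1  # guard against an all-zero column
        cm = make_cm(counts.tolist() + [[1] * 5])
        f = size_factors_min_coverage(cm)
        scaled = cm.counts.sum(axis=0) * f
        assert np.allclose(scaled, scaled.min())

    def test_row_permutation_invariant(self, rng):
        counts = rng.integers(1, 100, size=(50, 3))
        f1 = size_factors_min_coverage(make_cm(counts))
        f2 = size_factors_min_coverage(make_cm(counts[rng.permutation(50)]))
        assert np.allclose(f1, f2)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            size_factors_min_coverage(make_cm([[1, 0], [2, 0]]))

    def test_library_sizes_override_table_totals(self):
        counts = [[100, 10], [100, 10]]
        samples = [
            SampleMeta("a", "H3K4me3", 0.0, 1, False, library_size=1_000_000),
            SampleMeta("b", "H3K4me3", 2.0, 1, True, library_size=2_000_000),
        ]
        cm = CountMatrix(["x", "y"], samples, np.array(counts))
        assert np.allclose(size_factors_min_coverage(cm), [1.0, 0.5])


class TestSpikeInFactors:
    def _cm(self, spike_block, extra_rows=0):
        n_spike, n_samp = spike_block.shape
        gene = np.full((extra_rows, n_samp), 7)
        counts = np.vstack([gene, spike_block])
        spike = np.array([False] * extra_rows + [True] * n_spike)
        return make_cm(counts, assay="RNA", spike=spike)

    def test_identical_columns_give_unit_factors(self):
        block = np.tile(np.arange(10, 30)[:, None], (1, 4))
        f = size_factors_spike_in(self._cm(block))
        assert np.allclose(f, 1.0)

    def test_doubled_column_has_double_factor(self):
        base = np.arange(10, 30)
        block = np.stack([base, base, 2 * base], axis=1)
        f = size_factors_spike_in(self._cm(block))
        assert np.allclose(f[2] / f[0], 2.0)
        assert np.allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_invariant_to_non_spike_rows(self, rng):
        block = rng.poisson(300, size=(40, 3)) + 1
        f1 = size_factors_spike_in(self._cm(block, extra_rows=0))
        f2 = size_factors_spike_in(self._cm(block, extra_rows=25))
        assert np.allclose(f1, f2)

    def test_no_spike_rows_directs_to_min_coverage(self):
        cm = make_cm([[5, 5], [5, 5]], assay="RNA")
        with pytest.raises(NoSpikeInError, match="min_coverage"):
            size_factors_spike_in(cm)

    def test_true_factors_recovered_within_two_percent(self, rng):
        true = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=4))
        means = 500.0 * np.exp(rng.normal(0.0, 0.5, size=92))
        block = rng.poisson(means[:, None] * true[None, :])
        est = size_factors_spike_in(self._cm(block))
        true_rescaled = true / np.exp(np.mean(np.log(true)))
        assert np.all(np.abs(est / true_rescaled - 1.0) < 0.02)


class TestDispersion:
    def test_poisson_like_row_hits_floor(self):
        row = np.array([100, 100, 100, 100])
        assert estimate_dispersion(row) == ALPHA_FLOOR

    def test_moment_formula(self):
        # mean 100, variance 1100 -> (1100 - 100) / 100^2 = 0.1
        row = np.array([100 - np.sqrt(550), 100 + np.sqrt(550)])
        assert np.isclose(estimate_dispersion(row), 0.1)

    def test_nb_rows_recovered_within_thirty_percent(self, rng):
        alpha, mu, n_samp = 0.05, 400.0, 50
        n = 1 / alpha
        rows = rng.negative_binomial(n, n / (n + mu), size=(300, n_samp))
        est = np.median([estimate_dispersion(r) for r in rows])
        assert abs(est - alpha) / alpha < 0.30


class TestNbWaldTest:
    def test_identical_groups_give_zero_lfc(self):
        y = np.full((3, 4), 80)
        res = nb_wald_test(y[:, 2:], y[:, :2], np.ones(2), np.ones(2), 0.05)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.all(res["p"] > 0.9)

    def test_all_zero_site_flagged_untestable(self):
        y = np.zeros((1, 6))
        res = nb_wald_test(y[:, 3:], y[:, :3], np.ones(3), np.ones(3), 0.05)
        assert bool(res["untestable"][0])
        assert res["p"][0] == 1.0 and res["log2fc"][0] == 0.0

    @pytest.mark.parametrize("alpha", [0.01, 0.1])
    def test_null_rejection_rate_calibrated(self, alpha):
        rng = np.random.default_rng(7)
        n = 1 / alpha
        y = rng.negative_binomial(n, n / (n + 200.0), size=(20000, 6))
        res = nb_wald_test(y[:, 3:], y[:, :3], np.ones(3), np.ones(3), alpha)
        rate = float((res["p"] < 0.05).mean())
        assert 0.035 <= rate <= 0.065

    def test_fourfold_depletion_recovered(self):
        rng = np.random.default_rng(3)
        n = 1 / 0.05
        c = rng.negative_binomial(n, n / (n + 500.0), size=(5000, 3))
        t = rng.negative_binomial(n, n / (n + 125.0), size=(5000, 3))
        res = nb_wald_test(t, c, np.ones(3), np.ones(3), 0.05)
        assert abs(np.median(res["log2fc"]) - (-2.0)) < 0.15

    def test_power_monotone_in_effect_and_replicates(self):
        rng = np.random.default_rng(9)
        alpha = 0.05
        n = 1 / alpha

        def rejection(fold, reps):
            c = rng.negative_binomial(n, n / (n + 300.0), size=(3000, reps))
            t = rng.negative_binomial(n, n / (n + 300.0 / fold), size=(3000, reps))
            res = nb_wald_test(t, c, np.ones(reps), np.ones(reps), alpha)
            return float((res["p"] < 0.05).mean())

        assert rejection(1.0, 3) < rejection(1.5, 3) < rejection(3.0, 3)
        assert rejection(1.5, 2) < rejection(1.5, 6)

    def test_size_factors_shift_inference_not_biology(self):
        rng = np.random.default_rng(5)
        n = 1 / 0.05
        base = rng.negative_binomial(n, n / (n + 400.0), size=(2000, 2))
        deep = rng.negative_binomial(n, n / (n + 800.0), size=(2000, 2))
        res = nb_wald_test(deep, base, np.full(2, 2.0), np.ones(2), 0.05)
        assert abs(np.median(res["log2fc"])) < 0.1


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert np.allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_stepup_by_hand(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_nan_propagates_and_is_excluded_from_ranks(self):
        p = np.array([0.01, np.nan, 0.02])
        q = bh_adjust(p)
        assert np.isnan(q[1])
        # with the NaN excluded, m = 2
        assert np.allclose(q[[0, 2]], bh_adjust(np.array([0.01, 0.02])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_matches_hand_coded_stepup_on_permutations(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                prev = min(prev, p[i] * m / rank_from_top)
                q[i] = prev
            return q

        base = np.array([0.001, 0.011, 0.02, 0.35, 0.6, 0.93])
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            assert np.allclose(bh_adjust(p), oracle(p))


class TestCallSignificant:
    th = AnalysisThresholds()

    @pytest.mark.parametrize(
        "lfc,q,expected",
        [
            (-0.60, 0.01, "loss"),
            (-0.50, 0.001, "none"),  # fails the fold-change bound
            (0.70, 0.20, "none"),    # fails the q bound
            (0.59, 0.049, "gain"),
            (0.58, 0.01, "none"),    # bound is strict
        ],
    )
    def test_threshold_rule(self, lfc, q, expected):
        dt = pd.DataFrame({"log2fc": [lfc], "q": [q]})
        assert call_significant(dt, self.th)["call"].iloc[0] == expected

    def test_requires_q_column(self):
        with pytest.raises(ValueError):
            call_significant(pd.DataFrame({"log2fc": [0.0]}), self.th)


class TestDifferentialAnalysis:
    def test_contrast_detects_planted_losses(self, rng):
        n_sites = 400
        base = rng.lognormal(np.log(200), 0.3, n_sites)
        lost = np.zeros(n_sites, dtype=bool)
        lost[:100] = True
        mu_t = np.where(lost, base / 4.0, base)
        n = 1 / 0.05
        counts = np.column_stack(
            [rng.negative_binomial(n, n / (n + base)) for _ in range(2)]
            + [rng.negative_binomial(n, n / (n + mu_t)) for _ in range(2)]
        )
        cm = make_cm(counts, timepoints=[0.0, 0.0, 2.0, 2.0])
        dt = differential_analysis(cm, 2.0)
        calls = dt["call"].to_numpy()
        assert (calls[:100] == "loss").mean() > 0.8
        assert (calls[100:] == "loss").mean() < 0.05

    def test_matches_deseq2_on_small_matrix(self, rng):
        """Independent cross-check: log2FC agrees with pydeseq2's estimates."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        n_sites = 150
        base = rng.lognormal(np.log(300), 0.4, n_sites)
        fold = np.exp2(rng.normal(0.0, 1.0, n_sites))
        n = 1 / 0.05
        counts = np.column_stack(
            [rng.negative_binomial(n, n / (n + base)) for _ in range(3)]
            + [rng.negative_binomial(n, n / (n + base * fold)) for _ in range(3)]
        )
        res = nb_wald_test(
            counts[:, 3:], counts[:, :3], np.ones(3), np.ones(3), 0.05
        )

        metadata = pd.DataFrame(
            {"condition": ["ctrl"] * 3 + ["trt"] * 3},
            index=[f"s{i}" for i in range(6)],
        )
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts.T, index=metadata.index),
            metadata=metadata,
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "trt", "ctrl"], quiet=True)
        stats.summary()
        ref_lfc = stats.results_df["log2FoldChange"].to_numpy()

        r = np.corrcoef(res["log2fc"], ref_lfc)[0, 1]
        assert r > 0.95
        assert np.median(np.abs(res["log2fc"] - ref_lfc)) < 0.2
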