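import numpy as np
import pytest

from secom import (
    CountTable,
    bias_correct,
    bias_correct_multi,
    build_presence_mask,
    center_log_counts,
    estimate_sampling_fraction_simple,
    estimate_sampling_fraction_weighted,
    pearson_cca,
    simulate_linear,
)
from secom.bias_correction import BiasCorrectionError

from conftest import random_count_table


class TestPresenceMask:
    def test_diagonal_pattern_flags_empty_pair(self):
        t = CountTable(np.array([[0, 2], [3, 0]]), ["A", "B"], ["S1", "S2"])
        with pytest.warns(UserWarning, match="never observed together"):
            m = build_presence_mask(t)
        np.testing.assert_array_equal(m.mask, [[False, True], [True, False]])
        assert m.n_of_lm[0, 1] == 0
        assert m.empty_pairs[0, 1]

    def test_all_positive_mask(self):
        t = CountTable(np.ones((3, 4), dtype=int), list("ABC"), list("wxyz"))
        m = build_presence_mask(t)
        assert m.mask.all()
        assert (m.n_of_lm == 4).all()

    def test_pairwise_counts_match_brute_force(self, rng):
        table = random_count_table(rng, d=20, n=10, zero_frac=0.5)
        m = build_presence_mask(table)
        for l in range(20):
            for k in range(20):
                expected = sum(
                    1 for i in range(10)
                    if table.counts[l, i] > 0 and table.counts[k, i] > 0
                )
                assert m.n_of_lm[l, k] == expected
        assert m.d_of_i.sum() == np.count_nonzero(table.counts)


class TestCenterLogCounts:
    def test_worked_arithmetic(self):
        e = np.e
        counts = np.rint(np.array([[e, e, e**2]]) * 1e6).astype(int)
        t = CountTable(counts, ["A"], ["S1", "S2", "S3"])
        resid, _ = center_log_counts(t, build_presence_mask(t))
        np.testing.assert_allclose(resid[0], [-1 / 3, -1 / 3, 2 / 3], atol=1e-6)

    def test_taxon_scaling_invariance(self, random_table):
        mask = build_presence_mask(random_table)
        r1, _ = center_log_counts(random_table, mask)
        scaled = CountTable(
            random_table.counts * np.array([1, 1000] + [1] * 10)[:, None],
            random_table.taxon_ids, random_table.sample_ids,
        )
        r2, _ = center_log_counts(scaled, build_presence_mask(scaled))
        np.testing.assert_allclose(r1[np.isfinite(r1)], r2[np.isfinite(r2)], atol=1e-12)

    def test_matches_masked_recomputation(self, rng):
        table = random_count_table(rng, d=15, n=12, zero_frac=0.3)
        mask = build_presence_mask(table)
        resid, means = center_log_counts(table, mask)
        for j in range(15):
            obs = table.counts[j] > 0
            logs = np.log(table.counts[j, obs].astype(float))
            assert means[j] == pytest.approx(logs.mean())
            np.testing.assert_allclose(resid[j, obs], logs - logs.mean(), atol=1e-12)
            assert np.all(np.isnan(resid[j, ~obs]))


class TestSamplingFraction:
    def test_scale_profile_identity(self):
        # O_ij = k_i * P_j exactly: the estimator recovers centered log k
        k = np.array([1.0, 10.0, 100.0, 2.0])
        P = np.array([40.0, 400.0, 4000.0])
        counts = np.rint(np.outer(P, k)).astype(int)
        t = CountTable(counts, list("ABC"), list("wxyz"))
        mask = build_presence_mask(t)
        resid, _ = center_log_counts(t, mask)
        est = estimate_sampling_fraction_simple(resid, mask)
        expected = np.log(k) - np.log(k).mean()
        np.testing.assert_allclose(est.s_centered, expected, atol=1e-10)
        # equal residual variances: weighted estimator coincides
        w = estimate_sampling_fraction_weighted(resid, mask)
        np.testing.assert_allclose(w.s_centered, expected, atol=1e-8)

    def test_identical_columns_give_zero(self):
        t = CountTable(np.tile([[3], [7], [11]], (1, 4)), list("ABC"), list("wxyz"))
        mask = build_presence_mask(t)
        resid, _ = center_log_counts(t, mask)
        np.testing.assert_allclose(
            estimate_sampling_fraction_simple(resid, mask).s_centered, 0.0, atol=1e-12
        )

    def test_simple_estimator_hand_computation_with_zero(self):
        counts = np.array([[2, 4, 8], [3, 9, 27], [0, 5, 25]])
        t = CountTable(counts, list("ABC"), list("xyz"))
        mask = build_presence_mask(t)
        resid, _ = center_log_counts(t, mask)
        est = estimate_sampling_fraction_simple(resid, mask)
        logs = np.log(counts.astype(float))
        means = [logs[0].mean(), logs[1].mean(), logs[2, 1:].mean()]
        raw = np.array([
            ((logs[0, 0] - means[0]) + (logs[1, 0] - means[1])) / 2,
            ((logs[0, 1] - means[0]) + (logs[1, 1] - means[1]) + (logs[2, 1] - means[2])) / 3,
            ((logs[0, 2] - means[0]) + (logs[1, 2] - means[1]) + (logs[2, 2] - means[2])) / 3,
        ])
        np.testing.assert_allclose(est.s_centered, raw - raw.mean(), atol=1e-12)

    def test_weighted_inverse_variance_weights(self):
        # residual variances (1, 4) -> pairwise normalized weights (0.8, 0.2)
        rng = np.random.default_rng(5)
        n, d = 400, 40
        sds = np.tile([1.0, 2.0], 20)
        resid = rng.normal(0, 1.0, (d, n)) * sds[:, None]
        counts = np.rint(np.exp(8 + resid)).astype(int)
        t = CountTable(counts, [f"T{j}" for j in range(d)], [f"S{i}" for i in range(n)])
        mask = build_presence_mask(t)
        resid, _ = center_log_counts(t, mask)
        est = estimate_sampling_fraction_weighted(resid, mask)
        pair = est.weights[0] / (est.weights[0] + est.weights[1])
        assert pair == pytest.approx(0.8, abs=0.05)

    def test_empty_sample_raises(self):
        t = CountTable(np.array([[1, 0], [1, 0]]), ["A", "B"], ["S1", "S2"])
        mask = build_presence_mask(t)
        mask.d_of_i[1] = 0
        resid = np.full((2, 2), np.nan)
        resid[:, 0] = 0.0
        with pytest.raises(BiasCorrectionError, match="zero observed taxa"):
            estimate_sampling_fraction_simple(resid, mask)


class TestBiasCorrect:
    @pytest.mark.parametrize("method", ["simple", "weighted"])
    def test_sample_bias_invariance(self, rng, method):
        # exact invariance holds when every taxon is observed in every sample;
        # with zeros, a sample's bias leaks through the observed-only means
        table = random_count_table(rng, d=12, n=9, zero_frac=0.0)
        base = bias_correct(table, method=method)
        scaled = CountTable(
            table.counts * np.array([1, 100, 1, 7, 1, 1, 13, 1, 1])[None, :],
            table.taxon_ids, table.sample_ids,
        )
        out = bias_correct(scaled, method=method)
        np.testing.assert_allclose(base.y_hat, out.y_hat, atol=1e-10)

    @pytest.mark.parametrize("method", ["simple", "weighted"])
    def test_taxon_bias_invariance(self, random_table, method):
        base = bias_correct(random_table, method=method)
        mult = np.ones(random_table.n_taxa, dtype=int)
        mult[[1, 4, 7]] = [100, 3, 21]
        scaled = CountTable(
            random_table.counts * mult[:, None],
            random_table.taxon_ids, random_table.sample_ids,
        )
        out = bias_correct(scaled, method=method)
        np.testing.assert_allclose(
            base.y_hat[np.isfinite(base.y_hat)],
            out.y_hat[np.isfinite(out.y_hat)], atol=1e-10,
        )

    def test_noise_free_model_recovers_true_correlations(self):
        # a two-taxon latent correlation survives bias correction when the
        # count layer is exact (no NB noise, no rounding error)
        rng = np.random.default_rng(11)
        n, d, rho = 200, 30, 0.85
        z = rng.standard_normal((d, n))
        z[1] = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        a = 8.0 + z
        s = rng.uniform(-1.5, 0, n)
        c = rng.uniform(-1, 1, d)
        counts = np.rint(np.exp(a + s[None, :] + c[:, None]) * 1e3).astype(int)
        t = CountTable(counts, [f"T{j}" for j in range(d)], [f"S{i}" for i in range(n)])
        y = bias_correct(t, method="weighted")
        est = pearson_cca(y)
        true_corr = np.corrcoef(a[0], a[1])[0, 1]
        assert est.estimate[0, 1] == pytest.approx(true_corr, abs=0.02)

    def test_consistency_trend_in_n(self):
        """Sup-norm error of the correlation estimate shrinks as n grows."""
        errors = {}
        for n in (25, 50, 100, 200):
            errs = []
            for seed in range(3):
                t, truth = simulate_linear(
                    n=n, d=20, dispersion=0.1, n_corr_pairs=5, rho=0.8,
                    seed=900 + seed,
                )
                est = pearson_cca(bias_correct(t))
                errs.append(np.max(np.abs(est.estimate - truth.R0)))
            errors[n] = float(np.median(errs))
        assert errors[200] < errors[25]
        assert errors[100] < errors[25]


class TestMultiEcosystem:
    @staticmethod
    def _two_eco_table(rng, d=8, n=30):
        counts_a = random_count_table(rng, d=d, n=n, zero_frac=0.2).counts
        counts_b = random_count_table(rng, d=d, n=n, zero_frac=0.2).counts
        subjects = [f"p{i}" for i in range(n)]
        return CountTable(
            np.hstack([counts_a, counts_b]),
            [f"T{j}" for j in range(d)],
            [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
            ecosystem=["A"] * n + ["B"] * n,
            subject=subjects + subjects,
        )

    def test_single_ecosystem_reduces_to_bias_correct(self, random_table):
        single = bias_correct(random_table)
        multi = bias_correct_multi(random_table)
        np.testing.assert_array_equal(
            np.isfinite(single.y_hat), np.isfinite(multi.y_hat)
        )
        np.testing.assert_allclose(
            single.y_hat[np.isfinite(single.y_hat)],
            multi.y_hat[np.isfinite(multi.y_hat)], atol=1e-12,
        )

    def test_within_ecosystem_block_coherence(self, rng):
        """Within-site correlations are identical computed alone or concatenated."""
        table = self._two_eco_table(rng)
        d = 8
        multi = bias_correct_multi(table)
        est_multi = pearson_cca(multi, min_overlap=3)
        idx_a = [i for i, e in enumerate(table.ecosystem) if e == "A"]
        alone = bias_correct(table.select_samples(idx_a))
        est_alone = pearson_cca(alone, min_overlap=3)
        np.testing.assert_allclose(
            est_multi.estimate[:d, :d], est_alone.estimate, atol=1e-12
        )

    def test_duplicated_scaled_ecosystem_gives_cross_correlation_one(self, rng):
        base = random_count_table(rng, d=6, n=25, zero_frac=0.0)
        factors = rng.integers(2, 30, size=25)
        counts_b = base.counts * factors[None, :]
        n = 25
        table = CountTable(
            np.hstack([base.counts, counts_b]),
            base.taxon_ids,
            [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
            ecosystem=["A"] * n + ["B"] * n,
            subject=[f"p{i}" for i in range(n)] * 2,
        )
        est = pearson_cca(bias_correct_multi(table), min_overlap=3)
        for j in range(6):
            assert est.estimate[j, 6 + j] == pytest.approx(1.0, abs=1e-8)

    def test_missing_subject_column_raises(self, rng):
        table = self._two_eco_table(rng)
        table.subject = None
        with pytest.raises(BiasCorrectionError, match="subject"):
            bias_correct_multi(table)

    def test_disjoint_subjects_warn(self, rng):
        table = self._two_eco_table(rng, n=10)
        table.subject = [f"x{i}" for i in range(10)] + [f"y{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="no subjects shared"):
            bias_correct_multi(table)
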