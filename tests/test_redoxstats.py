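"""Log2-fold pixel statistics, binned maximum-likelihood fits, the
excess-pixel-count estimator and direction calls."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from retscope import redoxstats as rx
from retscope.redoxstats import (
    LogFoldHistogram,
    cell_delta_f_over_f0,
    call_bulk_trace,
    classify_direction,
    direction_threshold,
    excess_oxidised_fraction,
    expected_counts,
    fit_null,
    fit_two_normals,
    per_mito_dnadh,
    pixel_log2fold,
)


class TestPixelLog2Fold:
    def test_equal_frames_all_zero(self):
        f = np.full((32, 32), 50.0)
        h = pixel_log2fold(f, f, np.ones_like(f, dtype=bool))
        assert np.all(h.values == 0.0)

    def test_doubling_gives_one(self):
        f = np.full((32, 32), 50.0)
        h = pixel_log2fold(f, 2 * f, np.ones_like(f, dtype=bool), eps=0.0)
        np.testing.assert_allclose(h.values, 1.0)

    def test_mock_pair_mean_near_zero(self):
        rng = np.random.default_rng(0)
        s = np.full((64, 64), 200.0)
        a = s + rng.normal(0, 10, s.shape)
        b = s + rng.normal(0, 10, s.shape)
        h = pixel_log2fold(a, b, np.ones_like(s, dtype=bool))
        se = h.values.std() / math.sqrt(h.values.size)
        assert abs(h.values.mean()) < 2 * se + 1e-4

    def test_empty_mask_rejected(self):
        f = np.ones((8, 8))
        with pytest.raises(ValueError, match="mask"):
            pixel_log2fold(f, f, np.zeros_like(f, dtype=bool))


class TestCellDeltaF:
    def test_identity_and_scaling(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[:8] = 1
        labels[8:] = 2
        before = np.full((16, 16), 40.0)
        tab = cell_delta_f_over_f0(before, before * 1.5, labels)
        np.testing.assert_allclose(tab["dff"], 0.5)
        tab0 = cell_delta_f_over_f0(before, before, labels)
        np.testing.assert_allclose(tab0["dff"], 0.0)

    def test_global_uncoupler_like_decrease(self):
        """A global 50% decrease (maximal oxidation) reads as -0.5 per
        cell up to noise."""
        rng = np.random.default_rng(4)
        labels = np.repeat(np.arange(1, 9), 32 * 4).reshape(32, 32)
        before = rng.normal(200, 10, (32, 32)).clip(1)
        after = 0.5 * before + rng.normal(0, 5, (32, 32))
        tab = cell_delta_f_over_f0(before, after, labels)
        assert np.allclose(tab["dff"], -0.5, atol=0.05)

    def test_zero_baseline_cell_excluded(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[:4] = 1
        labels[4:] = 2
        before = np.zeros((8, 8))
        before[4:] = 10.0
        tab = cell_delta_f_over_f0(before, before + 1, labels)
        assert tab["cell"].tolist() == [2]


class TestFitNull:
    def test_recovers_gaussian_parameters(self):
        rng = np.random.default_rng(0)
        h = LogFoldHistogram.from_values(rng.normal(0.0, 0.2, 100_000),
                                         bin_width=0.05, source="mock")
        fit = fit_null(h)
        assert fit.mu0 == pytest.approx(0.0, abs=0.005)
        assert fit.sigma0 == pytest.approx(0.2, abs=0.005)

    def test_binned_fit_matches_unbinned_mle(self):
        """The binned estimate agrees with the direct (unbinned) MLE
        to within a tenth of the bin width."""
        rng = np.random.default_rng(1)
        x = rng.normal(0.13, 0.22, 20_000)
        h = LogFoldHistogram.from_values(x, bin_width=0.05)
        fit = fit_null(h)
        assert abs(fit.mu0 - x.mean()) < 0.05 / 10
        assert abs(fit.sigma0 - x.std()) < 0.05 / 10

    def test_fine_binning_locates_offset(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 0.05, 50_000)
        h = LogFoldHistogram.from_values(x, bin_width=0.01)
        assert fit_null(h).mu0 == pytest.approx(0.3, abs=0.002)

    def test_degenerate_histogram_rejected(self):
        h = LogFoldHistogram(
            bin_edges=np.array([0.0, 0.1, 0.2]), counts=np.array([0, 500]),
            n_pixels=500,
        )
        with pytest.raises(ValueError, match="degenerate|single"):
            fit_null(h)


class TestFitTwoNormals:
    def test_mixture_recovery(self):
        """0.26/0.74 mixture split by log2(1.5) recovered within 0.02."""
        rng = np.random.default_rng(0)
        n, s0 = 100_000, 0.2
        resp = rng.random(n) < 0.74
        x = np.where(resp, rng.normal(math.log2(1.5), s0, n), rng.normal(0, s0, n))
        fit = fit_two_normals(LogFoldHistogram.from_values(x, bin_width=0.05), s0)
        assert fit.w_resp == pytest.approx(0.74, abs=0.02)
        assert fit.mu_resp == pytest.approx(math.log2(1.5), abs=0.02)

    def test_single_component_degeneracy(self):
        """Data from one Gaussian: the two-component fit collapses (tiny
        responder weight or coincident means) and matches the single fit."""
        rng = np.random.default_rng(1)
        s0 = 0.2
        x = rng.normal(0.0, s0, 50_000)
        h = LogFoldHistogram.from_values(x, bin_width=0.05)
        two = fit_two_normals(h, s0)
        assert two.w_resp < 0.05 or (two.mu_resp - two.mu_nonresp) < 0.05
        one = fit_null(h)
        # the fitted total density explains the data about as well
        assert two.log_likelihood >= one.log_likelihood - 5.0

    def test_constrained_fit_no_better_than_free_sigma(self):
        """Fixing sigma to the wrong value cannot beat the fit at the
        maximum-likelihood sigma (nested models)."""
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 0.2, 30_000)
        h = LogFoldHistogram.from_values(x, bin_width=0.05)
        free = fit_null(h)  # sigma at its MLE
        constrained = fit_two_normals(h, sigma0=0.3)
        assert constrained.log_likelihood <= free.log_likelihood + 1e-6

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.2, 0.15, 5_000)
        fit = fit_two_normals(LogFoldHistogram.from_values(x), 0.15)
        assert fit.w_nonresp + fit.w_resp == pytest.approx(1.0)


class TestExcessFraction:
    def _model_histogram(self, fit, edges, n):
        p = fit.w_nonresp * np.diff(norm.cdf((edges - fit.mu_nonresp) / fit.sigma))
        p = p + fit.w_resp * np.diff(norm.cdf((edges - fit.mu_resp) / fit.sigma))
        counts = np.round(n * p / p.sum()).astype(int)
        return LogFoldHistogram(
            bin_edges=edges, counts=counts, n_pixels=int(counts.sum())
        )

    def test_data_equal_to_model_gives_zero(self):
        from retscope.redoxstats import NullFit, TwoComponentFit

        fit = TwoComponentFit(
            w_nonresp=0.3, w_resp=0.7, mu_nonresp=0.0, mu_resp=0.585,
            sigma=0.2, log_likelihood=0.0,
        )
        edges = np.arange(-1.5, 1.55, 0.05)
        h = self._model_histogram(fit, edges, 100_000)
        null = NullFit(mu0=0.0, sigma0=0.2, log_likelihood=0.0)
        est = excess_oxidised_fraction(h, fit, null)
        assert est.fraction < 5e-4

    def test_injected_left_tail_counted(self):
        from retscope.redoxstats import NullFit, TwoComponentFit

        fit = TwoComponentFit(
            w_nonresp=0.3, w_resp=0.7, mu_nonresp=0.0, mu_resp=0.585,
            sigma=0.2, log_likelihood=0.0,
        )
        edges = np.arange(-4.0, 1.55, 0.05)
        h = self._model_histogram(fit, edges, 95_000)
        # inject 5000 strongly oxidised pixels far below the threshold
        counts = h.counts.copy()
        counts[10] += 5_000
        h2 = LogFoldHistogram(bin_edges=edges, counts=counts,
                              n_pixels=int(counts.sum()))
        null = NullFit(mu0=0.0, sigma0=0.2, log_likelihood=0.0)
        est = excess_oxidised_fraction(h2, fit, null)
        assert est.fraction == pytest.approx(0.05, abs=0.005)

    def test_invalid_k_rejected(self):
        from retscope.redoxstats import NullFit, TwoComponentFit

        fit = TwoComponentFit(0.5, 0.5, 0.0, 0.5, 0.2, 0.0)
        null = NullFit(0.0, 0.2, 0.0)
        h = LogFoldHistogram.from_values(np.zeros(10) + 0.01)
        with pytest.raises(ValueError):
            excess_oxidised_fraction(h, fit, null, k=0.0)


class TestDirectionCalls:
    def test_zero_delta_is_stalled(self):
        calls = classify_direction(np.array([0.0]), threshold=0.1)
        assert calls[0].call == "stalled"

    def test_three_way_calls(self):
        calls = classify_direction(np.array([0.5, -0.5, 0.05]), threshold=0.1)
        assert [c.call for c in calls] == ["fet", "ret", "stalled"]

    def test_threshold_from_repeated_determinations(self):
        rng = np.random.default_rng(0)
        repeated = rng.normal(0.0, 0.3, size=(500, 3))
        thr = direction_threshold(repeated, c=1.5)
        # average SE of a 3-repeat mean, times 1.5
        expected = 1.5 * 0.3 / math.sqrt(3)
        assert thr == pytest.approx(expected, rel=0.15)

    def test_single_determination_demands_explicit_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            direction_threshold(np.zeros((10, 1)))

    def test_bulk_monotone_decay_called_ret(self):
        """A slow post-challenge decay of the redox trace is the reverse
        transport diagnostic."""
        t = np.linspace(0, 10, 50)
        trace = np.where(t < 5, 80.0, 80.0 * np.exp(-0.2 * (t - 5)))
        assert call_bulk_trace(trace, challenge_index=25, threshold=5.0) == "ret"

    def test_bulk_rise_called_fet(self):
        t = np.linspace(0, 10, 50)
        trace = np.where(t < 5, 50.0, 50.0 + 30 * (1 - np.exp(-(t - 5))))
        assert call_bulk_trace(trace, challenge_index=25, threshold=5.0) == "fet"


class TestPerMitoDnadh:
    def test_trivial_values(self):
        out = per_mito_dnadh(np.array([0.0, 100.0]), population_mean_pre=100.0)
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_dim_objects_stay_finite(self):
        """Population-mean normalization keeps values finite for
        near-zero-baseline objects."""
        rng = np.random.default_rng(0)
        delta = rng.normal(0, 30.0, 1000)  # some strongly negative
        out = per_mito_dnadh(delta, population_mean_pre=50.0)
        assert np.all(np.isfinite(out))

    def test_symmetric_deltas_symmetric_values(self):
        out = per_mito_dnadh(np.array([-20.0, 20.0]), 100.0)
        assert out[0] == pytest.approx(math.log2(0.8))
        assert out[1] == pytest.approx(math.log2(1.2))

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            per_mito_dnadh(np.zeros(3), 0.0)


class TestPooling:
    def test_pool_mean_and_se(self):
        mean, se = rx.pool_fractions([0.1, 0.2, 0.3])
        assert mean == pytest.approx(0.2)
        assert se == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1) / math.sqrt(3))

    def test_single_cell_has_nan_se(self):
        mean, se = rx.pool_fractions([0.1])
        assert math.isnan(se)
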