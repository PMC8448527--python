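import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparklet._errors import ParameterError
from sparklet.gating_sim import GatingParams, RenderParams, render_trace, simulate_open_counts
from sparklet.quantal import (
    IdealizedTrace,
    QuantalModel,
    SiteConfig,
    analyze_site,
    build_histogram,
    compute_npo,
    fit_multi_gaussian,
    global_quantal_model,
    idealize,
    sites_per_cell,
)
from sparklet.trace_ops import FluorescenceTrace


def _trace(values, fs=30.0):
    return FluorescenceTrace(np.asarray(values, dtype=float), fs)


class TestBuildHistogram:
    def test_constant_trace_single_bin(self):
        hist = build_histogram(_trace([1.0, 1.0, 1.0] * 10), bin_width=0.1)
        assert hist.counts.size == 1
        assert hist.counts[0] == 30

    def test_counts_sum_conservation(self):
        rng = np.random.default_rng(0)
        trace = _trace(rng.normal(1.0, 0.05, 500))
        hist = build_histogram(trace)
        assert hist.counts.sum() == 500

    @given(n=st.integers(min_value=10, max_value=200), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_counts_sum_property(self, n, seed):
        rng = np.random.default_rng(seed)
        hist = build_histogram(_trace(1.0 + 0.1 * rng.standard_normal(n)))
        assert hist.counts.sum() == n

    def test_short_trace_warns(self):
        with pytest.warns(UserWarning):
            build_histogram(_trace([1.0, 1.1, 1.2]))

    def test_two_level_modes_separated_by_q(self):
        rng = np.random.default_rng(3)
        q = 0.29
        levels = rng.random(4000) < 0.4
        v = 1.0 + q * levels + rng.normal(0, 0.02, 4000)
        hist = build_histogram(_trace(v))
        # mode-finding oracle: modes of the two halves of the histogram
        centers, counts = hist.centers, hist.counts
        split = np.searchsorted(centers, 1.0 + q / 2)
        mode_lo = centers[np.argmax(counts[:split])]
        mode_hi = centers[split + np.argmax(counts[split:])]
        assert abs((mode_hi - mode_lo) - q) <= hist.bin_width

    def test_bad_bin_params(self):
        with pytest.raises(ParameterError):
            build_histogram(_trace(np.linspace(1, 2, 50)), bin_width=-0.1)
        with pytest.raises(ParameterError):
            build_histogram(_trace(np.linspace(1, 2, 50)), n_bins=0)


class TestFitMultiGaussian:
    def test_single_gaussian_baseline_only(self):
        rng = np.random.default_rng(1)
        n, mu, sd = 4000, 1.0, 0.03
        hist = build_histogram(_trace(rng.normal(mu, sd, n)))
        model = fit_multi_gaussian(hist)
        assert model.n_levels == 0
        assert model.quantal_amplitude is None
        assert abs(model.baseline_mean - mu) <= 2 * sd / np.sqrt(n)

    def test_two_equal_gaussians_recover_spacing(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(1.00, 0.03, 3000), rng.normal(1.29, 0.03, 3000)])
        model = fit_multi_gaussian(build_histogram(_trace(v)))
        assert model.n_levels >= 1
        assert model.quantal_amplitude == pytest.approx(0.29, abs=0.01)

    def test_areas_normalized(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(1.00, 0.03, 3000), rng.normal(1.29, 0.03, 1500)])
        model = fit_multi_gaussian(build_histogram(_trace(v)))
        assert model.areas.sum() == pytest.approx(1.0, rel=0.05)

    def test_unconstrained_fit_mean_spacing(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(1.00, 0.03, 3000), rng.normal(1.30, 0.03, 2000)])
        model = fit_multi_gaussian(build_histogram(_trace(v)), equal_spacing=False)
        assert model.quantal_amplitude == pytest.approx(0.30, abs=0.02)
        assert np.all(np.diff(model.means) > 0)

    def test_forced_n_levels(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(1.00, 0.03, 3000), rng.normal(1.29, 0.03, 3000)])
        model = fit_multi_gaussian(build_histogram(_trace(v)), n_levels=1)
        assert model.n_levels == 1

    def test_equal_spacing_means_exact(self):
        rng = np.random.default_rng(7)
        v = np.concatenate(
            [rng.normal(1.0, 0.03, 3000), rng.normal(1.29, 0.03, 1200), rng.normal(1.58, 0.03, 400)]
        )
        model = fit_multi_gaussian(build_histogram(_trace(v)))
        q, mu0 = model.quantal_amplitude, model.baseline_mean
        np.testing.assert_allclose(model.means, mu0 + q * np.arange(model.n_components))


class TestIdealize:
    def test_noise_free_exact(self, noisefree_site):
        truth, trace = noisefree_site
        model = global_quantal_model(trace, q=0.29)
        ideal = idealize(trace, model)
        np.testing.assert_array_equal(ideal.levels, truth.open_counts)

    def test_brute_force_nearest_level_equivalence(self, noisefree_site):
        _, trace = noisefree_site
        model = global_quantal_model(trace, q=0.29)
        ideal = idealize(trace, model)
        means = model.level_means()
        brute = np.argmin(np.abs(trace.values[:, None] - means[None, :]), axis=1)
        np.testing.assert_array_equal(ideal.levels, brute)

    def test_midpoint_stays_at_previous_level(self):
        model = QuantalModel(
            1, np.array([1.0]), np.array([1.0]), np.array([0.01]), 0.29, 1.0
        )
        # frame 2 sits exactly at the 0/1 midpoint after a level-0 frame
        tr = _trace([1.0, 1.0, 1.0 + 0.145, 1.0])
        assert idealize(tr, model).levels[2] == 0
        # ... and keeps level 1 when approached from above
        tr = _trace([1.29, 1.29, 1.0 + 0.145, 1.29])
        assert idealize(tr, model).levels[2] == 1

    def test_no_hysteresis_ties_go_low(self):
        model = QuantalModel(
            1, np.array([1.0]), np.array([1.0]), np.array([0.01]), 0.29, 1.0
        )
        tr = _trace([1.29, 1.0 + 0.145])
        assert idealize(tr, model, hysteresis=False).levels[1] == 0

    def test_levels_clipped_to_four(self):
        model = QuantalModel(
            1, np.array([1.0]), np.array([1.0]), np.array([0.01]), 0.29, 1.0
        )
        tr = _trace([1.0 + 0.29 * 9])
        assert idealize(tr, model).levels[0] == 4

    def test_missing_q_rejected(self, flat_trace):
        model = QuantalModel(
            1, np.array([1.0]), np.array([1.0]), np.array([0.01]), None, 1.0
        )
        with pytest.raises(ParameterError):
            idealize(flat_trace, model)

    def test_noisy_agreement_at_q_over_6(self):
        # confusion-rate oracle vs ground truth over 20 seeds
        rates = []
        for seed in range(20):
            params = GatingParams(4, 1.5, 8.5, duration=30.0, seed=seed)
            truth = simulate_open_counts(params)
            trace = render_trace(truth, RenderParams(noise_sd=0.29 / 6), seed=100 + seed)
            model = global_quantal_model(trace, q=0.29)
            ideal = idealize(trace, model)
            rates.append(np.mean(ideal.levels == truth.open_counts))
        assert np.mean(rates) >= 0.95

    def test_min_dwell_merges_short_runs(self):
        model = QuantalModel(
            1, np.array([1.0]), np.array([1.0]), np.array([0.01]), 0.29, 1.0
        )
        v = np.ones(20)
        v[10] = 1.29  # single-frame blip
        ideal = idealize(_trace(v), model, min_dwell_frames=3)
        assert np.all(ideal.levels == 0)


class TestComputeNpo:
    def test_all_level_zero(self):
        ideal = IdealizedTrace(np.zeros(100, dtype=int), 30.0, np.zeros(4), 100 / 30.0)
        assert compute_npo(ideal) == 0.0

    def test_direct_substitution(self):
        # T1=2, T2=1, T3=0.5, T4=0, T_total=10 -> (2 + 2 + 1.5)/10 = 0.55
        ideal = IdealizedTrace(
            np.zeros(300, dtype=int), 30.0, np.array([2.0, 1.0, 0.5, 0.0]), 10.0
        )
        assert compute_npo(ideal) == pytest.approx(0.55)

    @given(seed=st.integers(0, 10_000), n=st.integers(10, 500))
    @settings(max_examples=50, deadline=None)
    def test_equals_mean_of_levels(self, seed, n):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 5, size=n)
        fs = 30.0
        dwell = np.bincount(levels, minlength=5)[1:] / fs
        ideal = IdealizedTrace(levels, fs, dwell, n / fs)
        assert compute_npo(ideal) == pytest.approx(levels.mean(), abs=1e-12)

    def test_npo_bounds(self, noisy_site):
        truth, trace = noisy_site
        result = analyze_site(trace, SiteConfig(detect=False))
        assert 0.0 <= result.npo <= 4.0


class TestSitesPerCell:
    def test_three_sites_fifteen_cells(self):
        assert sites_per_cell(3, 15) == pytest.approx(0.2)

    def test_zero_sites(self):
        assert sites_per_cell(0, 15) == 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ParameterError):
            sites_per_cell(3, 0)

    def test_negative_sites_rejected(self):
        with pytest.raises(ParameterError):
            sites_per_cell(-1, 15)


class TestAnalyzeSite:
    def test_flat_trace_baseline_only(self, flat_trace):
        result = analyze_site(flat_trace, SiteConfig(quantal_mode="fit", detect=False))
        assert result.npo == 0.0
        assert result.model.n_levels == 0

    def test_noise_free_exact_npo(self, noisefree_site):
        truth, trace = noisefree_site
        result = analyze_site(trace, SiteConfig(detect=False))
        assert result.npo == pytest.approx(truth.open_counts.mean(), abs=1e-12)

    def test_constructed_po_quarter(self):
        # 1 channel open exactly 25% of frames, noise-free
        v = np.ones(400)
        v[:100] = 1.29
        result = analyze_site(_trace(v), SiteConfig(detect=False))
        assert result.npo == pytest.approx(0.25)

    def test_recovery_within_ten_percent(self):
        errs = []
        for seed in range(20):
            params = GatingParams(4, 1.0, 9.0, duration=120.0, seed=seed)
            truth = simulate_open_counts(params)
            trace = render_trace(truth, RenderParams(noise_sd=0.29 / 6), seed=700 + seed)
            result = analyze_site(trace, SiteConfig(detect=False))
            errs.append(result.npo - 0.4)
        assert abs(np.mean(errs)) / 0.4 <= 0.10

    def test_monotone_in_k_open(self):
        # seed-averaged recovered NP_O never decreases when k_open grows
        means = []
        for k_open in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for seed in range(10):
                params = GatingParams(2, k_open, 9.0, duration=60.0, seed=seed)
                truth = simulate_open_counts(params)
                trace = render_trace(truth, RenderParams(noise_sd=0.29 / 6), seed=300 + seed)
                vals.append(analyze_site(trace, SiteConfig(detect=False)).npo)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) >= 0)

    def test_audit_intermediates_retained(self, noisy_site):
        _, trace = noisy_site
        result = analyze_site(trace)
        assert result.histogram.counts.sum() == trace.n_frames
        assert result.model.quantal_amplitude == pytest.approx(0.29)
        assert result.ideal is not None


class TestParameterRecoveryGrid:
    """Median relative error of NP_O <= 10% and of q_hat <= 5% on the grid."""

    GRID = [(n, po) for n in (1, 2, 4) for po in (0.05, 0.1, 0.3)]

    @pytest.mark.parametrize("n_channels,po", GRID)
    def test_npo_recovery(self, n_channels, po):
        k_total = 10.0
        errs = []
        for seed in range(20):
            params = GatingParams(
                n_channels, k_total * po, k_total * (1 - po), duration=120.0, seed=seed
            )
            truth = simulate_open_counts(params)
            trace = render_trace(truth, RenderParams(noise_sd=0.29 / 6), seed=5000 + seed)
            result = analyze_site(trace, SiteConfig(detect=False))
            errs.append(abs(result.npo - n_channels * po) / (n_channels * po))
        assert np.median(errs) <= 0.10

    @pytest.mark.parametrize("n_channels,po", GRID)
    def test_q_recovery(self, n_channels, po):
        k_total = 10.0
        errs = []
        for seed in range(20):
            params = GatingParams(
                n_channels, k_total * po, k_total * (1 - po), duration=120.0, seed=seed
            )
            truth = simulate_open_counts(params)
            trace = render_trace(truth, RenderParams(noise_sd=0.29 / 6), seed=5000 + seed)
            model = fit_multi_gaussian(build_histogram(trace))
            err = (
                abs(model.quantal_amplitude - 0.29) / 0.29
                if model.quantal_amplitude is not None
                else 1.0
            )
            errs.append(err)
        assert np.median(errs) <= 0.05
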