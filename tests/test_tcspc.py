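"""Reconvolution fitting, lifetime summaries and goodness of fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sifi import (
    ABASIC_HAIRPIN,
    CY3B,
    DecayHistogram,
    InstrumentConfig,
    PhotophysicsModel,
    fit_reconvolution,
    simulate_decay,
    simulate_irf,
)
from sifi import tcspc


def small_grid_irf(n=256, width=0.05, sigma_ch=4.0, center=30.0):
    t = np.arange(n)
    counts = 1e5 * np.exp(-0.5 * ((t - center) / sigma_ch) ** 2)
    return DecayHistogram(channel_width=width, counts=counts, kind="irf")


def brute_force_circular(irf_counts, channel_width, taus, amps, background):
    """Independent O(N^2) oracle: direct circular convolution sum."""
    n = irf_counts.size
    irf_n = irf_counts / irf_counts.sum()
    t = (np.arange(n) + 0.5) * channel_width
    period = n * channel_width
    model = np.zeros(n)
    for tau, a in zip(taus, amps):
        model += a * np.exp(-t / tau) / (1.0 - np.exp(-period / tau))
    out = np.zeros(n)
    for k in range(n):
        for j in range(n):
            out[k] += irf_n[j] * model[(k - j) % n]
    return out + background


class TestConvolution:
    def test_matches_bruteforce_oracle(self):
        irf = small_grid_irf()
        taus, amps, bg = (2.65, 0.8), (700.0, 300.0), 3.0
        fast = tcspc.expected_curve(irf.counts, irf.channel_width, taus, amps, background=bg)
        slow = brute_force_circular(irf.counts, irf.channel_width, taus, amps, bg)
        assert np.max(np.abs(fast - slow) / np.max(slow)) < 1e-10

    def test_delta_irf_gives_pure_exponential(self):
        n, width = 256, 0.05
        counts = np.zeros(n)
        counts[0] = 1e6
        curve = tcspc.expected_curve(counts, width, [2.0], [1000.0])
        ratio = curve[1:100] / curve[:99]
        assert np.allclose(ratio, np.exp(-width / 2.0), rtol=1e-9)

    def test_background_only_is_flat(self):
        irf = small_grid_irf()
        curve = tcspc.expected_curve(
            irf.counts, irf.channel_width, [1.0], [0.0], background=7.5
        )
        assert np.allclose(curve, 7.5, atol=1e-9)

    def test_total_signal_counts_preserved(self):
        irf = small_grid_irf()
        amps = (600.0, 400.0)
        curve = tcspc.expected_curve(irf.counts, irf.channel_width, (2.0, 0.4), amps)
        t = (np.arange(irf.n_channels) + 0.5) * irf.channel_width
        period = irf.n_channels * irf.channel_width
        direct = sum(
            a * (np.exp(-t / tau) / (1 - np.exp(-period / tau))).sum()
            for a, tau in zip(amps, (2.0, 0.4))
        )
        assert np.isclose(curve.sum(), direct, rtol=1e-10)

    def test_mismatched_grids_rejected(self, irf, abasic_decay):
        other = DecayHistogram(channel_width=0.016, counts=abasic_decay.counts)
        with pytest.raises(ValueError, match="grid"):
            tcspc.ReconvolutionModel(other, irf)


class TestLifetimeSummaries:
    @pytest.mark.parametrize(
        "amps, taus, tau_amp, tau_int, fint",
        [
            ((1.0,), (2.4,), 2.4, 2.4, (1.0,)),
            ((0.5, 0.5), (2.0, 1.0), 1.5, 5.0 / 3.0, (2.0 / 3.0, 1.0 / 3.0)),
            (
                (0.25, 0.25, 0.5),
                (2.6, 1.3, 0.3),
                1.125,
                1.91778,
                (0.57778, 0.28889, 0.13333),
            ),
        ],
    )
    def test_printed_formulas(self, amps, taus, tau_amp, tau_int, fint):
        assert tcspc.amplitude_weighted_lifetime(taus, amps) == pytest.approx(tau_amp, abs=1e-4)
        assert tcspc.intensity_weighted_lifetime(taus, amps) == pytest.approx(tau_int, abs=1e-4)
        assert tcspc.fractional_intensities(taus, amps) == pytest.approx(fint, abs=1e-4)

    def test_zero_amplitude_errors(self):
        with pytest.raises(ValueError):
            tcspc.amplitude_weighted_lifetime((1.0, 2.0), (0.0, 0.0))

    @given(
        taus=st.lists(st.floats(0.01, 50.0), min_size=1, max_size=4),
        amps=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_intensity_weighted_dominates_amplitude_weighted(self, taus, amps):
        """tau_bar >= <tau> for any component set (Cauchy-Schwarz)."""
        k = min(len(taus), len(amps))
        taus, amps = taus[:k], amps[:k]
        tb = tcspc.intensity_weighted_lifetime(taus, amps)
        ta = tcspc.amplitude_weighted_lifetime(taus, amps)
        assert tb >= ta * (1 - 1e-12)
        if len(set(np.round(taus, 12))) > 1:
            assert tb > ta or np.isclose(tb, ta)

    @given(
        taus=st.lists(st.floats(0.01, 50.0), min_size=1, max_size=4),
        amps=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=4),
    )
    @settings(max_examples=200, derandomize=True)
    def test_fractional_intensities_sum_to_one(self, taus, amps):
        k = min(len(taus), len(amps))
        f = tcspc.fractional_intensities(taus[:k], amps[:k])
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_alpha_tau_products_give_equal_fractions(self):
        f = tcspc.fractional_intensities((4.0, 2.0, 1.0), (0.25, 0.5, 1.0))
        assert np.allclose(f, 1.0 / 3.0)


class TestReconvolutionFit:
    def test_mono_exponential_noiseless_exact(self, instrument_cfg, irf):
        mono = PhotophysicsModel(lifetimes=(2.0,), amplitudes=(1.0,))
        decay = simulate_decay(mono, instrument_cfg, irf, noiseless=True)
        fit = fit_reconvolution(decay, irf, n_components=1)
        assert fit.lifetimes[0] == pytest.approx(2.0, abs=0.002)
        assert fit.chi2_reduced < 1e-6

    def test_tri_exponential_recovery(self, abasic_fit):
        """The three Cy3 conformer lifetimes are recovered from one decay."""
        assert abasic_fit.lifetimes[2] == pytest.approx(0.3, rel=0.15)
        assert abasic_fit.lifetimes[1] == pytest.approx(1.3, rel=0.10)
        assert 0.8 < abasic_fit.chi2_reduced < 1.2
        # descending order and positive amplitudes
        assert np.all(np.diff(abasic_fit.lifetimes) < 0)
        assert np.all(abasic_fit.amplitudes >= 0)

    def test_ensemble_recovery(self, abasic_fit_ensemble):
        """Median recovery error over repeated experiments: lifetimes within
        15%, fractional intensities within 0.05; chi2 centred on 1."""
        true_tau = np.array(ABASIC_HAIRPIN.lifetimes)
        true_f = tcspc.fractional_intensities(
            ABASIC_HAIRPIN.lifetimes, ABASIC_HAIRPIN.amplitudes
        )
        taus = np.array([f.lifetimes for f in abasic_fit_ensemble])
        fs = np.array([f.f_intensity for f in abasic_fit_ensemble])
        chis = np.array([f.chi2_reduced for f in abasic_fit_ensemble])
        rel = np.median(np.abs(taus - true_tau) / true_tau, axis=0)
        assert np.all(rel <= 0.15)
        assert np.all(np.median(np.abs(fs - true_f), axis=0) <= 0.05)
        assert 0.9 <= chis.mean() <= 1.1

    def test_summary_is_printable(self, abasic_fit):
        text = abasic_fit.summary()
        assert "reduced chi-square" in text
        assert "tau_bar" in text

    def test_sparse_decay_rejected(self, irf):
        counts = np.zeros(irf.n_channels)
        counts[:30] = 100
        decay = DecayHistogram(channel_width=irf.channel_width, counts=counts)
        with pytest.raises(ValueError, match="sparse"):
            tcspc.ReconvolutionModel(decay, irf, n_components=3)


class TestGoodnessOfFit:
    def test_correct_model_passes_runs_test(self, abasic_fit_ensemble):
        """Residuals of a correctly specified fit are random: the runs test
        rejects at the 1% level only rarely."""
        ps = [tcspc.goodness_of_fit(f)["residual_randomness_p"] for f in abasic_fit_ensemble]
        assert np.mean(np.asarray(ps) > 0.01) >= 0.95

    def test_misspecified_model_flagged(self, abasic_decay, irf):
        """A mono-exponential fit to tri-exponential data fails both criteria."""
        fit = fit_reconvolution(abasic_decay, irf, n_components=1)
        gof = tcspc.goodness_of_fit(fit)
        assert gof["chi2_reduced"] > 2.0
        assert gof["residual_randomness_p"] < 0.01

    def test_noiseless_fit_has_zero_chi2(self, instrument_cfg, irf):
        mono = PhotophysicsModel(lifetimes=(1.5,), amplitudes=(1.0,))
        decay = simulate_decay(mono, instrument_cfg, irf, noiseless=True)
        fit = fit_reconvolution(decay, irf, n_components=1)
        gof = tcspc.goodness_of_fit(fit)
        assert gof["chi2_reduced"] == pytest.approx(0.0, abs=1e-6)
        assert gof["residual_randomness_p"] == 1.0


class TestModelSelection:
    def test_tri_exponential_needs_three_components(self, abasic_decay, irf):
        assert tcspc.select_n_components(abasic_decay, irf) == 3

    def test_cy3b_is_mono_exponential(self, instrument_cfg, irf):
        decay = simulate_decay(CY3B, instrument_cfg, irf, seed=7)
        assert tcspc.select_n_components(decay, irf) == 1

    def test_separated_bi_exponential(self, instrument_cfg, irf):
        bi = PhotophysicsModel(lifetimes=(2.5, 0.4), amplitudes=(0.5, 0.5))
        decay = simulate_decay(bi, instrument_cfg, irf, seed=8)
        assert tcspc.select_n_components(decay, irf) == 2
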