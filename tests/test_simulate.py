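import math

import numpy as np
import pytest

import nmrdecon as nd


def measured_fwhm(spectrum):
    """Half-height crossing width (ppm) of a single-peak trace."""
    y = spectrum.intensities
    axis = spectrum.ppm_axis
    half = y.max() / 2
    above = np.nonzero(y >= half)[0]
    return abs(axis[above[0]] - axis[above[-1]])


class TestDrawRandomPeaks:
    def test_fixed_seed_reproducible(self):
        a = nd.draw_random_peaks(np.random.default_rng(5))
        b = nd.draw_random_peaks(np.random.default_rng(5))
        assert [(p.height, p.center_ppm, p.fwhm_ppm) for p in a] \
            == [(p.height, p.center_ppm, p.fwhm_ppm) for p in b]

    def test_widths_positive_and_intensities_normalised(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            peaks = nd.draw_random_peaks(rng)
            assert all(p.fwhm_ppm > 0 for p in peaks)
            if peaks:
                assert sum(p.height for p in peaks) == pytest.approx(1.0)

    def test_mean_peak_count_matches_uniform_draw(self):
        rng = np.random.default_rng(2)
        counts = [len(nd.draw_random_peaks(rng)) for _ in range(1000)]
        assert np.mean(counts) == pytest.approx(6.0, abs=0.4)


class TestSimulateFidSpectrum:
    def test_apex_at_requested_center(self):
        pk = nd.LorentzianPeak(1.0, 0.2, 30 / 376.5)
        sp = nd.simulate_fid_spectrum(nd.SimulationSpec(peaks=(pk,)))
        i = int(np.argmax(sp.intensities))
        assert abs(sp.ppm_axis[i] - 0.2) <= sp.dppm

    def test_measured_fwhm_matches_request(self):
        w = 30 / 376.5
        pk = nd.LorentzianPeak(1.0, 0.2, w)
        sp = nd.simulate_fid_spectrum(nd.SimulationSpec(peaks=(pk,)))
        assert abs(measured_fwhm(sp) - w) <= 1.5 * sp.dppm

    def test_fid_route_matches_closed_form_within_one_percent(self):
        pk = nd.LorentzianPeak(1.0, 0.2, 30 / 376.5)
        sp = nd.simulate_fid_spectrum(nd.SimulationSpec(peaks=(pk,)))
        cf = nd.evaluate_peak(pk, sp.ppm_axis)
        assert np.max(np.abs(sp.intensities - cf)) < 0.01 * pk.height

    def test_phase_offset_reduces_apex_and_is_recoverable(self):
        pk = nd.LorentzianPeak(1.0, 0.2, 30 / 376.5)
        sp0 = nd.simulate_fid_spectrum(nd.SimulationSpec(peaks=(pk,)))
        sp = nd.simulate_fid_spectrum(nd.SimulationSpec(
            peaks=(pk,), zero_order_phase_rad=math.pi / 8))
        assert sp.intensities.max() < sp0.intensities.max()
        init = nd.PeakModel((nd.LorentzianPeak(0.8, 0.22, 35 / 376.5),),
                            phase_mode="variable")
        res = nd.fit_model(sp, init)
        assert res.model.peaks[0].phase_rad \
            == pytest.approx(math.pi / 8, abs=math.pi / 16)

    def test_target_snr_reproduced_on_spectrum(self):
        pk = nd.LorentzianPeak(1.0, 0.0, 40 / 376.5)
        for target in (25, 75, 244):
            spec = nd.SimulationSpec(peaks=(pk,), target_snr=target, seed=3)
            sp = nd.simulate_fid_spectrum(spec)
            assert nd.signal_to_noise(sp) == pytest.approx(target, rel=0.20)
        # at low SNR the measured max-over-RMS is biased high because
        # noise excursions inflate the apex estimate
        for target, slack in ((10, 0.35), (5, 0.6)):
            spec = nd.SimulationSpec(peaks=(pk,), target_snr=target, seed=3)
            assert nd.signal_to_noise(nd.simulate_fid_spectrum(spec)) \
                == pytest.approx(target, rel=slack)

    def test_aliasing_warns_when_dwell_pinned(self):
        pk = nd.LorentzianPeak(1.0, 5.0, 0.1)  # 1882 Hz >> 500 Hz Nyquist
        spec = nd.SimulationSpec(peaks=(pk,), auto_spectral_width=False)
        with pytest.warns(UserWarning, match="alias"):
            nd.simulate_fid_spectrum(spec)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            nd.SimulationSpec(dwell_s=0.0)
        with pytest.raises(ValueError):
            nd.SimulationSpec(dwell_s=0.01, acq_s=0.001)


class TestExchangeSystem:
    def test_two_site_stationarity_and_total_rate(self):
        s = nd.ExchangeSystem.two_site(100.0, 50.0, (0.25, 0.75), r2=2.0)
        k = s.rate_matrix
        assert np.allclose(k.sum(axis=0), 0.0)
        assert np.allclose(k @ s.populations, 0.0)
        # total exchange rate = forward + reverse
        assert k[1, 0] + k[0, 1] == pytest.approx(50.0)

    def test_chain_stationary_for_skewed_populations(self):
        s = nd.ExchangeSystem.chain([-150, -50, 50, 150],
                                    [0.1, 0.4, 0.3, 0.2], 80.0, r2=3.0)
        assert np.allclose(s.rate_matrix @ s.populations, 0.0, atol=1e-10)

    def test_invalid_populations_rejected(self):
        with pytest.raises(ValueError):
            nd.ExchangeSystem(np.array([-50.0, 50.0]),
                              np.array([0.6, 0.6]),
                              np.zeros((2, 2)), np.array([1.0, 1.0]))


class TestExchangeLineshape:
    def test_slow_limit_two_resolved_sites_with_equal_areas(self):
        s = nd.ExchangeSystem.two_site(200.0, 2.0, (0.5, 0.5), r2=5.0)
        axis = np.linspace(-400, 400, 8192)
        y = nd.exchange_lineshape(s, axis)
        assert nd.count_maxima(y) == 2
        step = axis[1] - axis[0]
        top_two = np.sort(axis[np.argsort(y)[-2:]])
        assert abs(top_two[0] + 100.0) <= step
        assert abs(top_two[1] - 100.0) <= step
        left = np.trapezoid(y[axis < 0], axis[axis < 0])
        total = np.trapezoid(y, axis)
        assert left / total == pytest.approx(0.5, abs=0.01)

    def test_fast_limit_single_line_at_weighted_mean(self):
        s = nd.ExchangeSystem.two_site(200.0, 2e5, (0.5, 0.5), r2=5.0)
        axis = np.linspace(-400, 400, 8192)
        y = nd.exchange_lineshape(s, axis)
        assert nd.count_maxima(y) == 1
        assert abs(axis[np.argmax(y)]) <= axis[1] - axis[0]

    def test_skewed_slow_populations_recovered_from_areas(self):
        s = nd.ExchangeSystem.two_site(200.0, 2.0, (0.25, 0.75), r2=5.0)
        axis = np.linspace(-400, 400, 8192)
        y = nd.exchange_lineshape(s, axis)
        left = np.trapezoid(y[axis < 0], axis[axis < 0])
        total = np.trapezoid(y, axis)
        assert left / total == pytest.approx(0.25, abs=0.02)

    def test_total_area_invariant_to_exchange_rate(self):
        areas = []
        axis = np.linspace(-3000, 3000, 2 ** 15)
        for ratio in (0.1, 1.0, 4.44, 10.0):
            s = nd.ExchangeSystem.two_site(100.0, ratio * 100.0,
                                           (0.5, 0.5), r2=1.0)
            areas.append(np.trapezoid(nd.exchange_lineshape(s, axis), axis))
        assert np.ptp(areas) / np.mean(areas) < 0.005

    def test_separation_shrinks_monotonically_to_coalescence(self):
        axis = np.linspace(-200, 200, 2 ** 14)
        seps = []
        for ratio in (0.5, 1.5, 2.5, 3.5, 4.2):
            s = nd.ExchangeSystem.two_site(100.0, ratio * 100.0,
                                           (0.5, 0.5), r2=0.1)
            y = nd.exchange_lineshape(s, axis)
            from scipy.signal import find_peaks
            idx, _ = find_peaks(y, prominence=1e-10 * y.max())
            seps.append(np.ptp(axis[idx]) if idx.size > 1 else 0.0)
        assert all(b < a for a, b in zip(seps, seps[1:]))

    def test_degenerate_zero_rate_zero_relaxation_perturbs(self):
        s = nd.ExchangeSystem(np.array([-50.0, 50.0]),
                              np.array([0.5, 0.5]),
                              np.zeros((2, 2)), np.array([0.0, 0.0]))
        axis = np.linspace(-100, 100, 512)
        with pytest.warns(UserWarning, match="singular"):
            y = nd.exchange_lineshape(s, axis)
        assert np.all(np.isfinite(y))


class TestCountMaxima:
    def test_counts_for_basic_shapes(self):
        axis = np.linspace(5, -5, 4001)
        one = nd.evaluate_peak(nd.LorentzianPeak(1.0, 0.0, 0.2), axis)
        assert nd.count_maxima(one) == 1
        two = (nd.evaluate_peak(nd.LorentzianPeak(1.0, -1.0, 0.2), axis)
               + nd.evaluate_peak(nd.LorentzianPeak(1.0, 1.0, 0.2), axis))
        assert nd.count_maxima(two) == 2

    def test_merged_past_coalescence_counts_one(self):
        s = nd.ExchangeSystem.two_site(100.0, 600.0, (0.5, 0.5), r2=0.1)
        axis = np.linspace(-200, 200, 2 ** 14)
        assert nd.count_maxima(nd.exchange_lineshape(s, axis)) == 1


class TestCoalescence:
    def test_equal_population_critical_ratio(self):
        assert nd.find_coalescence_ratio(100.0) \
            == pytest.approx(4.44, abs=0.05)

    def test_ratio_invariant_to_shift_difference(self):
        assert nd.find_coalescence_ratio(100.0) \
            == pytest.approx(nd.find_coalescence_ratio(200.0), abs=0.02)

    def test_skewed_populations_merge_earlier(self):
        equal = nd.find_coalescence_ratio(100.0)
        skewed = nd.find_coalescence_ratio(100.0, populations=(0.25, 0.75))
        assert skewed < equal
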