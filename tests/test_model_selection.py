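import numpy as np
import pytest

import nmrdecon as nd
from nmrdecon.errors import PlacementError
from nmrdecon.fitting import FitResult
from nmrdecon.model_selection import forward_build, place_next_peak
from tests.conftest import closed_form_spectrum


def fake_results(bics):
    """FitResults with prescribed BICs and sizes 1..len (for rule tests)."""
    out = []
    for size, bic in enumerate(bics, start=1):
        peaks = tuple(nd.LorentzianPeak(1.0, 0.1 * i, 0.2)
                      for i in range(size))
        out.append(FitResult(model=nd.PeakModel(peaks), rss=1.0,
                             n_data=100, bic=bic,
                             param_stderr=np.full(4 * size, np.nan),
                             converged=True))
    return out


class TestPlaceNextPeak:
    axis = np.linspace(5, -5, 101)

    def test_single_positive_block_hosts_the_peak(self):
        r = np.zeros(101)
        r[40:51] = 1.0
        pk = place_next_peak(r, self.axis)
        mid = 0.5 * (self.axis[40] + self.axis[50])
        assert pk.center_ppm == pytest.approx(mid)
        assert pk.height == pytest.approx(1.0)
        assert pk.fwhm_ppm == pytest.approx(11 * 0.1, rel=1e-6)

    def test_longest_run_wins(self):
        r = np.full(101, -1.0)
        r[5:35] = 0.5       # 30-point run
        r[60:72] = 2.0      # 12-point run with higher max
        pk = place_next_peak(r, self.axis)
        assert pk.center_ppm == pytest.approx(
            0.5 * (self.axis[5] + self.axis[34]))

    def test_equal_runs_tie_broken_by_higher_maximum(self):
        r = np.full(101, -1.0)
        r[5:15] = 0.5
        r[60:70] = 0.8
        pk = place_next_peak(r, self.axis)
        assert pk.height == pytest.approx(0.8)

    def test_identical_runs_tie_broken_leftmost(self):
        r = np.full(101, -1.0)
        r[5:15] = 0.5
        r[60:70] = 0.5
        pk = place_next_peak(r, self.axis)
        assert pk.center_ppm == pytest.approx(
            0.5 * (self.axis[5] + self.axis[14]))

    def test_no_positive_residual_raises(self):
        with pytest.raises(PlacementError):
            place_next_peak(-np.ones(101), self.axis)


class TestSelectSeedModel:
    def test_worked_sequence_picks_size_five(self):
        results = fake_results([100, 60, 55, 57, 54, 58])
        assert nd.select_seed_model(results).n_peaks == 5

    def test_monotone_increasing_keeps_size_one(self):
        assert nd.select_seed_model(fake_results([10, 20, 30])).n_peaks == 1

    def test_monotone_decreasing_keeps_largest(self):
        assert nd.select_seed_model(fake_results([30, 20, 10])).n_peaks == 3


class TestForwardBuild:
    def test_noiseless_single_peak_stops_growing(self, single_peak_spectrum):
        results = forward_build(single_peak_spectrum, 3)
        best = min(results, key=lambda r: r.bic)
        assert best.n_peaks == 1

    def test_rss_non_increasing_with_model_size(self, three_peak_truth):
        sp = closed_form_spectrum(three_peak_truth, noise_sigma=0.01, seed=2)
        results = forward_build(sp, 5)
        rss = [r.rss for r in results]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(rss, rss[1:]))

    def test_pure_noise_additions_never_beat_size_zero(self):
        rng = np.random.default_rng(11)
        sp = nd.Spectrum(3.0, -3.0, rng.normal(0, 1, 512))
        ens = nd.deconvolve(sp, max_peaks=3, seed=1, mc_refits=0)
        assert ens.best.n_peaks == 0


class TestPrunePeaks:
    def test_large_second_peak_survives_default_plimit(self):
        # second peak carries 40% of the total area: deleting it would
        # explode the rss, so the deletion is rejected
        peaks = (nd.LorentzianPeak(1.0, -1.0, 0.3),
                 nd.LorentzianPeak(1.0, 1.0, 0.2))
        sp = closed_form_spectrum(peaks, noise_sigma=0.01, seed=5)
        seed_fit = nd.fit_model(sp, nd.PeakModel(peaks))
        trail = nd.prune_peaks(seed_fit, sp, plimit=15.0)
        assert trail == []

    def test_plimit_zero_only_accepts_non_worsening_deletions(self):
        # a duplicated peak is redundant: deleting one of the pair cannot
        # worsen the fit, but deleting the genuine second peak would
        peaks = (nd.LorentzianPeak(0.5, -1.0, 0.3),
                 nd.LorentzianPeak(0.5, -1.0, 0.3),
                 nd.LorentzianPeak(1.0, 1.0, 0.2))
        sp = closed_form_spectrum(
            [nd.LorentzianPeak(1.0, -1.0, 0.3),
             nd.LorentzianPeak(1.0, 1.0, 0.2)], noise_sigma=0.01, seed=6)
        seed_fit = nd.fit_model(sp, nd.PeakModel(peaks))
        trail = nd.prune_peaks(seed_fit, sp, plimit=0.0)
        assert trail  # the redundant copy goes
        assert trail[-1].n_peaks == 2
        assert trail[-1].bic <= seed_fit.bic


class TestSplitPeaks:
    def test_doublet_fit_by_one_peak_gains_from_split(self):
        w = 0.3
        peaks = (nd.LorentzianPeak(1.0, -0.09, w),
                 nd.LorentzianPeak(1.0, 0.09, w))  # 0.6 x FWHM apart
        sp = closed_form_spectrum(peaks, noise_sigma=0.005, seed=7)
        one = nd.fit_model(sp, nd.PeakModel(
            (nd.LorentzianPeak(1.5, 0.0, 1.5 * w),)))
        trail = nd.split_peaks(one, sp, np.random.default_rng(0))
        assert trail
        assert trail[-1].n_peaks == 2
        assert trail[-1].bic < one.bic

    def test_true_singlet_rejects_all_splits(self):
        sp = closed_form_spectrum([nd.LorentzianPeak(1.0, 0.0, 0.3)],
                                  noise_sigma=0.01, seed=8)
        one = nd.fit_model(sp, nd.PeakModel(
            (nd.LorentzianPeak(1.0, 0.0, 0.3),)))
        trail = nd.split_peaks(one, sp, np.random.default_rng(0))
        assert trail == []


class TestMonteCarloRefine:
    def test_infinite_snr_reproduces_incumbent(self, single_peak_spectrum):
        best = nd.fit_model(single_peak_spectrum, nd.PeakModel(
            (nd.LorentzianPeak(0.9, 0.32, 0.27),)))
        refits = nd.monte_carlo_refine(best, single_peak_spectrum, 5,
                                       np.random.default_rng(0),
                                       snr=float("inf"))
        for r in refits:
            assert np.allclose(r.param_values(), best.param_values(),
                               rtol=1e-12)

    def test_fixed_seed_reproduces_refit_set(self, three_peak_truth):
        sp = closed_form_spectrum(three_peak_truth, noise_sigma=0.01, seed=9)
        best = nd.fit_model(sp, nd.PeakModel(three_peak_truth))
        a = nd.monte_carlo_refine(best, sp, 4, np.random.default_rng(42),
                                  snr=80.0)
        b = nd.monte_carlo_refine(best, sp, 4, np.random.default_rng(42),
                                  snr=80.0)
        assert [r.bic for r in a] == [r.bic for r in b]

    def test_well_separated_peaks_refit_within_two_bic(self,
                                                       three_peak_truth):
        spec = nd.SimulationSpec(peaks=three_peak_truth, acq_s=0.4,
                                 target_snr=75, seed=3)
        sp = nd.simulate_fid_spectrum(spec)
        ens = nd.deconvolve(sp, max_peaks=6, seed=1)
        assert len(ens.mc_results) == 10
        for r in ens.mc_results:
            assert abs(r.bic - ens.incumbent_bic) < 2.0


class TestDeconvolve:
    def test_noiseless_single_peak_exact(self, single_peak_spectrum):
        ens = nd.deconvolve(single_peak_spectrum, max_peaks=3, seed=1,
                            apply_baseline=False)
        assert ens.best.n_peaks == 1
        pk = ens.best.model.peaks[0]
        assert pk.height == pytest.approx(1.0, rel=1e-6)
        assert pk.center_ppm == pytest.approx(0.3, abs=1e-6)
        assert pk.fwhm_ppm == pytest.approx(0.25, rel=1e-6)

    def test_same_seed_identical_ensemble(self, three_peak_truth):
        spec = nd.SimulationSpec(peaks=three_peak_truth, acq_s=0.3,
                                 target_snr=50, seed=4)
        sp = nd.simulate_fid_spectrum(spec)
        a = nd.deconvolve(sp, max_peaks=4, seed=3)
        b = nd.deconvolve(sp, max_peaks=4, seed=3)
        assert [c.bic for c in a.candidates] == [c.bic for c in b.candidates]
        assert np.array_equal(a.best.param_values(), b.best.param_values())

    def test_best_has_minimum_bic_and_reported_within_plimit(
            self, three_peak_truth):
        spec = nd.SimulationSpec(peaks=three_peak_truth, acq_s=0.3,
                                 target_snr=50, seed=4)
        sp = nd.simulate_fid_spectrum(spec)
        ens = nd.deconvolve(sp, max_peaks=4, seed=3)
        bics = [c.bic for c in ens.candidates]
        assert ens.best.bic == min(bics)
        for c in ens.reported:
            assert c.bic <= ens.best.bic + ens.plimit

    def test_never_overfits_random_spectra(self):
        """Across seeded random draws the best model never carries more
        peaks than the truth (heavy overlap may merge peaks, so fewer is
        expected and allowed)."""
        for s in range(12):
            rng = np.random.default_rng(100 + s)
            drawn = nd.draw_random_peaks(rng, max_peaks=3)
            if not drawn:
                sp = nd.Spectrum(3.0, -3.0, rng.normal(0, 1, 512))
            else:
                spec = nd.SimulationSpec(peaks=tuple(drawn), acq_s=0.15,
                                         target_snr=50,
                                         seed=int(rng.integers(2 ** 31)))
                sp = nd.simulate_fid_spectrum(spec)
            ens = nd.deconvolve(sp, max_peaks=max(2, 2 * len(drawn)),
                                seed=1, mc_refits=0)
            assert ens.best.n_peaks <= len(drawn)
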