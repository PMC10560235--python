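"""ERSP, band averaging, mismatch difference waves and peak measures."""

import numpy as np
import pytest

from ecognet.bands import BandSet, ERSP_BANDS
from ecognet.containers import Epochs
from ecognet.evoked import (
    ERSP,
    band_average,
    compute_ersp,
    mismatch_difference,
    vot_peak_measures,
)
from ecognet.preprocess import fir_bandpass
from ecognet.synth import (
    INTRAOP_DESIGN,
    EvokedEffectSpec,
    evoked_template,
    label_congruency,
    make_task_roster,
    simulate_evoked_trials,
)


def _osc_epochs(fs=500.0, n_trials=30, gain_post=1.0, f0=40.0, seed=0):
    rng = np.random.default_rng(seed)
    times = -0.5 + np.arange(int(1.5 * fs)) / fs
    data = np.empty((n_trials, 1, len(times)))
    for k in range(n_trials):
        ph = rng.uniform(0, 2 * np.pi)
        osc = np.cos(2 * np.pi * f0 * times + ph)
        gain = np.where(times >= 0, gain_post, 1.0)
        data[k, 0] = osc * gain + 0.05 * rng.normal(size=len(times))
    return Epochs(data, fs, -0.5, ["c0"], baseline=(-0.4, -0.1))


class TestERSP:
    def test_stationary_input_near_zero(self):
        # broadband stationary noise: every frequency carries stable power
        rng = np.random.default_rng(17)
        fs = 500.0
        data = rng.normal(size=(60, 1, int(2.0 * fs)))
        ep = Epochs(data, fs, -1.0, ["c0"], baseline=(-0.6, -0.3))
        ersp = compute_ersp(ep, np.array([20.0, 40.0, 60.0]),
                            baseline=(-0.6, -0.3))
        # stay clear of the wavelet half-length at the epoch edges; the
        # per-point dB trace fluctuates at the 1/sqrt(n_trials) scale, so the
        # stationarity identity is on the time-mean at every frequency
        interior = (ersp.times > -0.6) & (ersp.times < 0.6)
        assert np.abs(ersp.values[:, :, interior].mean(axis=2)).max() < 0.2

    def test_amplitude_doubling_is_6dB(self):
        ep = _osc_epochs(gain_post=2.0, n_trials=40)
        ersp = compute_ersp(ep, np.array([40.0]), baseline=(-0.4, -0.1))
        post = (ersp.times > 0.2) & (ersp.times < 0.8)
        assert ersp.values[0, 0, post].mean() == pytest.approx(
            20 * np.log10(2), abs=0.3
        )

    def test_baseline_normalisation_identity(self):
        ep = _osc_epochs(n_trials=40)
        ersp = compute_ersp(ep, np.array([20.0, 40.0]), baseline=(-0.4, -0.1))
        bmask = ep.time_mask((-0.4, -0.1))
        assert np.abs(ersp.values[:, :, bmask].mean(axis=2)).max() < 0.1

    def test_frequency_above_nyquist_rejected(self):
        ep = _osc_epochs()
        with pytest.raises(ValueError):
            compute_ersp(ep, np.array([400.0]))


class TestBandAverage:
    def _ersp(self, values, freqs):
        t = np.linspace(-0.1, 0.5, values.shape[-1])
        return ERSP(values, np.asarray(freqs, dtype=float), t,
                    (-0.1, 0.0), ["ch"])

    def test_constant_across_frequencies(self):
        freqs = np.arange(4.0, 151.0, 2.0)
        ersp = self._ersp(np.full((1, len(freqs), 20), 2.5), freqs)
        out = band_average(ersp)
        for course in out.values():
            assert np.allclose(course, 2.5)

    def test_energy_at_20Hz_lands_in_beta(self):
        freqs = np.arange(4.0, 61.0, 1.0)
        vals = np.zeros((1, len(freqs), 10))
        vals[0, freqs == 20.0, :] = 8.0
        low_bands = BandSet({"theta": (4.0, 8.0), "alpha": (9.0, 12.0),
                             "beta": (13.0, 30.0)})
        out = band_average(self._ersp(vals, freqs), low_bands)
        assert out["beta"].max() > 0
        assert np.allclose(out["theta"], 0)
        assert np.allclose(out["alpha"], 0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        freqs = np.arange(4.0, 151.0, 2.0)
        a = rng.normal(size=(2, len(freqs), 15))
        b = rng.normal(size=(2, len(freqs), 15))
        oa = band_average(self._ersp(a, freqs))
        ob = band_average(self._ersp(b, freqs))
        oab = band_average(self._ersp(2 * a + 3 * b, freqs))
        for band in oa:
            np.testing.assert_allclose(oab[band], 2 * oa[band] + 3 * ob[band],
                                       atol=1e-12)

    def test_empty_band_errors(self):
        freqs = np.arange(20.0, 30.0, 1.0)
        with pytest.raises(ValueError, match="no frequency bins"):
            band_average(self._ersp(np.zeros((1, len(freqs), 5)), freqs),
                         BandSet({"theta": (4.0, 8.0)}))


@pytest.fixture(scope="module")
def labeled_evoked():
    roster = label_congruency(make_task_roster(INTRAOP_DESIGN, seed=21))
    spec = EvokedEffectSpec(noise_sd=2.0)
    ep = simulate_evoked_trials(roster, spec, fs=500.0, seed=22)
    exp = np.where(ep.annotations["trial_class"] == "experimental")[0]
    return ep.select_trials(exp), spec


class TestMismatchDifference:
    filter_spec = (0.5, 50.0, 700, 5.65)

    def test_condition_counts(self, labeled_evoked):
        ep, _ = labeled_evoked
        dw = mismatch_difference(ep, self.filter_spec)
        assert dw.n_congruent == 96
        assert dw.n_incongruent == 96

    def test_matches_filtered_template_contrast(self, labeled_evoked):
        """The difference wave equals the (filtered) congruent-minus-
        incongruent template contrast up to ensemble noise."""
        ep, spec = labeled_evoked
        dw = mismatch_difference(ep, self.filter_spec)
        t = ep.times
        expected = -fir_bandpass(
            evoked_template(spec, t, 1, True) -
            evoked_template(spec, t, 1, False),
            *[self.filter_spec[0], self.filter_spec[1]], ep.fs,
            self.filter_spec[2], self.filter_spec[3],
        )
        noise_scale = spec.noise_sd * np.sqrt(2 / 96)
        assert np.abs(dw.values[0] - expected).max() < 5 * noise_scale

    def test_identical_templates_null_difference(self):
        roster = label_congruency(make_task_roster(INTRAOP_DESIGN, seed=30))
        spec = EvokedEffectSpec(mismatch_amplitude=0.0, noise_sd=2.0)
        ep = simulate_evoked_trials(roster, spec, fs=500.0, seed=31)
        exp = np.where(ep.annotations["trial_class"] == "experimental")[0]
        dw = mismatch_difference(ep.select_trials(exp), self.filter_spec)
        assert np.abs(dw.values).max() < 5 * spec.noise_sd * np.sqrt(2 / 96)

    def test_antisymmetry_under_label_swap(self, labeled_evoked):
        ep, _ = labeled_evoked
        swapped = ep.copy_with(
            annotations=ep.annotations.assign(
                congruency=ep.annotations["congruency"].map(
                    {"congruent": "incongruent", "incongruent": "congruent",
                     "n/a": "n/a"}
                )
            )
        )
        a = mismatch_difference(ep, self.filter_spec)
        b = mismatch_difference(swapped, self.filter_spec)
        np.testing.assert_allclose(a.values, -b.values, atol=1e-10)

    def test_unbalanced_conditions_error(self, labeled_evoked):
        ep, _ = labeled_evoked
        keep = ep.annotations.index[
            ~((ep.annotations["congruency"] == "congruent")
              & (ep.annotations["vot_step"] == 1))
        ].to_numpy()
        with pytest.raises(ValueError, match="unbalanced"):
            mismatch_difference(ep.select_trials(keep), self.filter_spec)


class TestPeakMeasures:
    def test_flat_signal_tie_flagged(self):
        import pandas as pd

        ep = Epochs(np.zeros((4, 1, 400)), 500.0, -0.15, ["x"],
                    pd.DataFrame({"vot_step": [1, 1, 2, 2],
                                  "trial_class": "experimental"}))
        peaks = vot_peak_measures(ep)
        assert peaks["peak1_tied"].all()
        # tie broken to the earliest sample of the search window
        assert (peaks["peak1_latency"] == peaks["peak1_latency"].min()).all()

    def test_default_windows_centered_on_peaks(self, labeled_evoked):
        ep, spec = labeled_evoked
        peaks = vot_peak_measures(ep)
        assert (peaks["peak1_amplitude"] < 0).all()
        assert (peaks["peak2_amplitude"] > 0).all()
        assert peaks["peak1_latency"].between(0.175, 0.325).all()
        assert peaks["peak2_latency"].between(0.275, 0.425).all()
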