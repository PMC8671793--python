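"""Wavelet power map properties (ridge fidelity, nonnegativity, scale
covariance), ERD index identities, oracle equivalence of the two power
paths, and topography/ROI summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import affective_erd as ae
from affective_erd.tfr import morlet_kernel

from helpers import hilbert_band_power, oracle_erd


def _epochs_from_array(data, sfreq, montage, labels=None, t0=-2.0):
    n_tr, n_ch, n_t = data.shape
    times = np.arange(n_t) / sfreq + t0
    labels = labels if labels is not None else np.array(["Sad"] * n_tr)
    return ae.EpochSet(data=data, times=times, labels=labels,
                       correct=np.ones(n_tr, bool), sfreq=sfreq,
                       montage=montage)


def _sine_epochs(freqs_amps, sfreq=256.0, dur=6.0, montage=None, n_trials=1):
    montage = montage or ae.default_montage()
    n_t = int(dur * sfreq)
    t = np.arange(n_t) / sfreq - 2.0
    sig = sum(a * np.cos(2 * np.pi * f * t) for f, a in freqs_amps)
    data = np.tile(sig, (n_trials, len(montage.channel_names), 1))
    return _epochs_from_array(data, sfreq, montage)


class TestCwtPower:
    def test_pure_tone_ridge_flat_and_correct(self, montage):
        """Unit 10 Hz sinusoid: ridge power at the 10 Hz bin equals the
        squared amplitude and is constant over interior time within 2%."""
        ep = _sine_epochs([(10.0, 1.0)], montage=montage)
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config(), channels=["Oz"])
        j = int(np.argmin(np.abs(tfm.freqs - 10.0)))
        interior = (tfm.times > -1.0) & (tfm.times < 3.0)
        ridge = tfm.power[0, j, interior]
        assert np.allclose(ridge, 1.0, rtol=0.02)

    def test_two_tone_band_separation(self, montage):
        """6 + 20 Hz tones leave under 5% of total power inside 8-13 Hz."""
        ep = _sine_epochs([(6.0, 1.0), (20.0, 1.0)], montage=montage)
        wcfg = ae.WaveletConfig(freqs_hz=tuple(np.arange(2.0, 30.5, 0.5)))
        tfm = ae.cwt_power(ep, wcfg, channels=["Oz"])
        interior = (tfm.times > -1.0) & (tfm.times < 3.0)
        total = tfm.power[0, :, interior].sum()
        band = (tfm.freqs >= 8.0) & (tfm.freqs <= 13.0)
        in_band = tfm.power[0, band][:, interior].sum()
        assert in_band / total <= 0.05
        # two distinct ridges present
        prof = tfm.power[0, :, interior].mean(axis=0)
        assert prof[np.argmin(np.abs(tfm.freqs - 6.0))] > 0.5
        assert prof[np.argmin(np.abs(tfm.freqs - 20.0))] > 0.5

    def test_zero_signal_zero_power(self, montage):
        ep = _sine_epochs([(10.0, 0.0)], montage=montage)
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config(), channels=["Oz", "Cz"])
        assert np.allclose(tfm.power, 0.0)

    def test_power_nonnegative_on_noise(self, small_recording):
        ep = ae.epoch(small_recording, (-2.0, 4.0), baseline_s=None)
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config(), channels=["Pz"])
        assert np.all(tfm.power >= 0)

    def test_scale_covariance_k_squared(self, montage):
        """Scaling the input by k scales power by k^2 and leaves Di fixed."""
        rng = np.random.default_rng(5)
        data = rng.normal(size=(2, 1, int(6 * 256)))
        base = _epochs_from_array(data, 256.0, montage)
        scaled = _epochs_from_array(3.0 * data, 256.0, montage)
        wcfg = ae.alpha_wavelet_config()
        t1 = ae.cwt_power(base, wcfg, channels=["Fp1"])
        t2 = ae.cwt_power(scaled, wcfg, channels=["Fp1"])
        assert np.allclose(t2.power, 9.0 * t1.power, rtol=1e-9)
        d1 = ae.compute_erd(t1)["Di"]
        d2 = ae.compute_erd(t2)["Di"]
        assert np.allclose(d1, d2, rtol=1e-9)

    def test_nyquist_guard(self, montage):
        ep = _sine_epochs([(10.0, 1.0)], sfreq=64.0, dur=6.0, montage=montage)
        with pytest.raises(ValueError, match="Nyquist"):
            ae.cwt_power(ep, ae.WaveletConfig(freqs_hz=(10.0, 40.0)),
                         channels=["Oz"])

    def test_coi_masks_edges(self, montage):
        ep = _sine_epochs([(10.0, 1.0)], montage=montage)
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config(), channels=["Oz"])
        assert tfm.coi is not None
        assert not tfm.coi[0, 0] and tfm.coi[0, tfm.coi.shape[1] // 2]

    def test_kernel_is_unit_ridge_normalized(self):
        k = morlet_kernel(10.0, 512.0, 7.0)
        t = np.arange(4096) / 512.0
        sig = 2.5 * np.cos(2 * np.pi * 10.0 * t)
        conv = np.convolve(sig, k, mode="same")
        mid = abs(conv[1000:3000])
        assert np.allclose(mid, 2.5, rtol=0.01)


class TestBandCourse:
    def test_constant_power_constant_course(self, montage):
        tfm = ae.TimeFreqMap(power=np.full((1, 11, 50), 3.0),
                             times=np.arange(50) / 10.0,
                             freqs=np.arange(8.0, 13.5, 0.5),
                             channels=("Oz",), n_trials=1)
        course = ae.band_power_course(tfm)
        assert np.allclose(course, 3.0)

    def test_single_hot_bin_diluted_by_band_mean(self, montage):
        power = np.zeros((1, 11, 50))
        j = 4  # the 10 Hz bin of the 8..13 grid
        power[0, j, :] = 7.0
        tfm = ae.TimeFreqMap(power=power, times=np.arange(50) / 10.0,
                             freqs=np.arange(8.0, 13.5, 0.5),
                             channels=("Oz",), n_trials=1)
        course = ae.band_power_course(tfm)
        assert np.allclose(course, 7.0 / 11.0)

    def test_empty_band_raises(self):
        tfm = ae.TimeFreqMap(power=np.ones((1, 3, 10)),
                             times=np.arange(10.0),
                             freqs=np.array([20.0, 21.0, 22.0]),
                             channels=("Oz",), n_trials=1)
        with pytest.raises(ValueError, match="band"):
            ae.band_power_course(tfm, (8.0, 13.0))


class TestErdIndex:
    def test_equal_powers_give_zero(self):
        assert ae.erd_index(2.0, 2.0) == 0.0

    def test_halved_power_gives_minus_half(self):
        assert ae.erd_index(1.0, 2.0) == -0.5

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            ae.erd_index(1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p_test=st.floats(0.0, 1e6), p_ref=st.floats(1e-6, 1e6))
    def test_bounds_and_identity(self, p_test, p_ref):
        di = ae.erd_index(p_test, p_ref)
        assert di >= -1.0
        if p_test == p_ref:
            assert di == 0.0

    def test_interval_outside_epoch_raises(self, montage):
        ep = _sine_epochs([(10.0, 1.0)], dur=3.0, montage=montage)
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config(), channels=["Oz"])
        with pytest.raises(ValueError, match="interval"):
            ae.compute_erd(tfm, test_s=(1.0, 2.0), ref_s=(-3.0, -2.5))


class TestOracleEquivalence:
    def test_cwt_and_voltage_paths_agree_on_alpha_signal(self, small_design,
                                                         quiet_effects):
        """On narrowband alpha data the wavelet path and the band-filtered
        voltage (Hilbert-equivalent) path give Di within 10% relative."""
        from dataclasses import replace
        eff = replace(quiet_effects, erd_depth={c: 0.5 for c in ae.CONDITIONS})
        rec = ae.generate_recording(small_design, eff, 1, "sadness", seed=6)
        ep = ae.epoch(rec, (-2.0, 4.0), baseline_s=None).select_conditions(["Sad"])
        roi = list(rec.montage.roi_sets["occipital_po"])
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config(), channels=roi)
        di_cwt = ae.compute_erd(tfm)["Di"].mean()
        di_volt = ae.erd_from_voltage(ep.select_channels(roi))["Di"].mean()
        di_hilb = oracle_erd(rec, "Sad", channels=roi)
        assert di_cwt == pytest.approx(di_volt, rel=0.10)
        assert di_cwt == pytest.approx(di_hilb, rel=0.10)


class TestTopography:
    def _erd_frame(self, montage, values):
        return pd.DataFrame({"channel": list(montage.scalp_channels),
                             "Di": values,
                             "erd_strength": -np.asarray(values)})

    def test_uniform_value_flat_map_and_rois(self, montage):
        erd = self._erd_frame(montage, np.full(32, -0.4))
        topo = ae.erd_topography(erd, montage)
        vals = topo.values[~np.isnan(topo.values)]
        assert np.allclose(vals, 0.4, atol=1e-6)
        assert all(v == pytest.approx(-0.4) for v in topo.roi_means.values())

    def test_roi_mean_is_member_mean(self, montage):
        values = np.full(32, -0.1)
        po = [montage.scalp_channels.index(c)
              for c in montage.roi_sets["parieto_occipital"]]
        values[po] = -0.6
        erd = self._erd_frame(montage, values)
        topo = ae.erd_topography(erd, montage)
        assert topo.roi_means["parieto_occipital"] == pytest.approx(-0.6)

    def test_missing_channel_raises_with_names(self, montage):
        erd = self._erd_frame(montage, np.full(32, -0.4)).iloc[:-2]
        with pytest.raises(ValueError, match="O2"):
            ae.erd_topography(erd, montage)

    def test_posterior_weighted_suppression_shows_in_rois(self, small_design,
                                                          quiet_effects):
        """Generator suppression is posterior-dominant: measured ERD strength
        is larger over the parieto-occipital ROI than frontally."""
        from dataclasses import replace
        eff = replace(quiet_effects, noise_scale=7.0,
                      erd_depth={c: 0.6 for c in ae.CONDITIONS})
        rec = ae.generate_recording(small_design, eff, 1, "sadness", seed=8)
        ep = ae.epoch(rec, (-2.0, 4.0), baseline_s=None).select_conditions(["Sad"])
        tfm = ae.cwt_power(ep, ae.alpha_wavelet_config())
        erd = ae.compute_erd(tfm)
        erd = erd[erd.channel.isin(rec.montage.scalp_channels)]
        topo = ae.erd_topography(erd, rec.montage)
        assert (-topo.roi_means["parieto_occipital"]
                > -topo.roi_means["prefrontal"])
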