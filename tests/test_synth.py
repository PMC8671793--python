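"""Generator contracts: determinism, spectral shape, injected-ERD ground
truth (validated by the independent Hilbert oracle), blink topography, and
the storage round trip."""
import numpy as np
import pytest
from dataclasses import replace
from scipy import signal, stats as sps

import affective_erd as ae
from affective_erd.synth import RecordingParseError, _blink_gains

from helpers import oracle_erd


@pytest.fixture(scope="module")
def design():
    return ae.StudyDesign(n_subjects=2, trials_per_block=30, sfreq=256.0)


class TestMontage:
    def test_default_montage_is_valid_and_complete(self, montage):
        assert len(montage.scalp_channels) == 32
        assert set(montage.eog_channels) == {"EOG_V", "EOG_H"}
        pos = montage.position_array()
        assert np.all(np.hypot(pos[:, 0], pos[:, 1]) <= 1.0 + 1e-9)
        for roi, members in montage.roi_sets.items():
            assert set(members) <= set(montage.channel_names)

    def test_roi_membership_matches_study_definitions(self, montage):
        assert montage.roi_sets["occipital_po"] == ("PO3", "PO4", "O1", "Oz", "O2")
        assert montage.roi_sets["prefrontal"] == ("Fp1", "Fp2", "AF3", "AF4")
        assert len(montage.roi_sets["parieto_occipital"]) == 10

    def test_bad_roi_member_rejected(self, montage):
        with pytest.raises(ValueError, match="ROI"):
            ae.Montage(channel_names=("Cz", "EOG_V", "EOG_H"),
                       positions={"Cz": (0, 0)},
                       roi_sets={"bad": ("Oz",)})


class TestDesignValidation:
    @pytest.mark.parametrize("kwargs", [
        {"trials_per_block": 20},        # not divisible by 3
        {"sfreq": 32.0},                 # under-sampled for the content
        {"iti_jitter_s": 5.0},           # would overlap trials
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ae.StudyDesign(**kwargs)


class TestGenerator:
    def test_same_seed_bit_identical(self, design):
        a = ae.generate_recording(design, ae.EffectSpec(), 1, "sadness", seed=7)
        b = ae.generate_recording(design, ae.EffectSpec(), 1, "sadness", seed=7)
        assert np.array_equal(a.data, b.data)
        assert a.events == b.events and a.meta == b.meta

    def test_different_subject_or_seed_differs(self, design):
        a = ae.generate_recording(design, ae.EffectSpec(), 1, "sadness", seed=7)
        b = ae.generate_recording(design, ae.EffectSpec(), 2, "sadness", seed=7)
        c = ae.generate_recording(design, ae.EffectSpec(), 1, "sadness", seed=8)
        assert not np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_trial_structure(self, design, small_recording):
        rec = small_recording
        onsets = np.array([s for s, _ in rec.events])
        assert len(rec.events) == 9
        # fixed 8 s inter-trial interval, >= 2 s lead-in, >= 4 s post
        assert np.allclose(np.diff(onsets) / rec.sfreq, 8.0)
        assert onsets[0] / rec.sfreq >= 2.0
        assert rec.n_samples - onsets[-1] >= 4.0 * rec.sfreq
        conds = [c for _, c in rec.events]
        assert sorted(set(conds)) == ["Sad", "SadNeu", "SadPos"]
        assert all(conds.count(c) == 3 for c in set(conds))

    def test_block_conditions(self, design):
        rec = ae.generate_recording(design, ae.EffectSpec(), 1, "disgust", seed=7)
        assert {c for _, c in rec.events} == {"Dis", "DisPos", "DisNeu"}

    def test_unknown_block_rejected(self, design):
        with pytest.raises(ValueError, match="block"):
            ae.generate_recording(design, ae.EffectSpec(), 1, "joy", seed=7)

    def test_no_suppression_means_flat_alpha_ratio(self, design, quiet_effects):
        """erd_depth = 0 everywhere, no noise, no components: post/pre alpha
        power ratio is 1 for every trial."""
        eff = replace(quiet_effects,
                      erd_depth={c: 0.0 for c in ae.CONDITIONS})
        rec = ae.generate_recording(design, eff, 1, "sadness", seed=3)
        di = oracle_erd(rec, "Sad", channels=["Oz"])
        assert di == pytest.approx(0.0, abs=0.02)

    def test_square_law_depth_half(self, design, quiet_effects):
        """Amplitude suppression 0.5 -> power ratio 0.25 -> Di = -0.75,
        recovered by the Hilbert oracle on a 30-trial block average."""
        eff = replace(quiet_effects,
                      erd_depth={c: 0.5 for c in ae.CONDITIONS})
        rec = ae.generate_recording(design, eff, 1, "sadness", seed=3)
        di = oracle_erd(rec, "Sad",
                        channels=list(rec.montage.roi_sets["occipital_po"]))
        assert di == pytest.approx(-0.75, abs=0.05)

    def test_oracle_erd_monotone_in_depth(self, design, quiet_effects):
        """Deeper injected suppression gives strictly lower measured alpha
        power in the test interval."""
        dis = []
        for depth in (0.2, 0.4, 0.6, 0.8):
            eff = replace(quiet_effects,
                          erd_depth={c: depth for c in ae.CONDITIONS})
            rec = ae.generate_recording(design, eff, 1, "sadness", seed=3)
            dis.append(oracle_erd(rec, "Sad", channels=["Oz"]))
        assert all(b < a for a, b in zip(dis, dis[1:]))

    def test_background_spectrum_follows_one_over_f(self, design):
        """With alpha, components and ocular sources disabled, the Welch
        log-log slope over 2-40 Hz matches the configured exponent."""
        eff = ae.EffectSpec(
            alpha_base_amp=0.0, blink_amp=0.0, saccade_amp=0.0,
            component_amplitudes={c: {k: 0.0 for k in ae.CONDITIONS}
                                  for c in ae.COMPONENT_TABLE})
        rec = ae.generate_recording(design, eff, 1, "sadness", seed=9)
        f, psd = signal.welch(rec.data[rec.montage.index("Cz")], rec.sfreq,
                              nperseg=int(8 * rec.sfreq))
        mask = (f >= 2.0) & (f <= 40.0)
        slope = sps.linregress(np.log(f[mask]), np.log(psd[mask])).slope
        assert slope == pytest.approx(-eff.noise_exponent, abs=0.15)

    def test_blink_correlation_strongest_frontally(self, design):
        """Blink contamination correlates with EOG_V most at frontal sites
        and decays with the injected front-to-back gain profile."""
        rec = ae.generate_recording(design, ae.EffectSpec(), 1, "sadness",
                                    seed=13)
        eogv = rec.data[rec.montage.index("EOG_V")]
        gains = _blink_gains(rec.montage, 1.0, 0.6)
        corrs, gvals = [], []
        for ch in rec.montage.scalp_channels:
            i = rec.montage.index(ch)
            corrs.append(abs(np.corrcoef(rec.data[i], eogv)[0, 1]))
            gvals.append(gains[i])
        corrs, gvals = np.array(corrs), np.array(gvals)
        fp1 = rec.montage.scalp_channels.index("Fp1")
        oz = rec.montage.scalp_channels.index("Oz")
        assert corrs[fp1] > 0.5 > corrs[oz]
        assert sps.spearmanr(corrs, gvals).statistic > 0.7

    def test_correct_trial_rate_realistic(self, design):
        rec = ae.generate_recording(design, ae.EffectSpec(), 1, "sadness",
                                    seed=13)
        assert np.mean(rec.meta["correct"]) > 0.9


class TestRecordingValidation:
    def test_event_beyond_data_rejected(self, montage):
        data = np.zeros((34, 100))
        with pytest.raises(ValueError, match="outside"):
            ae.Recording(data=data, sfreq=100.0, montage=montage,
                         events=[(200, "Sad")])

    def test_non_increasing_events_rejected(self, montage):
        data = np.zeros((34, 100))
        with pytest.raises(ValueError, match="increasing"):
            ae.Recording(data=data, sfreq=100.0, montage=montage,
                         events=[(50, "Sad"), (50, "Sad")])

    def test_nan_rejected(self, montage):
        data = np.zeros((34, 100))
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN|Inf"):
            ae.Recording(data=data, sfreq=100.0, montage=montage, events=[])


class TestStorage:
    def test_hdf5_round_trip_exact(self, small_recording, tmp_path):
        path = tmp_path / "rec.h5"
        ae.write_recording(small_recording, path)
        back = ae.read_recording(path)
        assert np.allclose(back.data, small_recording.data, atol=1e-6)
        assert back.events == small_recording.events
        assert back.meta == small_recording.meta
        assert back.montage.channel_names == small_recording.montage.channel_names

    def test_csv_round_trip(self, montage, tmp_path):
        rng = np.random.default_rng(0)
        rec = ae.Recording(data=rng.normal(size=(34, 200)), sfreq=100.0,
                           montage=montage, events=[(50, "Sad")],
                           meta={"subject": "S01"})
        ae.write_recording_csv(rec, tmp_path / "rec")
        back = ae.read_recording_csv(tmp_path / "rec")
        assert np.allclose(back.data, rec.data, atol=1e-6)
        assert back.events == rec.events

    def test_event_past_end_is_parse_error(self, montage, tmp_path):
        rec = ae.Recording(data=np.zeros((34, 100)), sfreq=100.0,
                           montage=montage, events=[(50, "Sad")], meta={})
        path = tmp_path / "rec.h5"
        ae.write_recording(rec, path)
        import h5py
        with h5py.File(path, "r+") as f:
            f["event_sample"][0] = 1000
        with pytest.raises(RecordingParseError, match="event"):
            ae.read_recording(path)

    def test_empty_events_round_trip_and_empty_epochs(self, montage, tmp_path):
        rec = ae.Recording(data=np.zeros((34, 1000)), sfreq=100.0,
                           montage=montage, events=[], meta={})
        path = tmp_path / "rec.h5"
        ae.write_recording(rec, path)
        back = ae.read_recording(path)
        assert back.events == []
        ep = ae.epoch(back, (-0.2, 4.0))
        assert ep.n_trials == 0


class TestExpectedScores:
    def test_noise_free_scores_match_injected_ordering(self):
        exp = ae.noise_free_component_scores(ae.StudyDesign(sfreq=512.0),
                                             ae.EffectSpec())
        lpp = exp[exp.component == "LPP"].set_index("condition")["expected_uv"]
        assert lpp["Dis"] > lpp["Sad"] > 0
        n1 = exp[exp.component == "N1"].set_index("condition")["expected_uv"]
        assert n1["Sad"] < n1["SadNeu"] < 0
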