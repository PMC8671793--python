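import numpy as np
import pytest

import affective_erd as ae


@pytest.fixture(scope="session")
def montage():
    return ae.default_montage()


@pytest.fixture(scope="session")
def small_design():
    """Tiny fast design: 9 trials per block at 256 Hz."""
    return ae.StudyDesign(n_subjects=2, trials_per_block=9, sfreq=256.0)


@pytest.fixture(scope="session")
def small_recording(small_design):
    return ae.generate_recording(small_design, ae.EffectSpec(), 1, "sadness",
                                 seed=101)


@pytest.fixture(scope="session")
def quiet_effects():
    """No noise, no ocular activity, no ERP bumps: alpha + ERD only."""
    return ae.EffectSpec(
        noise_scale=0.0, eog_noise_scale=0.0, blink_amp=0.0, saccade_amp=0.0,
        component_amplitudes={c: {k: 0.0 for k in ae.CONDITIONS}
                              for c in ae.COMPONENT_TABLE},
        erd_subject_sd=0.0, comp_subject_sd=0.0, comp_trial_jitter=0.0)


def sine_recording(freq_hz, sfreq=512.0, dur_s=8.0, amp=1.0, n_channels=None,
                   montage=None):
    """Recording whose scalp channels all carry one pure sinusoid."""
    montage = montage or ae.default_montage()
    n = int(dur_s * sfreq)
    t = np.arange(n) / sfreq
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(sig, (len(montage.channel_names), 1))
    return ae.Recording(data=data, sfreq=sfreq, montage=montage, events=[],
                        meta={})
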