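"""Independent reference oracles used by the tests.

These deliberately avoid the package's wavelet code path: alpha power is
measured by Butterworth band-filtering plus the squared Hilbert envelope, so
agreement between the two routes is evidence, not tautology.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from affective_erd import Recording, epoch
from affective_erd.tfr import DEFAULT_REF_S, DEFAULT_TEST_S


def hilbert_band_power(x: np.ndarray, sfreq: float,
                       band: tuple[float, float] = (8.0, 13.0),
                       order: int = 4) -> np.ndarray:
    """Squared Hilbert envelope of the band-filtered signal (last axis=time)."""
    sos = signal.butter(order, band, btype="bandpass", fs=sfreq, output="sos")
    filt = signal.sosfiltfilt(sos, x, axis=-1)
    return np.abs(signal.hilbert(filt, axis=-1)) ** 2


def oracle_erd(rec: Recording, condition: str,
               channels: list[str] | None = None,
               test_s: tuple[float, float] = DEFAULT_TEST_S,
               ref_s: tuple[float, float] = DEFAULT_REF_S,
               band: tuple[float, float] = (8.0, 13.0)) -> float:
    """ERD index measured by the band-filter + Hilbert-envelope route.

    Power per interval is the mean of the squared envelope over the interval
    samples, pooled over the condition's trials and the given channels.
    """
    ep = epoch(rec, (-2.0, 4.0), baseline_s=None).select_conditions([condition])
    if channels is not None:
        ep = ep.select_channels(channels)
    env2 = hilbert_band_power(ep.data, rec.sfreq, band)
    tmask = (ep.times >= test_s[0]) & (ep.times <= test_s[1])
    rmask = (ep.times >= ref_s[0]) & (ep.times <= ref_s[1])
    p_test = env2[:, :, tmask].mean()
    p_ref = env2[:, :, rmask].mean()
    return float((p_test - p_ref) / p_ref)


def brute_force_oneway(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Textbook sum-of-squares decomposition for one-way ANOVA.

    Returns (F, df1, df2) computed directly from group means, independent of
    the package implementation.
    """
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df1, df2 = len(groups) - 1, len(all_vals) - len(groups)
    return ssb / df1 / (ssw / df2), df1, df2
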