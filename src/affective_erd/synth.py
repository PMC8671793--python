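"""Synthetic EEG for an affective picture-viewing study.

Emulates a two-block design (a sadness block and a disgust block) in which a
participant views 90 pictures per block — 30 negative, 30 positive, 30 neutral,
in randomized order — each trial being 4 s of fixation followed by 4 s of
picture presentation, recorded from a 32-channel 10-20 scalp montage plus two
EOG leads at 1024 Hz.

The generated signal is built from four additive parts:

* 1/f background activity, independent per channel, with a low-frequency knee
  so that very slow drift stays bounded (mimicking an amplifier high-pass);
* a continuous 10 Hz alpha oscillator with a posterior-focal scalp topography
  and a phase random walk (so it is induced, not phase-locked), whose amplitude
  envelope is suppressed after every picture onset by a condition-dependent
  depth — this is the ground truth for event-related desynchronization (ERD);
* stimulus-locked ERP deflections (N1, EPN, P2, N2, P3, LPP) injected as
  Gaussian-windowed half-sine bumps on their target electrode groups;
* ocular artifacts: blinks mixed into frontal channels with a gain that decays
  with distance from the front of the montage, and horizontal saccades.

The alpha envelope is shaped so that the time average of its square over the
ERD test interval (1-2 s after onset) is exactly ``(1 - depth)**2`` while the
envelope minimum sits uniquely at ``erd_peak_s`` (1 s), and the envelope is
back at baseline well before the next trial's reference interval.  Hence the
analytic expectation for the ERD index is ``Di = (1 - depth)**2 - 1``.
"""
from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy import fft as sp_fft
from scipy.fft import next_fast_len

logger = logging.getLogger("affective_erd")

# --------------------------------------------------------------------------
# conditions and blocks
# --------------------------------------------------------------------------

CONDITIONS: tuple[str, ...] = ("Sad", "SadPos", "SadNeu", "Dis", "DisPos", "DisNeu")
BLOCKS: tuple[str, str] = ("sadness", "disgust")
BLOCK_CONDITIONS: dict[str, tuple[str, str, str]] = {
    "sadness": ("Sad", "SadPos", "SadNeu"),
    "disgust": ("Dis", "DisPos", "DisNeu"),
}
#: broad affective category of each condition
VALENCE: dict[str, str] = {
    "Sad": "negative", "Dis": "negative",
    "SadPos": "positive", "DisPos": "positive",
    "SadNeu": "neutral", "DisNeu": "neutral",
}
#: block each condition belongs to
CONDITION_BLOCK: dict[str, str] = {
    "Sad": "sadness", "SadPos": "sadness", "SadNeu": "sadness",
    "Dis": "disgust", "DisPos": "disgust", "DisNeu": "disgust",
}

# --------------------------------------------------------------------------
# montage
# --------------------------------------------------------------------------

#: 2-D positions on the unit disc (nose at the top, +y toward the nose,
#: +x toward the right ear) for the 32-lead scalp cap.
SCALP_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "AF3": (-0.33, 0.78), "AF4": (0.33, 0.78),
    "F7": (-0.793, 0.576), "F3": (-0.37, 0.55), "Fz": (0.0, 0.53),
    "F4": (0.37, 0.55), "F8": (0.793, 0.576),
    "FC5": (-0.69, 0.28), "FC1": (-0.22, 0.28),
    "FC2": (0.22, 0.28), "FC6": (0.69, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.69, -0.28), "CP1": (-0.22, -0.28),
    "CP2": (0.22, -0.28), "CP6": (0.69, -0.28),
    "P7": (-0.793, -0.576), "P3": (-0.37, -0.55), "Pz": (0.0, -0.53),
    "P4": (0.37, -0.55), "P8": (0.793, -0.576),
    "PO3": (-0.33, -0.78), "PO4": (0.33, -0.78),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}

EOG_CHANNELS: tuple[str, str] = ("EOG_V", "EOG_H")

DEFAULT_ROI_SETS: dict[str, tuple[str, ...]] = {
    "occipital_po": ("PO3", "PO4", "O1", "Oz", "O2"),
    "prefrontal": ("Fp1", "Fp2", "AF3", "AF4"),
    "parieto_occipital": ("P7", "P3", "Pz", "P4", "P8",
                          "PO3", "PO4", "O1", "Oz", "O2"),
}


@dataclass(frozen=True)
class Montage:
    """Electrode layout: ordered channel labels, scalp positions, ROI groups."""

    channel_names: tuple[str, ...]
    positions: Mapping[str, tuple[float, float]]
    roi_sets: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel labels in montage")
        for name in self.scalp_channels:
            if name not in self.positions:
                raise ValueError(f"scalp channel {name!r} has no position")
            x, y = self.positions[name]
            if math.hypot(x, y) > 1.0 + 1e-9:
                raise ValueError(f"position of {name!r} lies outside the unit disc")
        for roi, members in self.roi_sets.items():
            for ch in members:
                if ch not in self.channel_names:
                    raise ValueError(f"ROI {roi!r} member {ch!r} not in montage")

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c not in EOG_CHANNELS)

    @property
    def eog_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c in EOG_CHANNELS)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    @property
    def scalp_indices(self) -> np.ndarray:
        return self.indices(self.scalp_channels)

    @property
    def eog_indices(self) -> np.ndarray:
        return self.indices(self.eog_channels)

    def roi_indices(self, roi: str) -> np.ndarray:
        return self.indices(self.roi_sets[roi])

    def position_array(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = self.scalp_channels if names is None else names
        return np.array([self.positions[n] for n in names], dtype=float)

    def to_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "positions": {k: list(v) for k, v in self.positions.items()},
            "roi_sets": {k: list(v) for k, v in self.roi_sets.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Montage":
        return cls(
            channel_names=tuple(d["channel_names"]),
            positions={k: (float(v[0]), float(v[1]))
                       for k, v in d["positions"].items()},
            roi_sets={k: tuple(v) for k, v in d["roi_sets"].items()},
        )


def default_montage() -> Montage:
    """The 32-lead 10-20 scalp montage plus vertical/horizontal EOG."""
    return Montage(
        channel_names=tuple(SCALP_POSITIONS) + EOG_CHANNELS,
        positions=dict(SCALP_POSITIONS),
        roi_sets=dict(DEFAULT_ROI_SETS),
    )


# --------------------------------------------------------------------------
# study design
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Trial structure and recording parameters of the picture-viewing study."""

    n_subjects: int = 20
    n_blocks: int = 2
    trials_per_block: int = 90
    fixation_s: float = 4.0
    picture_s: float = 4.0
    sfreq: float = 1024.0
    #: optional uniform inter-trial jitter added to each fixation (s); 0 = fixed 8 s ITI
    iti_jitter_s: float = 0.0
    lead_in_s: float = 2.0
    tail_s: float = 0.5

    #: lowest sampling rate that still resolves all synthesized narrowband
    #: content (10 Hz alpha plus ERP bumps) with a generous margin
    _MIN_SFREQ = 64.0

    def __post_init__(self) -> None:
        if self.trials_per_block % 3 != 0:
            raise ValueError("trials_per_block must be divisible by 3 "
                             "(equal counts per condition)")
        if self.sfreq < self._MIN_SFREQ:
            raise ValueError(
                f"sfreq {self.sfreq} Hz too low for the synthesized content "
                f"(need >= {self._MIN_SFREQ} Hz)")
        if self.iti_jitter_s < 0 or self.iti_jitter_s >= self.fixation_s:
            raise ValueError("iti_jitter_s must lie in [0, fixation_s)")
        if self.fixation_s < 1.0 or self.picture_s <= 0:
            raise ValueError("fixation_s must be >= 1 s and picture_s > 0")

    @property
    def trial_s(self) -> float:
        return self.fixation_s + self.picture_s

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects, "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "fixation_s": self.fixation_s, "picture_s": self.picture_s,
            "sfreq": self.sfreq, "iti_jitter_s": self.iti_jitter_s,
            "lead_in_s": self.lead_in_s, "tail_s": self.tail_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


# --------------------------------------------------------------------------
# injected effects
# --------------------------------------------------------------------------

#: scoring windows (s, relative to picture onset) and target electrode group
#: for the six ERP components.
COMPONENT_TABLE: dict[str, dict] = {
    "N1": {"window_s": (0.100, 0.200), "roi": "occipital_po", "polarity": -1},
    "EPN": {"window_s": (0.270, 0.470), "roi": "occipital_po", "polarity": -1},
    "P2": {"window_s": (0.130, 0.190), "roi": "prefrontal", "polarity": +1},
    "N2": {"window_s": (0.200, 0.250), "roi": "prefrontal", "polarity": -1},
    "P3": {"window_s": (0.250, 0.380), "roi": "prefrontal", "polarity": +1},
    "LPP": {"window_s": (0.700, 4.000), "roi": "prefrontal", "polarity": +1},
}

#: default injected peak amplitudes (uV, signed) per component x condition.
#: Orderings encode the qualitative findings the analysis should recover:
#: N1/EPN larger (more negative) for emotional than neutral pictures; P2, P3
#: and LPP largest for disgust; N2 most negative for disgust.
DEFAULT_COMPONENT_AMPLITUDES: dict[str, dict[str, float]] = {
    "N1": {"Sad": -5.0, "SadPos": -4.5, "SadNeu": -2.5,
           "Dis": -5.0, "DisPos": -4.5, "DisNeu": -2.5},
    "EPN": {"Sad": -3.5, "SadPos": -3.2, "SadNeu": -1.2,
            "Dis": -3.5, "DisPos": -3.2, "DisNeu": -1.2},
    "P2": {"Sad": 4.0, "SadPos": 4.2, "SadNeu": 3.8,
           "Dis": 7.0, "DisPos": 5.5, "DisNeu": 3.5},
    "N2": {"Sad": -2.5, "SadPos": -2.5, "SadNeu": -2.5,
           "Dis": -4.5, "DisPos": -2.6, "DisNeu": -2.5},
    "P3": {"Sad": 4.0, "SadPos": 4.2, "SadNeu": 4.0,
           "Dis": 7.0, "DisPos": 4.5, "DisNeu": 4.0},
    "LPP": {"Sad": 2.5, "SadPos": 2.3, "SadNeu": 2.2,
            "Dis": 4.5, "DisPos": 2.4, "DisNeu": 2.2},
}

#: alpha suppression depth (fraction of alpha amplitude removed at the
#: envelope plateau) per condition: emotional > neutral, no sad/disgust gap.
DEFAULT_ERD_DEPTH: dict[str, float] = {
    "Sad": 0.55, "SadPos": 0.50, "SadNeu": 0.30,
    "Dis": 0.55, "DisPos": 0.50, "DisNeu": 0.30,
}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect sizes and noise parameters for the generator.

    Amplitudes are in microvolt; the alpha suppression envelope is documented
    in the module docstring.  Defaults were fixed by a single calibration
    simulation so that the injected contrasts are recoverable at the study's
    sample size; they are study conditions, not tuning knobs.
    """

    alpha_base_amp: float = 25.0          # uV, alpha amplitude at the topography peak
    alpha_freq_hz: float = 10.0           # center of the 8-13 Hz band
    alpha_phase_jitter: float = 1.5       # rad / sqrt(s) phase random walk
    erd_depth: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERD_DEPTH))
    erd_onset_s: float = 0.0              # suppression starts at picture onset
    erd_peak_s: float = 1.0               # envelope minimum (Fig-style trough)
    erd_sustain_s: float = 2.0            # end of the controlled plateau
    erd_recover_s: float = 4.0            # recovery horizon within the picture
    erd_plateau_tilt: float = 0.15        # linear tilt of squared envelope on the plateau
    erd_recovery_frac: float = 0.8        # fraction of the dip recovered by erd_recover_s
    erd_subject_sd: float = 0.08          # between-subject sd of the depth
    component_amplitudes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_COMPONENT_AMPLITUDES.items()})
    component_shape_sigma: float = 0.3    # Gaussian window sd in window-normalized units
    component_spatial_sigma: float = 0.35  # scalp falloff (unit-disc distance)
    comp_subject_sd: float = 0.15         # between-subject lognormal sd (multiplicative)
    comp_trial_jitter: float = 0.20       # trial-to-trial lognormal sd (multiplicative)
    noise_exponent: float = 1.0           # 1/f^beta background slope
    noise_scale: float = 7.0              # uV RMS of background per scalp channel
    noise_knee_hz: float = 1.0            # spectrum flattens below this frequency
    blink_rate: float = 15.0              # events / min
    blink_amp: float = 200.0              # uV at the vertical EOG
    blink_dur_s: float = 0.35
    blink_frontal_gain: float = 0.40      # scalp gain at the frontal pole
    blink_spatial_sigma: float = 0.6      # decay of blink gain with distance from front
    saccade_rate: float = 8.0             # events / min on the horizontal EOG
    saccade_amp: float = 40.0             # uV
    eog_noise_scale: float = 4.0          # uV RMS of EOG-channel noise
    eog_alpha_gain: float = 0.05
    correct_rate: float = 0.995           # behavioral accuracy per trial

    def __post_init__(self) -> None:
        for cond, s in self.erd_depth.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"erd_depth[{cond!r}] = {s} outside [0, 1]")
        if not (self.erd_onset_s <= self.erd_peak_s <= self.erd_sustain_s
                <= self.erd_recover_s):
            raise ValueError("ERD envelope breakpoints must be ordered "
                             "onset <= peak <= sustain <= recover")
        for comp, meta in COMPONENT_TABLE.items():
            w0, w1 = meta["window_s"]
            if w0 < 0:
                raise ValueError(f"{comp} window starts before picture onset")

    def depth_for(self, condition: str) -> float:
        return float(self.erd_depth.get(condition, 0.0))

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("alpha_base_amp", "alpha_freq_hz", "alpha_phase_jitter",
                      "erd_onset_s", "erd_peak_s", "erd_sustain_s",
                      "erd_recover_s", "erd_plateau_tilt", "erd_recovery_frac",
                      "erd_subject_sd", "component_shape_sigma",
                      "component_spatial_sigma", "comp_subject_sd",
                      "comp_trial_jitter", "noise_exponent", "noise_scale",
                      "noise_knee_hz", "blink_rate", "blink_amp", "blink_dur_s",
                      "blink_frontal_gain", "blink_spatial_sigma",
                      "saccade_rate", "saccade_amp", "eog_noise_scale",
                      "eog_alpha_gain", "correct_rate")
        }
        d["erd_depth"] = dict(self.erd_depth)
        d["component_amplitudes"] = {k: dict(v)
                                     for k, v in self.component_amplitudes.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectSpec":
        return cls(**dict(d))


def null_effects() -> EffectSpec:
    """Effects with every condition contrast removed (for type-I studies).

    Background noise, alpha with a condition-independent suppression, and
    condition-independent ERP bumps remain, so the null data still look like
    EEG; only the between-condition differences are zeroed.
    """
    depth = {c: 0.4 for c in CONDITIONS}
    amps = {comp: {c: float(np.mean(list(v.values()))) for c in CONDITIONS}
            for comp, v in DEFAULT_COMPONENT_AMPLITUDES.items()}
    return EffectSpec(erd_depth=depth, component_amplitudes=amps)


# --------------------------------------------------------------------------
# recording container
# --------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multi-channel EEG (uV) with stimulus events.

    ``data`` has shape ``(n_channels, n_samples)``; ``events`` is a list of
    ``(onset_sample, condition)`` pairs at picture onsets, strictly increasing.
    """

    data: np.ndarray
    sfreq: float
    montage: Montage
    events: list[tuple[int, str]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage lists "
                f"{len(self.montage.channel_names)} channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        samples = [int(s) for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for s, cond in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event at sample {s} outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def scalp_data(self) -> np.ndarray:
        return self.data[self.montage.scalp_indices]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sfreq, self.montage,
                         list(self.events), dict(self.meta))


# --------------------------------------------------------------------------
# waveform primitives (shared with the expected-value helpers)
# --------------------------------------------------------------------------


def component_shape(n_samples: int, sigma: float = 0.3) -> np.ndarray:
    """Gaussian-windowed half-sine bump sampled on ``n_samples`` points.

    Unit peak at the window center; zero at the edges.
    """
    u = np.linspace(0.0, 1.0, n_samples)
    return np.sin(np.pi * u) * np.exp(-((u - 0.5) ** 2) / (2.0 * sigma ** 2))


def alpha_envelope(t: np.ndarray, depth: float, *, onset_s: float = 0.0,
                   peak_s: float = 1.0, sustain_s: float = 2.0,
                   recover_s: float = 4.0, plateau_tilt: float = 0.15,
                   recovery_frac: float = 0.8) -> np.ndarray:
    """Alpha amplitude envelope for one trial, on times ``t`` (s, onset = 0).

    Piecewise: 1 before onset; raised-cosine ramp down to the trough at
    ``peak_s``; a plateau on [peak_s, sustain_s] whose squared value is linear
    in time with mean exactly ``(1-depth)**2``; exponential recovery toward
    ``1 - (1-recovery_frac)*depth`` by ``recover_s``; relaxation back to 1
    afterwards (the next fixation).
    """
    depth = float(np.clip(depth, 0.0, 1.0))
    env = np.ones_like(t, dtype=float)
    if depth == 0.0:
        return env
    e2 = (1.0 - depth) ** 2
    mid = 0.5 * (peak_s + sustain_s)
    # squared-envelope tilt: rising through the plateau => unique trough at peak_s
    m1 = math.sqrt(e2 * (1.0 - plateau_tilt * (mid - peak_s)))
    m2 = math.sqrt(e2 * (1.0 + plateau_tilt * (sustain_s - mid)))
    r = 1.0 - (1.0 - recovery_frac) * depth
    tau_rec = max(0.3, (recover_s - sustain_s) / 2.5)
    tau_fix = 0.5

    ramp = (t >= onset_s) & (t < peak_s)
    if peak_s > onset_s:
        u = (t[ramp] - onset_s) / (peak_s - onset_s)
        env[ramp] = 1.0 - (1.0 - m1) * (1.0 - np.cos(np.pi * u)) / 2.0
    plateau = (t >= peak_s) & (t < sustain_s)
    env[plateau] = np.sqrt(e2 * (1.0 + plateau_tilt * (t[plateau] - mid)))
    rec = (t >= sustain_s) & (t < recover_s)
    env[rec] = r - (r - m2) * np.exp(-(t[rec] - sustain_s) / tau_rec)
    env_rec_end = r - (r - m2) * math.exp(-(recover_s - sustain_s) / tau_rec)
    fix = t >= recover_s
    env[fix] = 1.0 - (1.0 - env_rec_end) * np.exp(-(t[fix] - recover_s) / tau_fix)
    return env


def expected_erd_di(depth: float) -> float:
    """Analytic ERD index implied by an amplitude suppression ``depth``."""
    return (1.0 - depth) ** 2 - 1.0


def _alpha_topography(montage: Montage, spatial_sigma: float = 0.55) -> np.ndarray:
    """Posterior-focal alpha gain per channel (1 at the occipital pole)."""
    w = np.zeros(len(montage.channel_names))
    for i, name in enumerate(montage.channel_names):
        if name in EOG_CHANNELS:
            w[i] = 0.0
            continue
        x, y = montage.positions[name]
        d2 = (x - 0.0) ** 2 + (y + 0.85) ** 2
        w[i] = 0.2 + 0.8 * math.exp(-d2 / (2.0 * spatial_sigma ** 2))
    return w


def _erd_spatial_factor(montage: Montage) -> np.ndarray:
    """Per-channel scaling of the suppression depth: full posterior, weaker
    centrally, weakest frontally — makes the measured ERD posterior-dominant."""
    f = np.zeros(len(montage.channel_names))
    for i, name in enumerate(montage.channel_names):
        if name in EOG_CHANNELS:
            f[i] = 1.0
            continue
        y = montage.positions[name][1]
        f[i] = 1.0 if y <= -0.2 else (0.75 if y < 0.3 else 0.6)
    return f


def _blink_gains(montage: Montage, peak_gain: float, sigma: float) -> np.ndarray:
    g = np.zeros(len(montage.channel_names))
    for i, name in enumerate(montage.channel_names):
        if name in EOG_CHANNELS:
            continue
        x, y = montage.positions[name]
        d2 = x ** 2 + (y - 1.0) ** 2
        g[i] = peak_gain * math.exp(-d2 / (2.0 * sigma ** 2))
    return g


def _saccade_gains(montage: Montage) -> np.ndarray:
    g = np.zeros(len(montage.channel_names))
    for i, name in enumerate(montage.channel_names):
        if name in EOG_CHANNELS:
            continue
        x, y = montage.positions[name]
        g[i] = 0.12 * x * max(0.0, y + 0.2)
    return g


def _roi_weights(montage: Montage, roi: str, sigma: float) -> np.ndarray:
    """Scalp pattern for an injected component: 1 on the ROI, Gaussian falloff
    with distance to the nearest ROI electrode elsewhere; 0 on EOG."""
    members = montage.roi_sets[roi]
    mpos = np.array([montage.positions[m] for m in members])
    w = np.zeros(len(montage.channel_names))
    for i, name in enumerate(montage.channel_names):
        if name in EOG_CHANNELS:
            continue
        p = np.array(montage.positions[name])
        d2 = np.min(np.sum((mpos - p) ** 2, axis=1))
        w[i] = math.exp(-d2 / (2.0 * sigma ** 2))
    return w


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float, exponent: float, knee_hz: float,
                rms: float) -> np.ndarray:
    """1/f^exponent noise (flat below ``knee_hz``), normalized to ``rms`` uV."""
    if rms == 0.0:
        return np.zeros((n_channels, n_samples))
    nfft = next_fast_len(n_samples)
    # float32 spectral synthesis: ample precision for noise, ~2x faster FFTs
    white = rng.standard_normal((n_channels, nfft), dtype=np.float32)
    spec = sp_fft.rfft(white, axis=-1)
    f = sp_fft.rfftfreq(nfft, d=1.0 / sfreq)
    gain = np.empty(len(f), dtype=np.float32)
    gain[0] = 0.0
    fk = np.maximum(f[1:], knee_hz)
    gain[1:] = fk ** (-exponent / 2.0)
    x = sp_fft.irfft(spec * gain, n=nfft, axis=-1)[:, :n_samples]
    x = x.astype(float)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x * (rms / std)


def _subject_key(subject) -> int:
    if isinstance(subject, str):
        m = re.search(r"\d+", subject)
        return int(m.group()) if m else abs(hash(subject)) % (2 ** 20)
    return int(subject)


def _rngs(seed: int, subject, block: str
          ) -> tuple[np.random.Generator, np.random.Generator]:
    """(block-level rng, subject-level rng).

    Subject traits (alpha-suppression offset, component gains) come from the
    subject-level stream so they are identical across the subject's two
    blocks, as stable individual differences should be.
    """
    if block not in BLOCKS:
        raise ValueError(f"block must be one of {BLOCKS}, got {block!r}")
    subj_key = _subject_key(subject)
    block_ss = np.random.SeedSequence(entropy=int(seed),
                                      spawn_key=(subj_key, BLOCKS.index(block)))
    subj_ss = np.random.SeedSequence(entropy=int(seed),
                                     spawn_key=(subj_key, 1000))
    return np.random.default_rng(block_ss), np.random.default_rng(subj_ss)


# --------------------------------------------------------------------------
# the generator
# --------------------------------------------------------------------------


def generate_recording(design: StudyDesign, effects: EffectSpec, subject,
                       block: str, seed: int,
                       montage: Montage | None = None) -> Recording:
    """Generate one subject x block continuous recording.

    Deterministic in ``(design, effects, subject, block, seed)``.  Conditions
    of the block are drawn in randomized order, ``trials_per_block/3`` each.
    """
    montage = montage or default_montage()
    rng, subj_rng = _rngs(seed, subject, block)
    sfreq = design.sfreq
    n_ch = len(montage.channel_names)
    n_trials = design.trials_per_block
    trial_s = design.trial_s

    # condition sequence: equal counts, randomized
    conds = list(BLOCK_CONDITIONS[block]) * (n_trials // 3)
    order = rng.permutation(n_trials)
    conds = [conds[i] for i in order]

    # trial onsets (picture onsets)
    fixations = np.full(n_trials, design.fixation_s)
    if design.iti_jitter_s > 0:
        fixations = fixations + rng.uniform(-design.iti_jitter_s,
                                            design.iti_jitter_s, n_trials)
    starts = design.lead_in_s + np.concatenate(
        ([0.0], np.cumsum(fixations[:-1] + design.picture_s)))
    onsets_s = starts + fixations
    if np.any(np.diff(onsets_s) < design.picture_s):
        raise ValueError("trial windows overlap; reduce iti_jitter_s")
    total_s = onsets_s[-1] + design.picture_s + design.tail_s
    n_samp = int(round(total_s * sfreq))
    onset_samples = np.round(onsets_s * sfreq).astype(int)
    t_axis = np.arange(n_samp) / sfreq

    data = _pink_noise(rng, n_ch, n_samp, sfreq, effects.noise_exponent,
                       effects.noise_knee_hz, effects.noise_scale)
    # EOG channels get their own (smaller) broadband noise
    eog_idx = montage.eog_indices
    data[eog_idx] = _pink_noise(rng, len(eog_idx), n_samp, sfreq,
                                effects.noise_exponent, effects.noise_knee_hz,
                                effects.eog_noise_scale)

    # ---- alpha oscillator with ERD envelope -----------------------------
    depth_offset = subj_rng.normal(0.0, effects.erd_subject_sd)
    spatial = _erd_spatial_factor(montage)
    spatial_levels = np.unique(spatial)
    phase = (2.0 * np.pi * effects.alpha_freq_hz * t_axis
             + np.cumsum(rng.normal(0.0, effects.alpha_phase_jitter
                                    / math.sqrt(sfreq), n_samp)))
    carrier = np.cos(phase)
    topo = _alpha_topography(montage)
    topo[eog_idx] = effects.eog_alpha_gain
    if effects.alpha_base_amp > 0:
        env_by_level = {}
        for lev in spatial_levels:
            env = np.ones(n_samp)
            for onset, cond in zip(onset_samples, conds):
                s = effects.depth_for(cond)
                if s <= 0:
                    continue
                s_eff = float(np.clip((s + depth_offset) * lev, 0.0, 0.97))
                i1 = min(n_samp, onset + int(round(trial_s * sfreq)))
                tt = (np.arange(onset, i1) - onset) / sfreq
                env[onset:i1] = alpha_envelope(
                    tt, s_eff, onset_s=effects.erd_onset_s,
                    peak_s=effects.erd_peak_s, sustain_s=effects.erd_sustain_s,
                    recover_s=effects.erd_recover_s,
                    plateau_tilt=effects.erd_plateau_tilt,
                    recovery_frac=effects.erd_recovery_frac)
            env_by_level[lev] = env * carrier * effects.alpha_base_amp
        for i in range(n_ch):
            data[i] += topo[i] * env_by_level[spatial[i]]

    # ---- ERP components -------------------------------------------------
    comp_subject = {comp: math.exp(subj_rng.normal(0.0, effects.comp_subject_sd)
                                   - effects.comp_subject_sd ** 2 / 2.0)
                    for comp in COMPONENT_TABLE}
    weights = {roi: _roi_weights(montage, roi, effects.component_spatial_sigma)
               for roi in {m["roi"] for m in COMPONENT_TABLE.values()}}
    shapes = {}
    for comp, meta in COMPONENT_TABLE.items():
        w0, w1 = meta["window_s"]
        i0, i1 = int(round(w0 * sfreq)), int(round(w1 * sfreq))
        shapes[comp] = (i0, component_shape(max(2, i1 - i0),
                                            effects.component_shape_sigma))
    sd = effects.comp_trial_jitter
    for onset, cond in zip(onset_samples, conds):
        for comp, meta in COMPONENT_TABLE.items():
            amp = effects.component_amplitudes.get(comp, {}).get(cond, 0.0)
            if amp == 0.0:
                continue
            jitter = math.exp(rng.normal(0.0, sd) - sd ** 2 / 2.0) if sd > 0 else 1.0
            i0, shape = shapes[comp]
            a, b = onset + i0, min(n_samp, onset + i0 + len(shape))
            seg = shape[: b - a] * (amp * comp_subject[comp] * jitter)
            data[:, a:b] += weights[meta["roi"]][:, None] * seg[None, :]

    # ---- ocular artifacts ------------------------------------------------
    total_min = total_s / 60.0
    blink = np.zeros(n_samp)
    n_blinks = rng.poisson(effects.blink_rate * total_min)
    if n_blinks and effects.blink_amp > 0:
        times = np.sort(rng.uniform(0, total_s - effects.blink_dur_s, n_blinks))
        keep = np.concatenate(([True], np.diff(times) > 2 * effects.blink_dur_s))
        tpl = np.sin(np.pi * np.linspace(0, 1, int(effects.blink_dur_s * sfreq))) ** 2
        for bt in times[keep]:
            i = int(bt * sfreq)
            blink[i:i + len(tpl)] += tpl[: n_samp - i]
    sacc = np.zeros(n_samp)
    n_sacc = rng.poisson(effects.saccade_rate * total_min)
    if n_sacc and effects.saccade_amp > 0:
        for _ in range(n_sacc):
            st = rng.uniform(0, total_s - 0.6)
            dur = rng.uniform(0.15, 0.5)
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
            i0, i1 = int(st * sfreq), int((st + dur) * sfreq)
            sacc[i0:i1] += amp
        k = max(3, int(0.025 * sfreq))
        sacc = np.convolve(sacc, np.ones(k) / k, mode="same")
    v_idx, h_idx = montage.index("EOG_V"), montage.index("EOG_H")
    data[v_idx] += effects.blink_amp * blink
    data[h_idx] += effects.saccade_amp * sacc
    gains_b = _blink_gains(montage, effects.blink_frontal_gain,
                           effects.blink_spatial_sigma)
    gains_s = _saccade_gains(montage)
    data += gains_b[:, None] * (effects.blink_amp * blink)[None, :]
    data += gains_s[:, None] * (effects.saccade_amp * sacc)[None, :]

    correct = (rng.random(n_trials) < effects.correct_rate).tolist()
    meta = {"subject": subject if isinstance(subject, str) else f"S{int(subject):02d}",
            "block": block, "seed": int(seed), "correct": correct,
            "conditions": conds}
    events = list(zip(onset_samples.tolist(), conds))
    return Recording(data=data, sfreq=sfreq, montage=montage,
                     events=events, meta=meta)


def noise_free_component_scores(design: StudyDesign, effects: EffectSpec,
                                montage: Montage | None = None) -> "np.ndarray | object":
    """Expected (noise-free) ERP component scores, component x condition.

    Builds one clean trial per condition (components only; no noise, alpha or
    blinks), scores it with the same windows/ROIs the analysis uses, and
    returns a tidy DataFrame — the ground truth the recovery tests compare to.
    """
    import pandas as pd

    montage = montage or default_montage()
    sfreq = design.sfreq
    n_t = int(round(design.picture_s * sfreq)) + 1
    weights = {roi: _roi_weights(montage, roi, effects.component_spatial_sigma)
               for roi in {m["roi"] for m in COMPONENT_TABLE.values()}}
    rows = []
    times = np.arange(n_t) / sfreq
    for cond in CONDITIONS:
        wave = np.zeros((len(montage.channel_names), n_t))
        for comp, meta in COMPONENT_TABLE.items():
            amp = effects.component_amplitudes.get(comp, {}).get(cond, 0.0)
            if amp == 0.0:
                continue
            w0, w1 = meta["window_s"]
            i0, i1 = int(round(w0 * sfreq)), int(round(w1 * sfreq))
            shape = component_shape(max(2, i1 - i0), effects.component_shape_sigma)
            wave[:, i0:i0 + len(shape)] += (weights[meta["roi"]][:, None]
                                            * (amp * shape)[None, :])
        for comp, meta in COMPONENT_TABLE.items():
            w0, w1 = meta["window_s"]
            i0 = int(np.argmin(np.abs(times - w0)))
            i1 = int(np.argmin(np.abs(times - w1)))
            roi_idx = montage.roi_indices(meta["roi"])
            score = float(wave[roi_idx, i0:i1 + 1].mean())
            rows.append({"component": comp, "condition": cond,
                         "expected_uv": score})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# file I/O: HDF5 container with a JSON header, plus a CSV fallback
# --------------------------------------------------------------------------


class RecordingParseError(ValueError):
    """Raised when a stored recording fails validation; names the bad field."""


def write_recording(rec: Recording, path) -> None:
    """Write a recording to a single HDF5 file (datasets + JSON header)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("event_sample",
                         data=np.array([s for s, _ in rec.events], dtype=np.int64))
        labels = np.array([c for _, c in rec.events], dtype="S16")
        f.create_dataset("event_condition", data=labels)
        f.attrs["sfreq"] = float(rec.sfreq)
        f.attrs["montage"] = json.dumps(rec.montage.to_dict())
        f.attrs["meta"] = json.dumps(rec.meta)


def read_recording(path) -> Recording:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            samples = np.asarray(f["event_sample"]).tolist()
            labels = [c.decode() for c in np.asarray(f["event_condition"])]
            sfreq = float(f.attrs["sfreq"])
            montage = Montage.from_dict(json.loads(f.attrs["montage"]))
            meta = json.loads(f.attrs["meta"])
    except (KeyError, OSError) as err:
        raise RecordingParseError(f"malformed recording file {path}: {err}") from err
    if len(samples) != len(labels):
        raise RecordingParseError("events: sample/condition length mismatch")
    try:
        return Recording(data=data, sfreq=sfreq, montage=montage,
                         events=list(zip(samples, labels)), meta=meta)
    except ValueError as err:
        raise RecordingParseError(f"events: {err}") from err


def write_recording_csv(rec: Recording, prefix) -> None:
    """Plain-text fallback: ``<prefix>_data.csv`` (one column per channel),
    ``<prefix>_events.tsv`` and ``<prefix>_header.json``."""
    import pandas as pd

    prefix = Path(prefix)
    pd.DataFrame(rec.data.T, columns=list(rec.montage.channel_names)).to_csv(
        prefix.with_name(prefix.name + "_data.csv"), index=False)
    ev = pd.DataFrame(
        {"onset_sample": [s for s, _ in rec.events],
         "onset_s": [s / rec.sfreq for s, _ in rec.events],
         "condition": [c for _, c in rec.events]})
    ev.to_csv(prefix.with_name(prefix.name + "_events.tsv"), sep="\t", index=False)
    header = {"sfreq": rec.sfreq, "montage": rec.montage.to_dict(),
              "meta": rec.meta}
    prefix.with_name(prefix.name + "_header.json").write_text(
        json.dumps(header, indent=1))


def read_recording_csv(prefix) -> Recording:
    import pandas as pd

    prefix = Path(prefix)
    try:
        header = json.loads(prefix.with_name(prefix.name + "_header.json").read_text())
        montage = Montage.from_dict(header["montage"])
        df = pd.read_csv(prefix.with_name(prefix.name + "_data.csv"))
        ev = pd.read_csv(prefix.with_name(prefix.name + "_events.tsv"), sep="\t")
    except (FileNotFoundError, KeyError, ValueError) as err:
        raise RecordingParseError(f"malformed CSV recording {prefix}: {err}") from err
    missing = [c for c in montage.channel_names if c not in df.columns]
    if missing:
        raise RecordingParseError(f"data: missing channel columns {missing}")
    data = df[list(montage.channel_names)].to_numpy().T
    events = list(zip(ev["onset_sample"].astype(int).tolist(),
                      ev["condition"].astype(str).tolist()))
    try:
        return Recording(data=data, sfreq=float(header["sfreq"]), montage=montage,
                         events=events, meta=header.get("meta", {}))
    except ValueError as err:
        raise RecordingParseError(f"events: {err}") from err
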