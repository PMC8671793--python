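"""Event-related potentials: epoching with a 200 ms pre-stimulus baseline,
trial averaging over behaviorally correct trials, and mean-amplitude scoring
of the six components (N1, EPN over the occipital/parieto-occipital group;
P2, N2, P3, LPP over the prefrontal group).

Scores are the signed mean amplitude over the component window, averaged over
the ROI electrodes — no peak picking.  Window endpoints are mapped to the
sample grid by nearest-sample rounding (sub-millisecond error at 1024 Hz) and
are inclusive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import COMPONENT_TABLE, CONDITIONS, Montage, Recording

logger = logging.getLogger("affective_erd")


@dataclass
class EpochSet:
    """Trial-segmented EEG: ``data`` is trials x channels x time (uV)."""

    data: np.ndarray
    times: np.ndarray                    # s, relative to picture onset
    labels: np.ndarray                   # condition per trial
    correct: np.ndarray                  # behavioral-correctness mask per trial
    sfreq: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.correct = np.asarray(self.correct, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_conditions(self, conditions: Sequence[str]) -> "EpochSet":
        mask = np.isin(self.labels, list(conditions))
        return EpochSet(self.data[mask], self.times, self.labels[mask],
                        self.correct[mask], self.sfreq, self.montage)

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        idx = self.montage.indices(names)
        sub = Montage(channel_names=tuple(names),
                      positions={n: self.montage.positions[n]
                                 for n in names if n in self.montage.positions},
                      roi_sets={roi: tuple(m for m in members if m in names)
                                for roi, members in self.montage.roi_sets.items()})
        return EpochSet(self.data[:, idx, :], self.times, self.labels,
                        self.correct, self.sfreq, sub)


def epoch(rec: Recording, span_s: tuple[float, float] = (-0.2, 4.0),
          baseline_s: tuple[float, float] | None = (-0.2, 0.0)) -> EpochSet:
    """Cut trials around every picture onset and optionally baseline-correct.

    Baseline correction subtracts, per trial and channel, the mean amplitude
    over ``baseline_s`` (default the 200 ms before onset).  Events whose span
    would run past the recording edge are dropped with a logged warning.
    """
    t0, t1 = span_s
    if t1 <= t0:
        raise ValueError("span must have t1 > t0")
    sf = rec.sfreq
    i0, i1 = int(round(t0 * sf)), int(round(t1 * sf))
    n_t = i1 - i0 + 1
    times = (np.arange(n_t) + i0) / sf
    segs, labels, correct = [], [], []
    corr_flags = rec.meta.get("correct", [True] * len(rec.events))
    for k, (onset, cond) in enumerate(rec.events):
        a, b = onset + i0, onset + i1 + 1
        if a < 0 or b > rec.n_samples:
            logger.warning("dropping trial %d (%s): span outside recording", k, cond)
            continue
        segs.append(rec.data[:, a:b])
        labels.append(cond)
        correct.append(bool(corr_flags[k]) if k < len(corr_flags) else True)
    data = (np.stack(segs) if segs
            else np.empty((0, rec.n_channels, n_t)))
    ep = EpochSet(data=data, times=times, labels=np.array(labels, dtype=object),
                  correct=np.array(correct, dtype=bool), sfreq=sf,
                  montage=rec.montage)
    if baseline_s is not None and ep.n_trials:
        b0, b1 = baseline_s
        mask = (ep.times >= b0) & (ep.times < b1)
        if not mask.any():
            raise ValueError(f"baseline window {baseline_s} outside epoch span")
        ep.data -= ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return ep


def epoch_and_baseline(rec: Recording,
                       span_s: tuple[float, float] = (-0.2, 4.0)) -> EpochSet:
    """Epoching with the mandatory 200 ms pre-stimulus baseline correction."""
    if span_s[0] > -0.2:
        raise ValueError("span must include the 200 ms baseline window")
    return epoch(rec, span_s, baseline_s=(-0.2, 0.0))


def average_erp(epochs: EpochSet, condition: str,
                correct_only: bool = True) -> tuple[np.ndarray, int]:
    """Arithmetic mean across qualifying trials of one condition.

    Returns the per-channel waveform (channels x time) and the trial count.
    """
    mask = epochs.labels == condition
    if correct_only:
        mask &= epochs.correct
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no qualifying trials for condition {condition!r}")
    return epochs.data[mask].mean(axis=0), n


@dataclass(frozen=True)
class ComponentSpec:
    """Scoring definition of one ERP component."""

    name: str
    window_s: tuple[float, float]
    electrodes: str                     # ROI name in the montage
    polarity: int = 1                   # sign of the expected deflection

    def __post_init__(self) -> None:
        if self.window_s[1] <= self.window_s[0]:
            raise ValueError(f"{self.name}: empty window {self.window_s}")


def default_component_specs() -> list[ComponentSpec]:
    return [ComponentSpec(name=name, window_s=meta["window_s"],
                          electrodes=meta["roi"], polarity=meta["polarity"])
            for name, meta in COMPONENT_TABLE.items()]


def _window_slice(times: np.ndarray, window: tuple[float, float]) -> slice:
    if window[0] < times[0] - 1e-9 or window[1] > times[-1] + 1e-9:
        raise ValueError(f"window {window} outside epoch span "
                         f"[{times[0]:.3f}, {times[-1]:.3f}]")
    i0 = int(np.argmin(np.abs(times - window[0])))
    i1 = int(np.argmin(np.abs(times - window[1])))
    return slice(i0, i1 + 1)


def score_components(waveform: np.ndarray, times: np.ndarray,
                     specs: Sequence[ComponentSpec], montage: Montage
                     ) -> pd.DataFrame:
    """Mean-amplitude scores of one averaged waveform (channels x time)."""
    rows = []
    for spec in specs:
        members = montage.roi_sets[spec.electrodes]
        missing = [m for m in members if m not in montage.channel_names]
        if missing:
            raise ValueError(f"{spec.name}: electrodes {missing} not present")
        sl = _window_slice(times, spec.window_s)
        idx = montage.indices(members)
        rows.append({"component": spec.name,
                     "mean_amplitude_uv": float(waveform[idx, sl].mean())})
    return pd.DataFrame(rows)


def score_epochset(epochs: EpochSet, specs: Sequence[ComponentSpec] | None = None,
                   correct_only: bool = True, subject: str = "",
                   block: str = "") -> pd.DataFrame:
    """Per-condition component scores of one epoch set (tidy DataFrame)."""
    specs = specs or default_component_specs()
    rows = []
    for cond in sorted(set(epochs.labels.tolist()), key=list(CONDITIONS).index):
        wave, n = average_erp(epochs, cond, correct_only=correct_only)
        scores = score_components(wave, epochs.times, specs, epochs.montage)
        for _, r in scores.iterrows():
            rows.append({"subject": subject, "block": block, "condition": cond,
                         "component": r["component"],
                         "mean_amplitude_uv": r["mean_amplitude_uv"],
                         "n_trials": n})
    return pd.DataFrame(rows)


def difference_wave(epochs: EpochSet, minuend: str, subtrahend: str,
                    correct_only: bool = True) -> np.ndarray:
    """Convenience difference wave (e.g. emotional minus neutral)."""
    a, _ = average_erp(epochs, minuend, correct_only)
    b, _ = average_erp(epochs, subtrahend, correct_only)
    return a - b
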